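"""Generate a synthetic knockout screen and inspect its multiplexed layout.

The generator emulates a TMT 10plex screen: each run carries up to eight
knockout strains, one technical spike-in reference (127C) and one
biological wild-type control (130N), with run- and plate-level batch
effects and abundance-dependent missingness.
"""

import numpy as np

import proteoscan as ps

config = ps.ScreenSimConfig(seed=0)
matrix, manifest, growth, truth = ps.generate_screen(config)

layout = ps.validate_layout(manifest)
print(f"{layout.n_runs} runs, {layout.n_samples} samples "
      "(knockouts + biological controls; spike-ins excluded)")
print(f"matrix: {matrix.data.shape[0]} proteins x {matrix.data.shape[1]} channels")
missing = float(matrix.data.isna().mean().mean())
print(f"overall missingness: {missing:.1%}")

abundance = np.log2(matrix.data).mean(axis=1)
rate_hi = matrix.data.notna().mean(axis=1)[abundance >= abundance.quantile(0.9)].mean()
rate_lo = matrix.data.notna().mean(axis=1)[abundance <= abundance.quantile(0.1)].mean()
print(f"quantification rate, top vs bottom abundance decile: "
      f"{rate_hi:.2f} vs {rate_lo:.2f}")
print("-> abundant proteins are quantified more often, as in real screens")

# the full-scale design arithmetic of the screen this emulates
full = ps.validate_layout(ps.build_layout(3308, 461))
print(f"full-scale design: {full.n_runs} runs, {full.n_samples} samples")
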