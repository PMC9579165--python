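"""Three-stage cross-run normalization for multiplexed reporter intensities.

Stage 1 divides every channel by the run's technical spike-in channel (on
the log2 scale: a subtraction), which cancels per-(protein, run)
measurement shifts because the spike-in is the same frozen lysate in every
run.  Stage 2 centers each sample's median at zero.  Stage 3 adjusts each
protein's per-run median to its global median, removing residual
per-(protein, run) batch structure (e.g. plate-of-growth effects the
spike-in does not carry).  After stage 3 the technical channels are
uninformative and are dropped from downstream analysis.

Diagnostics: the bias coefficient (mean per-protein fraction of variance
explained by run membership) quantifies residual batch effect, and the
fidelity median (median per-sample Pearson correlation to the
pre-normalization data) quantifies how much of the original signal is
retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import IntensityMatrix, SampleManifest, ValidationError


@dataclass
class StageMetrics:
    stage: str
    bias_coefficient: float
    fidelity_median: float


@dataclass
class NormalizationReport:
    """Ordered per-stage diagnostics for a normalization pipeline."""

    stages: list[StageMetrics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages]).set_index("stage")


def _nontechnical(manifest: SampleManifest) -> list[str]:
    df = manifest.frame
    return df.loc[df["sample_type"] != "wt_technical", "sample_id"].tolist()


def spike_reference_normalize(
    m: IntensityMatrix, manifest: SampleManifest
) -> IntensityMatrix:
    """Log2-ratio against the run's technical spike-in channel.

    Proteins without an intensity in a run's spike-in channel are removed
    for that run (all its samples set missing for the protein).
    """
    m = m.to_log2()
    tech = manifest.technical_samples()  # run -> sample; raises if a run lacks one
    run_of = manifest.run_of()
    out = m.data.copy()
    for run, tech_sample in tech.items():
        run_samples = run_of.index[run_of == run]
        run_samples = [s for s in run_samples if s in out.columns]
        if tech_sample not in out.columns:
            raise ValidationError(f"technical sample {tech_sample} not in matrix")
        ref = out[tech_sample].copy()
        out.loc[:, run_samples] = out.loc[:, run_samples].sub(ref, axis=0)
        out.loc[ref.isna(), run_samples] = np.nan
    return IntensityMatrix(out, scale="log")


def sample_median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Shift each sample column so its median over observed proteins is 0."""
    if m.scale == "raw":
        m = m.to_log2()
    data = m.data
    n_obs = data.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValidationError(f"samples with zero observed proteins: {empty}")
    out = data.sub(data.median(axis=0, skipna=True), axis=1)
    return IntensityMatrix(out, scale=m.scale if m.scale != "raw" else "log")


def protein_median_adjust(
    m: IntensityMatrix,
    manifest: SampleManifest,
    drop_technical: bool = True,
) -> IntensityMatrix:
    """Equalize each protein's per-run median to its global median.

    Medians are computed over observed, non-technical samples only.  After
    adjustment each protein's per-run medians all equal its global
    pre-adjustment median exactly.  Technical spike-in columns are dropped
    afterwards by default (they play no further role).
    """
    if m.scale == "raw":
        m = m.to_log2()
    out = m.data.copy()
    run_of = manifest.run_of()
    keep = [s for s in _nontechnical(manifest) if s in out.columns]
    sub = out.loc[:, keep]
    runs = run_of.reindex(keep)
    global_median = sub.median(axis=1, skipna=True)
    for run in runs.drop_duplicates():
        cols = runs.index[runs == run].tolist()
        run_median = sub.loc[:, cols].median(axis=1, skipna=True)
        shift = global_median - run_median
        out.loc[:, cols] = out.loc[:, cols].add(shift, axis=0)
    if drop_technical:
        out = out.loc[:, keep]
    return IntensityMatrix(out, scale="normalized")


def batch_bias_metrics(
    before: IntensityMatrix,
    after: IntensityMatrix,
    manifest: SampleManifest,
    stage: str = "stage",
) -> StageMetrics:
    """Residual batch effect and fidelity of one normalization stage.

    Bias coefficient: mean over proteins of the fraction of that protein's
    variance explained by run membership (one-way between/total sum of
    squares over observed values, non-technical samples).  Fidelity: median
    over samples of the Pearson correlation between the before and after
    columns (pairwise-complete).
    """
    b = before.to_log2().data
    a = after.to_log2().data
    cols = [s for s in a.columns if s in b.columns]
    cols = [s for s in cols if s in set(_nontechnical(manifest))]
    idx = a.index.intersection(b.index)
    a = a.loc[idx, cols]
    b = b.loc[idx, cols]
    runs = manifest.run_of().reindex(cols)
    if runs.nunique() < 2:
        raise ValidationError("bias coefficient needs at least 2 runs")

    bias = _mean_between_run_variance_fraction(a, runs)

    fids = []
    for s in cols:
        x, y = b[s].to_numpy(), a[s].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            fids.append(np.corrcoef(x[ok], y[ok])[0, 1])
    fidelity = float(np.median(fids)) if fids else float("nan")
    return StageMetrics(stage=stage, bias_coefficient=bias, fidelity_median=fidelity)


def _mean_between_run_variance_fraction(data: pd.DataFrame, runs: pd.Series) -> float:
    run_codes, _ = pd.factorize(runs)
    vals = data.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    filled = np.where(obs, vals, 0.0)
    n_runs = run_codes.max() + 1
    # per-(protein, run) sums and counts via one-hot projection
    onehot = np.eye(n_runs)[run_codes]          # samples × runs
    sum_g = filled @ onehot                     # proteins × runs
    n_g = obs.astype(float) @ onehot
    tot_n = n_g.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = sum_g.sum(axis=1) / tot_n
        mean_g = sum_g / n_g
        dev = np.where(n_g > 0, (mean_g - grand[:, None]) ** 2, 0.0)
        ssb = (n_g * dev).sum(axis=1)
        sst = (filled**2).sum(axis=1) - tot_n * grand**2
        frac = ssb / sst
    usable = (tot_n >= 3) & ((n_g > 0).sum(axis=1) >= 2) & (sst > 1e-300)
    return float(frac[usable].mean()) if usable.any() else float("nan")


def normalize_pipeline(
    m: IntensityMatrix, manifest: SampleManifest
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Run spike → sample-median → protein-median and report diagnostics."""
    logged = m.to_log2()
    stages = [
        ("spike_reference", lambda x: spike_reference_normalize(x, manifest)),
        ("sample_median", sample_median_normalize),
        ("protein_median", lambda x: protein_median_adjust(x, manifest)),
    ]
    report = NormalizationReport()
    current = logged
    for name, fn in stages:
        current = fn(current)
        report.stages.append(batch_bias_metrics(logged, current, manifest, stage=name))
    return current, report
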