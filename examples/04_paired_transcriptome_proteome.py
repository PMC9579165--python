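"""Paired transcriptome-proteome correlation and regulation archetypes.

Matched quadruplicate transcript/protein measurements per strain yield
per-gene fold changes on both layers.  Genes changing at the protein
level under stable mRNA are selected, ranked by how many strains show the
pattern, and the top half is clustered with PAM; the silhouette-selected
number of clusters exposes the two regulation archetypes (generally up
vs generally down).
"""

import proteoscan as ps

config = ps.PairedSimConfig(seed=0)
txome, proteome, truth = ps.generate_paired_omics(config)
fc = ps.build_foldchanges(txome, proteome, truth.sample_to_strain)

sim = ps.strain_pair_similarity(fc)
print(f"{sim.n_pairs} ordered strain pairs "
      f"({len(fc.strains)} strains)")

per_strain = ps.per_strain_corr(fc)
print(f"per-strain transcript-protein correlation: "
      f"{per_strain['r'].min():.2f} to {per_strain['r'].max():.2f}")
print("-> low values flag strains with post-transcriptional effects")

per_gene = ps.per_gene_corr(fc)
pos = ((per_gene["p"] < 0.05) & (per_gene["r"] > 0)).sum()
neg = ((per_gene["p"] < 0.05) & (per_gene["r"] < 0)).sum()
print(f"genes with significant transcript-protein correlation: "
      f"{pos} positive, {neg} negative")

genes, counts = ps.select_protein_only(fc)
print(f"\nprotein-only regulated genes selected (top half of "
      f"{(counts > 0).sum()} candidates): {len(genes)}")

pam, sub = ps.cluster_protein_only(fc, genes, k_range=range(2, 11))
print(f"PAM on {sub.shape[0]} genes x {sub.shape[1]} strains: "
      f"silhouette-selected k = {pam.k} "
      f"(avg width {pam.silhouette:.2f})")
sizes = pam.labels.value_counts().sort_index()
print(f"archetype sizes: {sizes.tolist()} "
      "(generally-up vs generally-down genes)")
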