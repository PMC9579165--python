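"""SOM co-expression clustering of proteins and annotation benchmarking.

Proteins are z-scored across knockout strains and grouped on a
self-organizing map; clusters with tight member-to-codebook distances
(below the 75th percentile of all distances) are kept and benchmarked
against an association network: the connectivity score is the
within-cluster association count over size-matched random draws.
"""

from sklearn.metrics import adjusted_rand_score

import proteoscan as ps

matrix, manifest, _, truth = ps.generate_screen(ps.ScreenSimConfig(seed=0))
normed, _ = ps.normalize_pipeline(matrix, manifest)

z = ps.coexpression_input(normed, manifest)

model = ps.som_cluster(z, grid=(4, 3), epochs=100, seed=1)
clusters = ps.filter_clusters(model, percentile=75)
kept = clusters.kept_clusters
print(f"{len(kept)} of {len(clusters.members)} clusters kept "
      f"({sum(len(m) for m in kept.values())} proteins)")

labels = clusters.labels()
ari = adjusted_rand_score(truth.modules.reindex(labels.index), labels)
print(f"agreement with the planted co-expression modules (ARI): {ari:.2f}")

net = ps.generate_annotation_network(truth, within_module_rate=0.2,
                                     background_rate=0.1, seed=2)
conn = ps.connectivity_score(clusters, net, universe=list(truth.modules.index),
                             n_random=500, seed=3)
print(f"aggregate connectivity score of kept clusters: {conn.score:.2f}")
print("-> ~2 means twice as many within-cluster associations as expected "
      "by chance (the planted enrichment)")
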