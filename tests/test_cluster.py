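"""SOM clustering, quality filtering, connectivity and enrichment tests."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proteoscan as ps
from proteoscan.cluster import _ks_enrichment_score


# -- z-scoring ----------------------------------------------------------------

def test_zscore_rows_population_sd_convention():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"])
    out = ps.zscore_rows(df)
    np.testing.assert_allclose(out.loc["r"], [-1.2247448, 0.0, 1.2247448],
                               atol=1e-6)


def test_zscore_rows_missing_preserved_and_centered():
    df = pd.DataFrame([[1.0, np.nan, 3.0, 5.0]], index=["r"])
    out = ps.zscore_rows(df)
    assert np.isnan(out.iloc[0, 1])
    assert np.nanmean(out.to_numpy()) == pytest.approx(0.0, abs=1e-12)
    assert np.nanstd(out.to_numpy()) == pytest.approx(1.0, abs=1e-12)


def test_zscore_rows_rejects_constant_rows():
    df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    with pytest.raises(ps.ValidationError, match="flat"):
        ps.zscore_rows(df)


# -- pairwise-complete Pearson ------------------------------------------------

def _pearson_oracle(data, min_overlap):
    """Explicit loops over complete pairs."""
    X = data.to_numpy(dtype=float)
    n = len(X)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if ok.sum() < min_overlap:
                continue
            x, y = X[i][ok], X[j][ok]
            if x.std() == 0 or y.std() == 0:
                continue
            out[i, j] = np.corrcoef(x, y)[0, 1]
    return out


def test_pairwise_pearson_trivial_identities():
    df = pd.DataFrame([[1.0, 2.0, 4.0], [-1.0, -2.0, -4.0]], index=["x", "mx"])
    r = ps.pairwise_pearson(df, min_overlap=3)
    assert r.loc["x", "x"] == pytest.approx(1.0)
    assert r.loc["x", "mx"] == pytest.approx(-1.0)


def test_pairwise_pearson_partial_overlap_example():
    df = pd.DataFrame([[1.0, 2.0, 3.0, np.nan], [1.0, 1.0, 2.0, 5.0]],
                      index=["x", "y"])
    r = ps.pairwise_pearson(df, min_overlap=3)
    assert r.loc["x", "y"] == pytest.approx(0.8660254, abs=1e-6)


def test_pairwise_pearson_matches_brute_force_with_missingness():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(15, 30))
    X[rng.random(X.shape) < 0.2] = np.nan
    df = pd.DataFrame(X)
    r = ps.pairwise_pearson(df, min_overlap=5)
    oracle = _pearson_oracle(df, min_overlap=5)
    np.testing.assert_allclose(r.to_numpy(), oracle, atol=1e-12)


def test_pairwise_pearson_min_overlap_gives_missing():
    df = pd.DataFrame([[1.0, 2.0, np.nan, np.nan],
                       [np.nan, np.nan, 1.0, 2.0]], index=["a", "b"])
    r = ps.pairwise_pearson(df, min_overlap=3)
    assert np.isnan(r.loc["a", "b"])


# -- SOM ----------------------------------------------------------------------

def test_som_grid_unit_counts():
    rng = np.random.default_rng(1)
    items = pd.DataFrame(rng.normal(size=(160, 5)),
                         index=[f"i{k}" for k in range(160)])
    model = ps.train_som(items, grid=(12, 12), epochs=5, seed=0)
    assert model.n_units == 144
    model2 = ps.train_som(items, grid=(11, 11), epochs=5, seed=0)
    assert model2.n_units == 121


def test_som_separates_two_blobs_perfectly():
    rng = np.random.default_rng(2)
    a = rng.normal(0.0, 0.1, (30, 4))
    b = rng.normal(5.0, 0.1, (30, 4))
    items = pd.DataFrame(np.vstack([a, b]), index=[f"i{k}" for k in range(60)])
    model = ps.train_som(items, grid=(2, 1), epochs=50, seed=3)
    units = model.assignments()
    assert units.iloc[:30].nunique() == 1
    assert units.iloc[30:].nunique() == 1
    assert units.iloc[0] != units.iloc[-1]


def test_som_deterministic_and_rejects_empty():
    rng = np.random.default_rng(4)
    items = pd.DataFrame(rng.normal(size=(50, 6)))
    items.index = [f"i{k}" for k in range(50)]
    m1 = ps.train_som(items, grid=(3, 3), epochs=20, seed=9)
    m2 = ps.train_som(items, grid=(3, 3), epochs=20, seed=9)
    np.testing.assert_array_equal(m1.bmu, m2.bmu)
    np.testing.assert_allclose(m1.codebook, m2.codebook)
    with pytest.raises(ps.ValidationError):
        ps.train_som(items.iloc[:0], grid=(1, 1))


def test_som_handles_missing_dimensions():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 6))
    X[:20] += 4.0
    X[rng.random(X.shape) < 0.15] = np.nan
    items = pd.DataFrame(X, index=[f"i{k}" for k in range(40)])
    model = ps.train_som(items, grid=(2, 1), epochs=60, seed=1)
    units = model.assignments()
    assert np.isfinite(model.distances).all()
    agree = max((units.iloc[:20] == u).sum() + (units.iloc[20:] != u).sum()
                for u in (0, 1))
    assert agree >= 38  # near-perfect split despite missing entries


# -- cluster filtering --------------------------------------------------------

def _model_with_distances(cluster_distances):
    """Synthetic SOMModel: one unit per cluster, items at given distances."""
    items, bmu, dist = [], [], []
    for c, ds in enumerate(cluster_distances):
        for k, d in enumerate(ds):
            items.append(f"c{c}_{k}")
            bmu.append(c)
            dist.append(d)
    n = len(cluster_distances)
    return ps.SOMModel(grid=(n, 1), codebook=np.zeros((n, 1)),
                       item_ids=items, bmu=np.array(bmu),
                       distances=np.array(dist), seed=0, epochs=0)


def test_filter_clusters_percentile_rule():
    model = _model_with_distances([[1.0], [3.0], [5.0], [7.0]])
    # pooled 75th percentile of [1,3,5,7] = 5.5 -> keep means 1, 3, 5
    cs = ps.filter_clusters(model, percentile=75)
    assert cs.threshold == pytest.approx(5.5)
    assert cs.kept.tolist() == [True, True, True, False]


def test_filter_clusters_boundary_and_percentile_100():
    model = _model_with_distances([[2.0], [2.0], [2.0]])
    cs = ps.filter_clusters(model, percentile=75)
    assert not cs.kept.any()  # strictly-below rule, all at the threshold
    cs_all = ps.filter_clusters(model, percentile=100)
    assert not cs_all.kept.any()  # still not strictly below the maximum
    model2 = _model_with_distances([[1.0], [2.0], [3.0]])
    assert ps.filter_clusters(model2, percentile=100).kept.tolist() == [
        True, True, False]


def test_filter_clusters_kept_fraction_monotone_in_percentile(screen_bundle):
    z = ps.coexpression_input(screen_bundle["normed"], screen_bundle["manifest"])
    model = ps.som_cluster(z, grid=(4, 3), epochs=20, seed=0)
    fractions = []
    for pct in (25, 50, 75, 100):
        cs = ps.filter_clusters(model, percentile=pct)
        kept_items = sum(len(m) for m in cs.kept_clusters.values())
        fractions.append(kept_items)
    assert fractions == sorted(fractions)


# -- connectivity -------------------------------------------------------------

def test_connectivity_observed_counts_and_zero_cluster():
    net = ps.AnnotationNetwork(pd.DataFrame(dict(
        protein_a=["A", "B"], protein_b=["B", "C"], combined_score=[200, 100])))
    clusters = {0: ["A", "B", "C"], 1: ["D", "E"]}
    res = ps.connectivity_score(clusters, net,
                                universe=list("ABCDEFGH"), n_random=200, seed=0)
    row0 = res.per_cluster.set_index("cluster").loc[0]
    assert row0["observed"] == 1  # only A-B crosses the >150 threshold
    row1 = res.per_cluster.set_index("cluster").loc[1]
    assert row1["observed"] == 0
    assert row1["score"] == 0.0 or np.isnan(row1["score"])


def test_connectivity_recovers_planted_enrichment(screen_bundle):
    truth = screen_bundle["truth"]
    net = ps.generate_annotation_network(truth, within_module_rate=0.2,
                                         background_rate=0.1, seed=2)
    modules = truth.modules
    clusters = {int(k): list(v.index) for k, v in modules.groupby(modules)}
    res = ps.connectivity_score(clusters, net, universe=list(modules.index),
                                n_random=1000, seed=3)
    assert res.score == pytest.approx(2.0, rel=0.15)


def test_som_recovers_planted_modules(screen_bundle):
    from sklearn.metrics import adjusted_rand_score

    truth = screen_bundle["truth"]
    z = ps.coexpression_input(screen_bundle["normed"], screen_bundle["manifest"])
    model = ps.som_cluster(z, grid=(4, 3), epochs=100, seed=5)
    clusters = ps.filter_clusters(model)
    labels = clusters.labels()
    ari = adjusted_rand_score(truth.modules.reindex(labels.index), labels)
    assert ari >= 0.7


# -- strain clustering --------------------------------------------------------

def test_strain_pipeline_removes_wt_clusters_and_concentrates_wt():
    cfg = ps.ScreenSimConfig(seed=5, effect_fraction=0.3, effect_sd=8.0)
    m, manifest, _, _ = ps.generate_screen(cfg)
    normed, _ = ps.normalize_pipeline(m, manifest)
    clusters, model = ps.strain_cluster_pipeline(
        normed, manifest, grid=(4, 4), epochs=150, seed=2)
    wt = set(manifest.samples_of_type("wt_biological"))
    # surviving clusters contain no wild-type sample
    for members in clusters.members.values():
        assert not (set(members) & wt)
    # wild-type samples concentrate: >=80% land in <=20% of the units
    assign = model.assignments()
    wt_units = assign[assign.index.isin(wt)].value_counts()
    top = max(1, int(0.2 * model.n_units))
    assert wt_units.iloc[:top].sum() / wt_units.sum() >= 0.8


def test_strain_pipeline_toy_wt_removal_rule():
    # 3 tight blobs; one contains the only WT biological sample per run
    manifest = ps.build_layout(16, 2)
    rng = np.random.default_rng(0)
    proteins = [f"p{i}" for i in range(30)]
    cols = {}
    i_ko = 0
    for row in manifest.frame.itertuples(index=False):
        if row.sample_type == "wt_technical":
            cols[row.sample_id] = rng.normal(0.0, 0.05, 30)
        elif row.sample_type == "wt_biological":
            cols[row.sample_id] = rng.normal(20.0, 0.05, 30)
        else:
            cols[row.sample_id] = rng.normal(10.0 * (i_ko % 2), 0.05, 30)
            i_ko += 1
    m = ps.IntensityMatrix(pd.DataFrame(cols, index=proteins), scale="log")
    clusters, model = ps.strain_cluster_pipeline(
        m, manifest, grid=(3, 1), epochs=60, seed=1)
    assert len(clusters.members) == 2  # the WT blob's unit was removed
    assert sorted(len(v) for v in clusters.members.values()) == [8, 8]


# -- genetic-interaction benchmark --------------------------------------------

def test_gi_profile_comparison_detects_shift_and_null_is_uniformish():
    rng = np.random.default_rng(6)
    items = [f"s{i}" for i in range(40)]
    clusters = {0: items[:20], 1: items[20:]}
    # profile correlations: within-cluster pairs shifted +0.5
    corr = pd.DataFrame(rng.normal(0, 0.1, (40, 40)), index=items, columns=items)
    corr = (corr + corr.T) / 2
    for c, mem in clusters.items():
        for a, b in combinations(mem, 2):
            corr.loc[a, b] += 0.5
            corr.loc[b, a] += 0.5
    stat, p = ps.gi_profile_comparison(clusters, corr)
    assert p < 0.01
    # null: no shift
    pvals = []
    for seed in range(30):
        r = np.random.default_rng(seed)
        c2 = pd.DataFrame(r.normal(size=(20, 20)),
                          index=items[:20], columns=items[:20])
        c2 = (c2 + c2.T) / 2
        _, p0 = ps.gi_profile_comparison({0: items[:10], 1: items[10:20]}, c2)
        pvals.append(p0)
    assert min(pvals) < 0.5 < max(pvals)  # spread, not degenerate


def test_gi_profile_comparison_errors_on_tiny_group():
    corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
    with pytest.raises(ps.ValidationError):
        ps.gi_profile_comparison({0: ["a", "b"], 1: ["c"]}, corr)


# -- hypergeometric enrichment ------------------------------------------------

def test_hypergeom_closed_form_and_degenerate_cases():
    universe = [f"g{i}" for i in range(10)]
    gs = ps.GeneSetCollection({"s": frozenset(universe[:5])})
    cluster = universe[:4]
    out = ps.hypergeom_enrichment(cluster, gs, universe).set_index("set_id")
    assert out.loc["s", "p"] == pytest.approx(comb(5, 4) / comb(10, 4))
    disjoint = ps.hypergeom_enrichment(universe[5:9], gs, universe)
    assert disjoint["p"].iloc[0] == pytest.approx(1.0)
    everything = ps.hypergeom_enrichment(universe, gs, universe)
    assert everything["p"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(ps.ValidationError):
        ps.hypergeom_enrichment(cluster, gs, [])


# -- preranked GSEA -----------------------------------------------------------

def _gsea_oracle_exhaustive(n, k, observed_positions):
    """Brute-force: ES from a naive running sum; p over all placements."""
    def es_of(positions):
        hits = set(positions)
        running, best = 0.0, 0.0
        for i in range(n):
            running += (1.0 / k) if i in hits else (-1.0 / (n - k))
            if abs(running) > abs(best):
                best = running
        return best

    obs = es_of(observed_positions)
    null = [es_of(c) for c in combinations(range(n), k)]
    if obs >= 0:
        p = sum(1 for e in null if e >= obs) / len(null)
    else:
        p = sum(1 for e in null if e <= obs) / len(null)
    return obs, p


def test_gsea_exhaustive_matches_enumeration_oracle():
    ranking = [f"x{i}" for i in range(6)]
    for members in [("x0", "x1"), ("x2", "x4"), ("x4", "x5"), ("x0", "x5")]:
        res = ps.preranked_gsea(ranking, {"s": frozenset(members)},
                                exhaustive=True)
        positions = sorted(ranking.index(m) for m in members)
        es, p = _gsea_oracle_exhaustive(6, 2, positions)
        assert res["es"].iloc[0] == pytest.approx(es, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p, abs=1e-9)


def test_gsea_top_set_is_maximally_enriched():
    ranking = [f"s{i}" for i in range(60)]
    res = ps.preranked_gsea(ranking, {"top": frozenset(ranking[:6])},
                            n_perm=400, seed=0)
    assert res["es"].iloc[0] == pytest.approx(1.0)
    assert res["p"].iloc[0] <= 1.0 / 401 + 1e-9


def test_gsea_errors():
    ranking = ["a", "b", "c"]
    with pytest.raises(ps.ValidationError):
        ps.preranked_gsea(ranking, {"s": frozenset("abcd")}, n_perm=100)
    with pytest.raises(ps.ValidationError):
        ps.preranked_gsea(ranking, {"s": frozenset("a")}, n_perm=10)
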