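"""Co-expression clustering, cluster quality filtering and benchmarking.

Proteins (or, transposed, strains) are z-scored, grouped with a
self-organizing map, and clusters are kept when their mean member-to-
codebook distance falls below the 75th percentile of all item distances.
Kept clusters are benchmarked against an annotation network (connectivity
score: observed within-cluster associations over the mean of size-matched
random draws), against genetic-interaction profile correlations
(within- vs between-cluster rank-sum test), and against gene sets
(hypergeometric enrichment).  A preranked, unweighted-KS gene set
enrichment statistic with permutation p-values ranks strains by the extent
of their proteome remodeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AnnotationNetwork,
    GeneSetCollection,
    IntensityMatrix,
    SampleManifest,
    ValidationError,
)
from .diffexpr import bh_fdr
from .som import SOMModel, train_som


# -- row transforms and correlations ------------------------------------------

def zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score over observed entries (population SD, n denominator).

    Missing entries stay missing.  Rows with fewer than 2 observed values
    or zero SD are rejected.
    """
    vals = data.to_numpy(dtype=float)
    n_obs = (~np.isnan(vals)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd = np.nanstd(vals, axis=1, ddof=0)
    bad = (n_obs < 2) | (sd == 0) | np.isnan(sd)
    if bad.any():
        raise ValidationError(
            f"rows with <2 observations or zero SD: {data.index[bad].tolist()[:10]}"
        )
    mean = np.nanmean(vals, axis=1)
    out = (vals - mean[:, None]) / sd[:, None]
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def pairwise_pearson(data: pd.DataFrame, min_overlap: int = 10) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between rows.

    Each pair is correlated over the positions observed in both rows;
    pairs with fewer than ``min_overlap`` shared positions are missing.
    """
    X = data.to_numpy(dtype=float)
    M = (~np.isnan(X)).astype(float)
    A = np.where(np.isnan(X), 0.0, X)
    n = M @ M.T
    Sx = A @ M.T
    Sy = Sx.T
    Sxx = (A * A) @ M.T
    Syy = Sxx.T
    Sxy = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sy / n
        vx = Sxx - Sx * Sx / n
        vy = Syy - Sy * Sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < min_overlap) | ~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=data.index, columns=data.index)


def coexpression_input(
    m: IntensityMatrix,
    manifest: SampleManifest,
    min_obs: int = 3,
    winsorize: float | None = 3.0,
) -> pd.DataFrame:
    """Z-scored proteins × knockout-samples matrix for co-expression work.

    Proteins observed in fewer than ``min_obs`` knockout samples or with
    zero variance are dropped; z-scores are winsorized at ±``winsorize``
    (pass None to disable) so strains with extreme proteome remodeling do
    not dominate the Euclidean geometry of the clustering.
    """
    ko = set(manifest.samples_of_type("knockout"))
    prof = m.data.loc[:, [s for s in m.data.columns if s in ko]]
    usable = (prof.notna().sum(axis=1) >= min_obs) & (prof.std(axis=1, ddof=0) > 0)
    z = zscore_rows(prof.loc[usable])
    if winsorize is not None:
        z = z.clip(-winsorize, winsorize)
    return z


# -- SOM clustering and filtering ---------------------------------------------

def som_cluster(
    items: pd.DataFrame,
    grid: tuple[int, int] = (12, 12),
    epochs: int = 500,
    seed: int = 0,
) -> SOMModel:
    """Train a SOM on z-scored items (see :mod:`proteoscan.som`)."""
    return train_som(items, grid=grid, epochs=epochs, seed=seed)


@dataclass
class ClusterSet:
    """SOM units as clusters, with the mean-distance quality filter."""

    members: dict[int, list[str]]        # cluster id → item ids (disjoint)
    mean_distance: pd.Series             # cluster id → mean member distance
    kept: pd.Series                      # cluster id → bool
    threshold: float

    @property
    def kept_clusters(self) -> dict[int, list[str]]:
        return {c: m for c, m in self.members.items() if self.kept[c]}

    def labels(self, kept_only: bool = True) -> pd.Series:
        pairs = [
            (item, c)
            for c, mem in (self.kept_clusters if kept_only else self.members).items()
            for item in mem
        ]
        return pd.Series({i: c for i, c in pairs}, name="cluster")


def filter_clusters(model: SOMModel, percentile: float = 75.0) -> ClusterSet:
    """Keep clusters whose mean member distance is strictly below the
    given percentile of all item distances; empty units are dropped."""
    assign = model.assignments()
    threshold = float(np.percentile(model.distances, percentile))
    members: dict[int, list[str]] = {}
    means: dict[int, float] = {}
    dist = pd.Series(model.distances, index=model.item_ids)
    for unit, group in assign.groupby(assign):
        ids = group.index.tolist()
        members[int(unit)] = ids
        means[int(unit)] = float(dist[ids].mean())
    mean_distance = pd.Series(means).sort_index()
    kept = mean_distance < threshold
    return ClusterSet(members=members, mean_distance=mean_distance,
                      kept=kept, threshold=threshold)


# -- annotation-network connectivity ------------------------------------------

@dataclass
class ConnectivityResult:
    per_cluster: pd.DataFrame  # cluster, size, observed, null_mean, score, p
    score: float               # aggregate: Σ observed / Σ null mean
    n_random: int


def connectivity_score(
    clusters: ClusterSet | dict[int, list[str]],
    net: AnnotationNetwork,
    universe: list[str] | None = None,
    score_threshold: int = 150,
    n_random: int = 1000,
    seed: int = 0,
) -> ConnectivityResult:
    """Within-cluster association count versus size-matched random draws.

    observed = number of within-cluster pairs with combined score strictly
    above ``score_threshold``; the null is the mean observed count over
    ``n_random`` random protein sets of the same size drawn from the
    universe; score = observed / null mean and the empirical p-value is
    (1 + #{null ≥ observed}) / (n_random + 1).
    """
    members = clusters.kept_clusters if isinstance(clusters, ClusterSet) else clusters
    if universe is None:
        universe = sorted({i for mem in members.values() for i in mem})
    index_of = {p: i for i, p in enumerate(universe)}
    n = len(universe)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in net.associated_pairs(score_threshold):
        ia, ib = index_of.get(a), index_of.get(b)
        if ia is not None and ib is not None:
            adj[ia, ib] = adj[ib, ia] = True
    rng = np.random.default_rng(seed)
    rows = []
    total_obs, total_null = 0.0, 0.0
    for cid in sorted(members):
        ids = [i for i in members[cid] if i in index_of]
        size = len(ids)
        if size < 2:
            continue
        idx = np.array([index_of[i] for i in ids])
        observed = int(adj[np.ix_(idx, idx)].sum() // 2)
        null_counts = np.empty(n_random)
        for r in range(n_random):
            samp = rng.choice(n, size=size, replace=False)
            null_counts[r] = adj[np.ix_(samp, samp)].sum() // 2
        null_mean = float(null_counts.mean())
        score = observed / null_mean if null_mean > 0 else np.nan
        p = (1.0 + np.sum(null_counts >= observed)) / (n_random + 1.0)
        rows.append(dict(cluster=cid, size=size, observed=observed,
                         null_mean=null_mean, score=score, p=p))
        total_obs += observed
        total_null += null_mean
    per_cluster = pd.DataFrame(rows)
    agg = total_obs / total_null if total_null > 0 else np.nan
    return ConnectivityResult(per_cluster=per_cluster, score=float(agg),
                              n_random=n_random)


# -- strain-axis clustering ----------------------------------------------------

def strain_cluster_pipeline(
    m: IntensityMatrix,
    manifest: SampleManifest,
    grid: tuple[int, int] = (11, 11),
    epochs: int = 500,
    seed: int = 0,
    percentile: float = 75.0,
) -> tuple[ClusterSet, SOMModel]:
    """Cluster strains (knockouts + wild-type replicates) by proteome profile.

    Proteins are z-scored across all retained samples (the same transform
    the protein-axis clustering uses); each strain's profile is its column
    of per-protein z-scores, so unperturbed wild-type samples sit near the
    origin and group together.  Clusters containing ANY wild-type sample
    are removed, then the surviving clusters pass the usual mean-distance
    percentile filter (percentile computed over the surviving items'
    distances).
    """
    df = manifest.frame
    wt_samples = set(df.loc[df["sample_type"] == "wt_biological", "sample_id"])
    keep_cols = [s for s in m.data.columns
                 if s in wt_samples
                 or s in set(df.loc[df["sample_type"] == "knockout", "sample_id"])]
    sub = m.data.loc[:, keep_cols]
    usable = (sub.notna().sum(axis=1) >= 2) & (sub.std(axis=1, ddof=0) > 0)
    z = zscore_rows(sub.loc[usable])  # proteins × samples
    model = train_som(z.T, grid=grid, epochs=epochs, seed=seed)
    assign = model.assignments()
    dist = pd.Series(model.distances, index=model.item_ids)
    wt_units = set(assign[assign.index.isin(wt_samples)])
    ko_items = assign.index[~assign.map(lambda u: u in wt_units)]
    if len(ko_items) == 0:
        warnings.warn("all clusters contain wild-type samples", stacklevel=2)
        empty = ClusterSet({}, pd.Series(dtype=float), pd.Series(dtype=bool), np.nan)
        return empty, model
    threshold = float(np.percentile(dist[ko_items], percentile))
    members: dict[int, list[str]] = {}
    means: dict[int, float] = {}
    for unit, group in assign[ko_items].groupby(assign[ko_items]):
        members[int(unit)] = group.index.tolist()
        means[int(unit)] = float(dist[group.index].mean())
    mean_distance = pd.Series(means).sort_index()
    kept = mean_distance < threshold
    return ClusterSet(members, mean_distance, kept, threshold), model


# -- genetic-interaction benchmarking -----------------------------------------

def gi_profile_comparison(
    clusters: ClusterSet | dict[int, list[str]],
    profile_correlations: pd.DataFrame,
) -> tuple[float, float]:
    """Rank-sum test of within- vs between-cluster profile correlations.

    ``profile_correlations`` is a symmetric item × item correlation matrix
    (e.g. genetic-interaction profile correlations).  Returns the
    Mann-Whitney statistic and two-sided p-value.
    """
    members = clusters.kept_clusters if isinstance(clusters, ClusterSet) else clusters
    label = {i: c for c, mem in members.items() for i in mem}
    items = [i for i in profile_correlations.index if i in label]
    within, between = [], []
    for a, b in combinations(items, 2):
        r = profile_correlations.loc[a, b]
        if np.isnan(r):
            continue
        (within if label[a] == label[b] else between).append(r)
    if len(within) < 2 or len(between) < 2:
        raise ValidationError("need at least 2 pairs in each group")
    stat, p = stats.mannwhitneyu(within, between, alternative="two-sided",
                                 method="asymptotic")
    return float(stat), float(p)


# -- enrichment statistics -----------------------------------------------------

def hypergeom_enrichment(
    cluster_members: list[str],
    genesets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """One-sided (upper tail) hypergeometric enrichment per gene set, BH
    corrected across sets."""
    if len(universe) == 0:
        raise ValidationError("empty universe")
    uni = set(universe)
    clu = set(cluster_members) & uni
    rows = []
    for sid, members in sorted(genesets.items()):
        in_uni = members & uni
        k = len(clu & in_uni)
        p = stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(clu))
        rows.append(dict(set_id=sid, overlap=k, set_size=len(in_uni),
                         p=min(1.0, float(p))))
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _ks_enrichment_score(hit_positions: np.ndarray, n: int, n_hits: int) -> float:
    """Unweighted running-sum (KS-style) enrichment score from sorted hit
    positions in a ranking of length n."""
    inc = 1.0 / n_hits
    dec = 1.0 / (n - n_hits)
    running = 0.0
    best = 0.0
    prev = 0
    for pos in hit_positions:
        running -= dec * (pos - prev)      # misses before this hit
        if abs(running) > abs(best):
            best = running
        running += inc
        if abs(running) > abs(best):
            best = running
        prev = pos + 1
    running -= dec * (n - prev)
    if abs(running) > abs(best):
        best = running
    return best


def preranked_gsea(
    ranking: list[str],
    sets: GeneSetCollection | dict[str, frozenset[str]],
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Preranked enrichment of item sets along an ordered list.

    ``ranking`` is best-first (e.g. strains ordered by number of altered
    proteins).  The enrichment score is the extremum of the unweighted KS
    running sum.  p-values come from random placements of the hit set:
    (1 + #{perm ES ≥ observed}) / (n_perm + 1) for positive scores,
    mirrored for negative.  With ``exhaustive=True`` (small instances) all
    C(n, k) placements are enumerated and the p-value is the exact
    fraction of placements at least as extreme (the observed placement
    included).
    """
    if n_perm < 100 and not exhaustive:
        raise ValidationError("need n_perm >= 100")
    items = list(ranking)
    pos_of = {g: i for i, g in enumerate(items)}
    if len(pos_of) != len(items):
        raise ValidationError("ranking contains duplicates")
    n = len(items)
    rng = np.random.default_rng(seed)
    set_items = sets.items() if hasattr(sets, "items") else sets
    rows = []
    for sid, members in sorted(set_items):
        if len(members) > n:
            raise ValidationError(f"set {sid} is larger than the ranking")
        hits = sorted(pos_of[g] for g in members if g in pos_of)
        k = len(hits)
        if k == 0 or k >= n:
            raise ValidationError(f"set {sid}: needs 1..n-1 members in the ranking")
        es = _ks_enrichment_score(np.asarray(hits), n, k)
        if exhaustive:
            null = np.array([
                _ks_enrichment_score(np.asarray(c), n, k)
                for c in combinations(range(n), k)
            ])
            extreme = (null >= es) if es >= 0 else (null <= es)
            p = float(extreme.sum()) / len(null)
        else:
            null = np.array([
                _ks_enrichment_score(np.sort(rng.choice(n, k, replace=False)), n, k)
                for _ in range(n_perm)
            ])
            extreme = (null >= es) if es >= 0 else (null <= es)
            p = (1.0 + float(extreme.sum())) / (n_perm + 1.0)
        rows.append(dict(set_id=sid, n_hits=k, es=es, p=p))
    return pd.DataFrame(rows)
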