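"""Partitioning around medoids (PAM) with silhouette-based k selection.

Classic deterministic PAM: the BUILD phase greedily seeds k medoids, the
SWAP phase repeatedly applies the best (medoid, non-medoid) exchange until
no exchange lowers the total distance-to-medoid objective.  Swap gains are
evaluated for all candidates in O(n²) per sweep using the nearest /
second-nearest medoid decomposition.  No random restarts, so the selected
k is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .datamodel import ValidationError


@dataclass
class PAMResult:
    k: int
    medoids: np.ndarray            # indices into item order
    labels: pd.Series              # item → cluster number (0..k-1)
    silhouette: float
    silhouette_by_k: dict[int, float]
    objective: float


def _build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        d_near = np.minimum(d_near, D[:, best])
    return medoids


def _swap(D: np.ndarray, medoids: list[int], max_sweeps: int = 200) -> list[int]:
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_sweeps):
        Dm = D[:, medoids]                       # n × k
        order = np.argsort(Dm, axis=1)
        near = order[:, 0]                       # index into medoid list
        d1 = Dm[np.arange(n), near]
        d2 = Dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        best_delta, best_pair = -1e-12, None
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        for h in np.flatnonzero(~in_medoids):
            dh = D[:, h]
            g = np.minimum(dh - d1, 0.0)         # gain for points reassigned to h
            total_g = g.sum()
            g_by_m = np.bincount(near, weights=g, minlength=len(medoids))
            loss = np.minimum(dh, d2) - d1       # points losing their medoid
            loss_by_m = np.bincount(near, weights=loss, minlength=len(medoids))
            delta = total_g - g_by_m + loss_by_m  # per removed medoid i
            i = int(np.argmin(delta))
            if delta[i] < best_delta:
                best_delta, best_pair = float(delta[i]), (i, h)
        if best_pair is None:
            break
        i, h = best_pair
        medoids[i] = int(h)
    return medoids


def pam(D: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """Run PAM on a precomputed distance matrix; returns (medoids, labels,
    objective)."""
    medoids = _swap(D, _build(D, k))
    labels = np.argmin(D[:, medoids], axis=1)
    objective = float(D[np.arange(D.shape[0]), np.asarray(medoids)[labels]].sum())
    return medoids, labels, objective


def pam_cluster(
    data: pd.DataFrame,
    k_range: range | list[int] = range(2, 11),
    metric: str = "euclidean",
) -> PAMResult:
    """PAM over a k range; k chosen by maximal average silhouette width.

    ``data`` is items × features with no missing entries.  Ties in the
    silhouette break toward the smaller k.
    """
    if len(data) < 4:
        raise ValidationError("need at least 4 items to cluster")
    if data.isna().any().any():
        raise ValidationError("PAM input must be complete (no missing values)")
    X = data.to_numpy(dtype=float)
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X, metric=metric))
    sil_by_k: dict[int, float] = {}
    results: dict[int, tuple[list[int], np.ndarray, float]] = {}
    for k in k_range:
        if not 2 <= k <= len(data) - 1:
            continue
        medoids, labels, objective = pam(D, k)
        if len(np.unique(labels)) < 2:
            continue
        sil_by_k[k] = float(silhouette_score(D, labels, metric="precomputed"))
        results[k] = (medoids, labels, objective)
    if not sil_by_k:
        raise ValidationError("no valid k in range")
    best_k = max(sorted(sil_by_k), key=lambda k: sil_by_k[k])
    medoids, labels, objective = results[best_k]
    return PAMResult(
        k=best_k,
        medoids=np.asarray(medoids),
        labels=pd.Series(labels, index=data.index, name="cluster"),
        silhouette=sil_by_k[best_k],
        silhouette_by_k=sil_by_k,
        objective=objective,
    )
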