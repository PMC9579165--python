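"""Self-organizing map with missing-data support.

Online Kohonen training on a rectangular grid with a Gaussian
neighborhood; learning rate and radius decay linearly over epochs.
Distances are masked Euclidean, normalized by the number of observed
dimensions, so items with missing entries compete on their observed
coordinates only; codebook updates likewise touch observed dimensions
only.  Training is deterministic given the seed; best-matching-unit ties
break to the lowest unit index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray          # units × dims
    item_ids: list[str]
    bmu: np.ndarray               # item → unit index
    distances: np.ndarray         # item → masked distance to its BMU codebook
    seed: int
    epochs: int

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def assignments(self) -> pd.Series:
        return pd.Series(self.bmu, index=self.item_ids, name="unit")


def _masked_distance(codebook: np.ndarray, x: np.ndarray, obs: np.ndarray) -> np.ndarray:
    diff = codebook[:, obs] - x[obs]
    return np.sqrt((diff * diff).mean(axis=1))


def train_som(
    items: pd.DataFrame,
    grid: tuple[int, int] = (12, 12),
    epochs: int = 500,
    seed: int = 0,
    learning_rate: tuple[float, float] = (0.5, 0.01),
    radius: tuple[float, float] | None = None,
) -> SOMModel:
    """Train a SOM on an items × dimensions matrix (NaN = missing).

    The codebook is initialized from randomly drawn items (missing entries
    replaced by column means).  Items with no observed dimension are
    rejected.
    """
    if len(items) == 0:
        raise ValidationError("empty input")
    rows, cols = grid
    n_units = rows * cols
    if n_units > len(items):
        raise ValidationError("grid has more units than items")
    X = items.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (~obs.any(axis=1)).any():
        bad = items.index[~obs.any(axis=1)].tolist()
        raise ValidationError(f"items with no observed dimensions: {bad[:5]}")

    rng = np.random.default_rng(seed)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(obs, X, col_mean[None, :])
    init_idx = rng.choice(len(items), size=n_units, replace=n_units > len(items))
    codebook = filled[init_idx].copy() + rng.normal(0, 1e-4, (n_units, X.shape[1]))

    unit_rc = np.array([(u // cols, u % cols) for u in range(n_units)], dtype=float)
    grid_d2 = ((unit_rc[:, None, :] - unit_rc[None, :, :]) ** 2).sum(-1)

    lr0, lr1 = learning_rate
    if radius is None:
        radius = (max(rows, cols) / 2.0, 0.5)
    r0, r1 = radius

    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        rad = r0 + (r1 - r0) * frac
        h_all = np.exp(-grid_d2 / (2.0 * rad * rad))
        for i in rng.permutation(len(items)):
            x, o = X[i], obs[i]
            d = _masked_distance(codebook, x, o)
            bmu = int(np.argmin(d))
            w = lr * h_all[bmu]
            codebook[:, o] += w[:, None] * (x[o] - codebook[:, o])

    bmu = np.empty(len(items), dtype=int)
    dist = np.empty(len(items))
    for i in range(len(items)):
        d = _masked_distance(codebook, X[i], obs[i])
        bmu[i] = int(np.argmin(d))
        dist[i] = d[bmu[i]]
    return SOMModel(grid=grid, codebook=codebook, item_ids=list(items.index),
                    bmu=bmu, distances=dist, seed=seed, epochs=epochs)
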