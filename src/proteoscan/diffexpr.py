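"""Differential expression against a wild-type reference distribution.

The screen has no per-strain replicates, so instead of a t-test each
knockout measurement is compared to the empirical distribution of the
biological wild-type replicates pooled across all runs: per protein a
reference mean μ and SD σ are estimated, each knockout intensity x yields
z = (x − μ)/σ and a two-sided normal p-value, and Benjamini–Hochberg
correction is applied per strain.  Proteins with FDR q < 0.05 in a strain
are called altered.

For datasets with replicates (the paired-omics follow-up) a standard
two-sided Student t-test is used with the |log2FC| > 0.2 and p < 0.03
calling rule, and a Bayesian-PCA-style EM imputation fills the fourth
replicate when exactly three of four are observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import IntensityMatrix, SampleManifest, ValidationError


@dataclass
class WTReference:
    """Per-protein wild-type mean/SD estimated from biological replicates."""

    table: pd.DataFrame  # index protein; mean, sd, n, testable, degenerate
    min_n: int

    @property
    def testable_proteins(self) -> list[str]:
        return self.table.index[self.table["testable"]].tolist()


@dataclass
class DEResult:
    """Long-format per-(protein, strain) differential expression calls."""

    table: pd.DataFrame  # protein_id, strain_id, sample_id, log2fc, z, p, q, altered
    alpha: float = 0.05

    def altered_counts(self) -> pd.Series:
        return (
            self.table.groupby("strain_id")["altered"].sum().astype(int)
        )


@dataclass
class StrainSummary:
    table: pd.DataFrame  # index strain; n_altered, n_quantified, low_coverage
    coverage_threshold: int = 1250


def build_wt_reference(
    m: IntensityMatrix, manifest: SampleManifest, min_n: int = 10
) -> WTReference:
    """Estimate μ, σ (sample SD, n−1) per protein over observed WT values.

    Proteins observed in fewer than ``min_n`` wild-type biological samples
    are untestable; proteins with zero variance are flagged degenerate.
    """
    wt = manifest.samples_of_type("wt_biological")
    wt = [s for s in wt if s in m.data.columns]
    if not wt:
        raise ValidationError("no wild-type biological samples in matrix")
    sub = m.data.loc[:, wt]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    degenerate = (n >= 2) & (sd == 0.0)
    testable = (n >= min_n) & sd.gt(0).fillna(False)
    table = pd.DataFrame(dict(mean=mean, sd=sd, n=n,
                              testable=testable, degenerate=degenerate))
    return WTReference(table=table, min_n=min_n)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ztest_de(
    m: IntensityMatrix,
    manifest: SampleManifest,
    ref: WTReference,
    alpha: float = 0.05,
) -> DEResult:
    """Two-sided z-test of every knockout sample against the WT reference.

    BH correction is applied per strain across that strain's tested
    proteins.  Degenerate (σ = 0) proteins are skipped with a warning.
    """
    ko = manifest.frame[manifest.frame["sample_type"] == "knockout"]
    ko = ko[ko["sample_id"].isin(m.data.columns)]
    tab = ref.table
    if bool(tab["degenerate"].any()):
        n_deg = int(tab["degenerate"].sum())
        warnings.warn(f"skipping {n_deg} zero-variance proteins", stacklevel=2)
    use = tab.index[tab["testable"]]
    mu = tab.loc[use, "mean"].to_numpy()
    sd = tab.loc[use, "sd"].to_numpy()

    frames = []
    for row in ko.itertuples(index=False):
        x = m.data.loc[use, row.sample_id].to_numpy()
        ok = ~np.isnan(x)
        if not ok.any():
            continue
        z = (x[ok] - mu[ok]) / sd[ok]
        p = 2.0 * stats.norm.sf(np.abs(z))
        q = bh_fdr(p)
        frames.append(pd.DataFrame(dict(
            protein_id=np.asarray(use)[ok],
            strain_id=row.strain_id,
            sample_id=row.sample_id,
            log2fc=x[ok] - mu[ok],
            z=z, p=p, q=q, altered=q < alpha,
        )))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["protein_id", "strain_id", "sample_id",
                                        "log2fc", "z", "p", "q", "altered"]))
    return DEResult(table=table, alpha=alpha)


def ttest_de(
    group: pd.DataFrame,
    reference: pd.DataFrame,
    fc_threshold: float = 0.2,
    p_threshold: float = 0.03,
) -> pd.DataFrame:
    """Replicate-mode differential expression (two-sided Student t).

    ``group`` and ``reference`` are proteins × replicates log2 matrices
    sharing an index.  Altered ⇔ |log2FC| > ``fc_threshold`` and
    p < ``p_threshold``.
    """
    if group.shape[1] < 2 or reference.shape[1] < 2:
        raise ValidationError("need at least 2 replicates per group")
    idx = group.index.intersection(reference.index)
    a = group.loc[idx].to_numpy(dtype=float)
    b = reference.loc[idx].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
    log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    out = pd.DataFrame(dict(log2fc=log2fc, t=t, p=p), index=idx)
    out["altered"] = (np.abs(out["log2fc"]) > fc_threshold) & (out["p"] < p_threshold)
    return out


# -- imputation ---------------------------------------------------------------

def _gavish_donoho_rank(s: np.ndarray, shape: tuple[int, int]) -> int:
    """Automatic rank: keep singular values above the optimal hard
    threshold for white noise (ω(β)·median singular value)."""
    n, d = max(shape), min(shape)
    beta = d / n
    omega = 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43
    tau = omega * np.median(s)
    keep = (s > tau) & (s > s[0] * 1e-8)  # numerical floor for clean low-rank data
    return max(1, int(keep.sum()))


def em_pca_impute(
    X: np.ndarray, max_iter: int = 1000, tol: float = 1e-9
) -> np.ndarray:
    """EM over a low-rank (probabilistic PCA) model for missing entries.

    Missing cells are initialized at column means and refined by iterating
    SVD reconstruction; the retained dimensionality shrinks automatically
    to the components above the noise floor.  Observed cells are never
    modified.  Returns a filled copy.
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    if obs.all():
        return X.copy()
    col_mean = np.nanmean(np.where(obs, X, np.nan), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(obs, X, col_mean[None, :])
    # dimensionality from the uncorrupted (complete) rows, fixed through EM
    complete = obs.all(axis=1)
    if complete.sum() >= X.shape[1]:
        sub = X[complete]
        s_c = np.linalg.svd(sub - sub.mean(axis=0), compute_uv=False)
        q = min(_gavish_donoho_rank(s_c, sub.shape), X.shape[1] - 1)
    else:
        q = 1
    prev = filled[~obs].copy()
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        U, s, Vt = np.linalg.svd(filled - mu, full_matrices=False)
        recon = (U[:, :q] * s[:q]) @ Vt[:q] + mu
        filled[~obs] = recon[~obs]
        delta = np.max(np.abs(filled[~obs] - prev)) if prev.size else 0.0
        if delta < tol:
            break
        prev = filled[~obs].copy()
    return filled


def bpca_impute(replicates: pd.DataFrame) -> pd.DataFrame:
    """Fill the missing replicate when exactly one of the set is absent.

    Rows (proteins) with exactly ``n_replicates − 1`` observed values get
    their single missing cell reconstructed from the low-rank structure of
    the replicate matrix; rows with more missing values are left missing,
    and observed values are returned unchanged.
    """
    X = replicates.to_numpy(dtype=float)
    n_rep = X.shape[1]
    n_obs = (~np.isnan(X)).sum(axis=1)
    eligible = n_obs == n_rep - 1
    if not eligible.any():
        return replicates.copy()
    fit_rows = n_obs >= n_rep - 1  # complete rows anchor the model
    filled = em_pca_impute(X[fit_rows])
    out = X.copy()
    rows = np.flatnonzero(fit_rows)
    sub = np.isin(rows, np.flatnonzero(eligible))
    out[rows[sub]] = filled[sub]
    return pd.DataFrame(out, index=replicates.index, columns=replicates.columns)


# -- labeling QC --------------------------------------------------------------

_OVERLABEL_RESIDUES = frozenset("HSTY")


def labeling_qc(evidence: pd.DataFrame) -> tuple[float, float]:
    """Percentage of under- and over-labeled evidence records.

    ``evidence`` needs a ``tmt_sites`` column: a comma-separated list of
    labeled positions per record using ``N-term``, ``K``, ``H``, ``S``,
    ``T``, ``Y`` (empty/NaN = unlabeled).  Rows flagged in an optional
    ``contaminant`` column are excluded first.  Under-labeling is the
    percentage of records carrying no label at all; over-labeling the
    percentage carrying a label on H, S, T or Y.
    """
    df = evidence
    if "contaminant" in df.columns:
        df = df[~df["contaminant"].astype(bool)]
    if len(df) == 0:
        raise ValidationError("no evidence records")
    sites = df["tmt_sites"].fillna("").astype(str)
    tokens = sites.str.split(",").map(
        lambda xs: [t.strip() for t in xs if t.strip()]
    )
    unlabeled = tokens.map(len) == 0
    over = tokens.map(lambda xs: any(t in _OVERLABEL_RESIDUES for t in xs))
    n = len(df)
    return 100.0 * unlabeled.sum() / n, 100.0 * over.sum() / n


def summarize_strains(
    de: DEResult, m: IntensityMatrix, manifest: SampleManifest,
    coverage_threshold: int = 1250,
) -> StrainSummary:
    """Per-strain altered and quantified protein counts.

    Strains quantifying fewer than ``coverage_threshold`` proteins are
    flagged low-coverage (such samples were re-measured in the screen).
    """
    ko = manifest.frame[manifest.frame["sample_type"] == "knockout"]
    ko = ko[ko["sample_id"].isin(m.data.columns)]
    quantified = {
        row.strain_id: int(m.data[row.sample_id].notna().sum())
        for row in ko.itertuples(index=False)
    }
    altered = de.altered_counts()
    table = pd.DataFrame(dict(
        n_quantified=pd.Series(quantified),
        n_altered=altered.reindex(quantified.keys()).fillna(0).astype(int),
    ))
    table["low_coverage"] = table["n_quantified"] < coverage_threshold
    table.index.name = "strain_id"
    return StrainSummary(table=table, coverage_threshold=coverage_threshold)
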