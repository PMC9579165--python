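"""Paired transcriptome–proteome comparison.

From matched replicate matrices (log2 CPM and log2 protein intensity,
typically quadruplicates per strain plus wild-type replicates) this module
computes per-(gene, strain) fold changes against wild-type with
significance flags on each layer, then three correlation views:

* strain-pair similarity — how alike two knockouts are on the
  transcriptome versus on the proteome, and the meta-correlation between
  the two pairwise-similarity vectors over all ordered strain pairs;
* per-strain correlation — transcript FC vs protein FC across genes, low
  values flag strains with post-transcriptional effects;
* per-gene correlation — transcript FC vs protein FC across strains, with
  a t-based two-sided p-value, separating transcriptionally coupled genes
  from post-transcriptionally regulated ones.

Genes changing at the protein level while their mRNA is stable (measured
on both layers, flagged on the protein layer only) are counted per strain,
ranked, and the top half clustered with PAM to expose the regulation
archetypes (generally-up vs generally-down).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import IntensityMatrix, TranscriptMatrix, ValidationError
from .diffexpr import ttest_de
from .pam import PAMResult, pam_cluster

TRANSCRIPT_FC_MIN = 0.6
TRANSCRIPT_P_MAX = 0.005
PROTEIN_FC_MIN = 0.2
PROTEIN_P_MAX = 0.03


@dataclass
class FoldChangeTable:
    """Wide per-layer fold changes and significance flags (genes × strains)."""

    transcript_fc: pd.DataFrame
    transcript_p: pd.DataFrame
    protein_fc: pd.DataFrame
    protein_p: pd.DataFrame
    transcript_sig: pd.DataFrame
    protein_sig: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return self.transcript_fc.columns.tolist()

    def both_measured(self) -> pd.DataFrame:
        return self.transcript_fc.notna() & self.protein_fc.notna()


def _layer_foldchanges(
    matrix: pd.DataFrame,
    sample_to_strain: pd.DataFrame,
    wt_strain: str,
    fc_min: float,
    p_max: float,
    strict_fc: bool,
    strict_p: bool,
):
    s2s = sample_to_strain.set_index("sample_id")["strain_id"]
    s2s = s2s[s2s.index.isin(matrix.columns)]
    if wt_strain not in set(s2s):
        raise ValidationError(f"wild-type strain {wt_strain!r} not in samples")
    wt_cols = s2s.index[s2s == wt_strain].tolist()
    wt = matrix.loc[:, wt_cols]
    fcs, ps = {}, {}
    for strain in s2s[s2s != wt_strain].drop_duplicates():
        cols = s2s.index[s2s == strain].tolist()
        res = ttest_de(matrix.loc[:, cols], wt)
        fcs[strain] = res["log2fc"]
        ps[strain] = res["p"]
    fc = pd.DataFrame(fcs)
    p = pd.DataFrame(ps)
    abs_ok = np.abs(fc) > fc_min if strict_fc else np.abs(fc) >= fc_min
    p_ok = p < p_max if strict_p else p <= p_max
    sig = (abs_ok & p_ok).fillna(False)
    return fc, p, sig


def build_foldchanges(
    txome: TranscriptMatrix,
    proteome: IntensityMatrix,
    sample_to_strain: pd.DataFrame,
    wt_strain: str = "WT",
) -> FoldChangeTable:
    """Per-(gene, strain) log2 fold changes vs the wild-type mean.

    Both layers use a two-sided Student t-test over replicates.  The
    transcript flag requires |log2FC| ≥ 0.6 and p ≤ 0.005; the protein
    flag |log2FC| > 0.2 and p < 0.03.
    """
    prot = proteome.to_log2() if proteome.scale == "raw" else proteome
    t_fc, t_p, t_sig = _layer_foldchanges(
        txome.data, sample_to_strain, wt_strain,
        TRANSCRIPT_FC_MIN, TRANSCRIPT_P_MAX, strict_fc=False, strict_p=False)
    p_fc, p_p, p_sig = _layer_foldchanges(
        prot.data, sample_to_strain, wt_strain,
        PROTEIN_FC_MIN, PROTEIN_P_MAX, strict_fc=True, strict_p=True)
    strains = [s for s in t_fc.columns if s in p_fc.columns]
    genes_t, genes_p = t_fc.index, p_fc.index
    return FoldChangeTable(
        transcript_fc=t_fc.loc[:, strains], transcript_p=t_p.loc[:, strains],
        protein_fc=p_fc.loc[:, strains], protein_p=p_p.loc[:, strains],
        transcript_sig=t_sig.loc[:, strains], protein_sig=p_sig.loc[:, strains],
    )


# -- correlation measures -----------------------------------------------------

def _pairwise_complete_r(x: np.ndarray, y: np.ndarray, min_n: int = 3):
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < min_n:
        return np.nan, n
    xo, yo = x[ok], y[ok]
    if np.std(xo) == 0 or np.std(yo) == 0:
        return np.nan, n
    return float(np.corrcoef(xo, yo)[0, 1]), n


@dataclass
class StrainPairSimilarity:
    pairs: pd.DataFrame       # strain_a, strain_b, r_transcriptome, r_proteome
    meta_correlation: float   # Pearson between the two pair-R vectors
    n_pairs: int


def strain_pair_similarity(fc: FoldChangeTable) -> StrainPairSimilarity:
    """Similarity of strain pairs on each layer, over all ordered pairs.

    For every ordered pair (i, j), i ≠ j, the Pearson correlation between
    the two strains' fold-change vectors is computed per layer
    (pairwise-complete genes, ≥3 shared); the meta-correlation compares
    the transcriptome-similarity vector with the proteome one.
    """
    strains = fc.strains
    if len(strains) < 2:
        raise ValidationError("need at least 2 strains")
    tm = fc.transcript_fc.to_numpy(dtype=float)
    pm = fc.protein_fc.to_numpy(dtype=float)
    rows = []
    for i, a in enumerate(strains):
        for j, b in enumerate(strains):
            if i == j:
                continue
            rt, _ = _pairwise_complete_r(tm[:, i], tm[:, j])
            rp, _ = _pairwise_complete_r(pm[:, i], pm[:, j])
            rows.append((a, b, rt, rp))
    pairs = pd.DataFrame(rows, columns=["strain_a", "strain_b",
                                        "r_transcriptome", "r_proteome"])
    both = pairs.dropna(subset=["r_transcriptome", "r_proteome"])
    meta, _ = _pairwise_complete_r(both["r_transcriptome"].to_numpy(),
                                   both["r_proteome"].to_numpy())
    return StrainPairSimilarity(pairs=pairs, meta_correlation=meta,
                                n_pairs=len(pairs))


def per_strain_corr(fc: FoldChangeTable) -> pd.DataFrame:
    """Transcript-vs-protein fold-change correlation within each strain."""
    rows = []
    for s in fc.strains:
        r, n = _pairwise_complete_r(fc.transcript_fc[s].to_numpy(),
                                    fc.protein_fc[s].to_numpy())
        rows.append(dict(strain_id=s, r=r, n=n))
    return pd.DataFrame(rows).set_index("strain_id")


def per_gene_corr(fc: FoldChangeTable) -> pd.DataFrame:
    """Transcript-vs-protein fold-change correlation per gene across strains.

    Two-sided p from t = R·√(n−2)/√(1−R²) with n−2 degrees of freedom.
    """
    genes = fc.transcript_fc.index.intersection(fc.protein_fc.index)
    rows = []
    for g in genes:
        r, n = _pairwise_complete_r(fc.transcript_fc.loc[g].to_numpy(),
                                    fc.protein_fc.loc[g].to_numpy())
        if np.isnan(r) or n < 3:
            rows.append(dict(gene_id=g, r=r, n=n, p=np.nan))
            continue
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows.append(dict(gene_id=g, r=r, n=n, p=float(p)))
    return pd.DataFrame(rows).set_index("gene_id")


# -- protein-only regulation and archetype clustering -------------------------

def select_protein_only(fc: FoldChangeTable) -> tuple[list[str], pd.Series]:
    """Genes changing at the protein level under stable mRNA, ranked.

    Per gene, count strains where the protein flag is set, the transcript
    flag is not, and both layers are measured.  Among genes with a nonzero
    count, keep the top half (ceil; ties broken by gene id).  Returns the
    kept gene list and the full per-gene counts.
    """
    both = fc.both_measured()
    mask = fc.protein_sig & ~fc.transcript_sig & both
    counts = mask.sum(axis=1).astype(int)
    counts.name = "n_protein_only_strains"
    candidates = counts[counts > 0]
    # stable sort: count descending, ties broken by gene id ascending
    order = candidates.sort_index().sort_values(ascending=False, kind="mergesort")
    keep = order.index[: ceil(len(order) / 2)].tolist()
    return keep, counts


def cluster_protein_only(
    fc: FoldChangeTable,
    genes: list[str],
    k_range: range | list[int] = range(2, 11),
) -> tuple[PAMResult, pd.DataFrame]:
    """PAM clustering of the selected genes' protein fold changes.

    Restricted to strains with complete protein fold changes over the
    selected genes (Euclidean distance needs complete rows); k chosen by
    average silhouette width.
    """
    sub = fc.protein_fc.loc[genes]
    complete_strains = sub.columns[sub.notna().all(axis=0)]
    sub = sub.loc[:, complete_strains]
    result = pam_cluster(sub, k_range=k_range)
    return result, sub
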