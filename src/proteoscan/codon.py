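"""Codon-usage and codon-optimality analysis.

For genes regulated only at the protein level, the per-gene usage
percentage of each of the 64 codons is computed from the coding sequence;
fold-changes in mean usage between the generally-upregulated and
generally-downregulated groups reveal whether translational upregulation
preferentially uses optimal codons (those decoded by abundant tRNAs).
Group usage is the mean of per-gene percentages, weighting genes equally.
A square-root-transformed Student t-test evaluates the matched
fluorescent-reporter comparison between codon-optimized and non-optimized
constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ALL_CODONS, CodonTable, ORFSet, ValidationError
from .paired import FoldChangeTable


def codon_usage(orfs: ORFSet) -> pd.DataFrame:
    """Per-gene usage percentage of each codon (rows sum to 100)."""
    if len(orfs) == 0:
        raise ValidationError("empty ORF set")
    col_of = {c: i for i, c in enumerate(ALL_CODONS)}
    genes = sorted(orfs.sequences)
    counts = np.zeros((len(genes), 64))
    for gi, gene in enumerate(genes):
        seq = orfs[gene]
        for i in range(0, len(seq), 3):
            counts[gi, col_of[seq[i:i + 3]]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    pct = 100.0 * counts / totals
    return pd.DataFrame(pct, index=genes, columns=list(ALL_CODONS))


def group_foldchange(
    profiles: pd.DataFrame,
    up_genes: list[str],
    down_genes: list[str],
    codon_table: CodonTable | None = None,
) -> pd.DataFrame:
    """Per-codon log2 ratio of mean usage (up group / down group).

    Means are taken over per-gene percentages within each group.  Codons
    with zero mean usage in either group yield a missing ratio rather than
    an infinity.
    """
    up = [g for g in up_genes if g in profiles.index]
    down = [g for g in down_genes if g in profiles.index]
    if not up or not down:
        raise ValidationError("both groups must be non-empty")
    mean_up = profiles.loc[up].mean(axis=0)
    mean_down = profiles.loc[down].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_up / mean_down)
    log2fc = log2fc.where((mean_up > 0) & (mean_down > 0))
    out = pd.DataFrame(dict(mean_up=mean_up, mean_down=mean_down,
                            log2_ratio=log2fc))
    if codon_table is not None:
        out["optimal"] = codon_table.optimal
    out.index.name = "codon"
    return out


def per_strain_codon_matrix(
    fc: FoldChangeTable,
    profiles: pd.DataFrame,
    codon_table: CodonTable,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Strains × 64 codon log2 up/down usage ratios.

    Per strain, the up (down) group holds genes with a positive (negative)
    protein fold change that is protein-flagged, not transcript-flagged,
    and measured on both layers; strains with an empty group give a
    missing row.
    """
    if genes is None:
        genes = [g for g in profiles.index if g in fc.protein_fc.index]
    both = fc.both_measured()
    protein_only = fc.protein_sig & ~fc.transcript_sig & both
    rows = {}
    for strain in fc.strains:
        mask = protein_only[strain]
        sel = [g for g in genes if g in mask.index and bool(mask[g])]
        up = [g for g in sel if fc.protein_fc.loc[g, strain] > 0]
        down = [g for g in sel if fc.protein_fc.loc[g, strain] < 0]
        if not up or not down:
            rows[strain] = pd.Series(np.nan, index=list(ALL_CODONS))
            continue
        rows[strain] = group_foldchange(profiles, up, down)["log2_ratio"]
    out = pd.DataFrame(rows).T
    out = out.loc[:, list(ALL_CODONS)]
    out.index.name = "strain_id"
    return out


@dataclass
class ReporterTestResult:
    fold_change: float  # ratio of arm means, original scale
    t: float
    p: float
    df: int


def reporter_test(
    intensities_optimized,
    intensities_nonoptimized,
) -> ReporterTestResult:
    """Compare reporter fluorescence between codon-optimized and
    non-optimized constructs.

    Intensities are square-root transformed (variance stabilization toward
    normality) before a two-sided Student t-test on the means; the fold
    change is reported as the ratio of arm means on the original scale.
    """
    a = np.asarray(intensities_optimized, dtype=float)
    b = np.asarray(intensities_nonoptimized, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 measurements per arm")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("intensities must be non-negative")
    t, p = stats.ttest_ind(np.sqrt(a), np.sqrt(b), equal_var=True)
    return ReporterTestResult(
        fold_change=float(a.mean() / b.mean()),
        t=float(t), p=float(p), df=len(a) + len(b) - 2,
    )
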