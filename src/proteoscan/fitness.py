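"""Growth fitness versus extent of proteome remodeling.

Growth (OD600) is standardized within each 96-well plate; strains are
ranked by their number of altered proteins and divided into consecutive
bins of 100 (remainder merged into the last bin), and the most-remodeled
bin is compared with all remaining strains by a Kruskal–Wallis rank test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GrowthTable, ValidationError


def growth_zscore(growth: GrowthTable) -> GrowthTable:
    """Plate-wise z-score of OD600 (sample SD, n−1 denominator).

    Plates with zero SD get missing z-scores with a warning.
    """
    df = growth.frame.copy()
    sizes = df.groupby("plate_id")["od600"].size()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValidationError(f"plates with fewer than 2 wells: {small}")
    mean = df.groupby("plate_id")["od600"].transform("mean")
    sd = df.groupby("plate_id")["od600"].transform(lambda x: x.std(ddof=1))
    z = (df["od600"] - mean) / sd.replace(0.0, np.nan)
    degenerate = sd == 0.0
    if degenerate.any():
        plates = df.loc[degenerate, "plate_id"].unique().tolist()
        warnings.warn(f"plates with zero OD600 variance: {plates}", stacklevel=2)
    df["growth_z"] = z
    return GrowthTable(df)


def bin_by_altered(altered_counts: pd.Series, bin_size: int = 100) -> pd.Series:
    """Partition strains into consecutive bins by altered-protein count.

    Strains are ranked by count descending (ties broken by strain id
    ascending); bin 1 holds the ``bin_size`` most-remodeled strains, and
    the final remainder (fewer than ``bin_size`` strains) is merged into
    the last bin, so 3308 strains at bin size 100 give 33 bins with the
    last holding 108.
    """
    order = altered_counts.sort_index().sort_values(ascending=False,
                                                    kind="mergesort")
    n = len(order)
    n_bins = max(1, n // bin_size)
    bins = np.minimum(np.arange(n) // bin_size, n_bins - 1) + 1
    return pd.Series(bins, index=order.index, name="bin")


def first_bin_growth_test(
    bins: pd.Series,
    growth: GrowthTable,
    all_bins: bool = False,
) -> tuple[float, float]:
    """Kruskal–Wallis test of growth in the most-remodeled bin vs the rest.

    Uses plate-wise growth z-scores (tie-corrected ranks, chi-square
    p-value).  With ``all_bins=True`` the test compares all bins jointly
    instead of bin 1 versus the pooled remainder.
    """
    df = growth.frame
    col = "growth_z" if "growth_z" in df.columns else "od600"
    values = df.set_index("strain_id")[col].reindex(bins.index)
    ok = values.notna()
    values, b = values[ok], bins[ok]
    if all_bins:
        groups = [values[b == i].to_numpy() for i in sorted(b.unique())]
    else:
        groups = [values[b == 1].to_numpy(), values[b != 1].to_numpy()]
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each compared group needs at least 2 strains")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
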