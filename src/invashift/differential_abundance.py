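"""Per-feature between-group tests on compositional microbiome data.

Two complementary routes: one-way ANOVA on centered log-ratio (CLR)
transformed counts, and Kruskal-Wallis on relative abundances with
Benjamini-Hochberg FDR correction across the features of one rank.  Both raw
and FDR-adjusted significance flags are always emitted because summary
percentages are sometimes quoted on raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .tables_io import CountTable, RelativeAbundanceTable, SampleMetadata

__all__ = [
    "clr_transform",
    "anova_per_feature",
    "kruskal_per_feature",
    "significance_summary",
]


def clr_transform(table: CountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform, row-wise: ``ln((x + c) / g)``.

    ``g`` is the geometric mean of the pseudocounted row, so every output row
    sums to zero.  The pseudocount (default 0.5) handles zeros.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = table.counts.astype(float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.feature_ids)


def _group_values(values: pd.DataFrame, meta: SampleMetadata, factor: str):
    labels = meta.group_labels(factor, list(values.index))
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    counts = labels.value_counts()
    small = [lv for lv in levels if counts[lv] < 2]
    if small:
        raise ValueError(f"levels with < 2 samples: {small}")
    masks = {lv: (labels == lv).to_numpy() for lv in levels}
    return levels, masks


def anova_per_feature(
    clr: pd.DataFrame, meta: SampleMetadata, factor: str, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA per feature on CLR values.

    Features with zero variance everywhere are degenerate: flagged, p = 1 by
    convention.  BH adjustment is applied across all tested features.
    """
    levels, masks = _group_values(clr, meta, factor)
    rows = []
    mat = clr.to_numpy()
    for j, fid in enumerate(clr.columns):
        groups = [mat[m, j] for m in masks.values()]
        pooled = mat[:, j]
        if np.allclose(pooled, pooled[0]):
            rows.append((fid, np.nan, 1.0, True))
            continue
        stat, p = scipy.stats.f_oneway(*groups)
        rows.append((fid, float(stat), float(p), False))
    out = pd.DataFrame(rows, columns=["feature_id", "statistic", "p", "degenerate"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["sig_raw"] = out["p"] < alpha
    out["sig_fdr"] = out["q"] < alpha
    for lv in levels:
        out[f"mean_{lv}"] = [clr.loc[masks[lv], fid].mean() for fid in out["feature_id"]]
    return out


def kruskal_per_feature(
    table: RelativeAbundanceTable,
    meta: SampleMetadata,
    factor: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis H (tie-corrected) per feature on relative abundances.

    BH adjustment runs across all features of the table (one rank = one
    correction family).
    """
    df = table.data
    levels, masks = _group_values(df, meta, factor)
    rows = []
    mat = df.to_numpy(dtype=float)
    for j, fid in enumerate(df.columns):
        pooled = mat[:, j]
        if np.allclose(pooled, pooled[0]):
            rows.append((fid, np.nan, 1.0, True))
            continue
        groups = [mat[m, j] for m in masks.values()]
        stat, p = scipy.stats.kruskal(*groups)
        rows.append((fid, float(stat), float(p), False))
    out = pd.DataFrame(rows, columns=["feature_id", "statistic", "p", "degenerate"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["sig_raw"] = out["p"] < alpha
    out["sig_fdr"] = out["q"] < alpha
    for lv in levels:
        out[f"mean_{lv}"] = mat[masks[lv]].mean(axis=0)
    return out


def significance_summary(
    results_per_rank: dict[str, pd.DataFrame], flag: str = "sig_raw"
) -> pd.DataFrame:
    """Counts and fractions of significant features per taxonomic rank."""
    if flag not in ("sig_raw", "sig_fdr"):
        raise ValueError("flag must be sig_raw or sig_fdr")
    rows = []
    for rank, res in results_per_rank.items():
        n_sig = int(res[flag].sum())
        n_tot = len(res)
        rows.append((rank, n_sig, n_tot, n_sig / n_tot if n_tot else np.nan))
    return pd.DataFrame(rows, columns=["rank", "n_significant", "n_tested", "fraction"])
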