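"""Cross-site and cross-sublineage comparison statistics.

Covers standardized transcript levels (median of within-sample z-scores),
detection overlap, Welch and one-tailed t-tests, Fisher's exact test of
diel status by habitat, rank/linear correlations, the pathway quantile
heat-map matrix that lets array intensities and sequencing counts share
one color scale, and circular peak-shift tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import label_cycle_hour

__all__ = [
    "standardized_level",
    "detection_overlap",
    "welch_test",
    "paired_unpaired_ttests",
    "fisher_habitat_test",
    "correlations",
    "pathway_correlations",
    "pathway_matrix",
    "peak_shift_table",
]


def standardized_level(expr: pd.DataFrame) -> pd.Series:
    """Median across samples of each gene's within-sample z-score.

    z-scores are taken across genes within each sample (ddof=1), so the
    result is translation-invariant per sample and comparable across
    separately normalized sites.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes per sample to standardize")
    z = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    return z.median(axis=1).rename("standardized_level")


def detection_overlap(detected_a, detected_b
                      ) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Partition two detected-gene sets into (both, only_a, only_b)."""
    a, b = pd.Index(detected_a), pd.Index(detected_b)
    return a.intersection(b), a.difference(b), b.difference(a)


def welch_test(group1, group2, alternative: str = "two-sided"
               ) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns (t, Satterthwaite df, p)."""
    a, b = np.asarray(group1, float), np.asarray(group2, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_unpaired_ttests(counts_a, counts_b, paired: bool,
                           alternative: str = "greater"
                           ) -> tuple[float, float]:
    """One-sided t-test that group A exceeds group B.

    Paired: one-sample t on the aligned differences; unpaired: Welch.
    """
    a, b = np.asarray(counts_a, float), np.asarray(counts_b, float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs aligned, equal-length groups")
        d = a - b
        if np.std(d, ddof=1) == 0:
            raise ValueError("degenerate paired test: differences are constant")
        res = stats.ttest_1samp(d, 0.0, alternative=alternative)
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def fisher_habitat_test(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Uses the probability-mass rule: the p-value sums all tables with the
    observed margins whose probability does not exceed the observed
    table's.  Returns (odds ratio, p).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def correlations(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 points")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def pathway_correlations(levels_a: pd.Series, levels_b: pd.Series,
                         pathway_map: pd.Series, min_genes: int = 5,
                         ) -> pd.DataFrame:
    """Per-pathway Pearson correlation of cross-site gene levels.

    Pathways with fewer than ``min_genes`` genes present at both sites
    are skipped; significance is flagged at p < 0.05.
    """
    shared = levels_a.index.intersection(levels_b.index)
    rows = []
    for pw, genes in pathway_map.loc[pathway_map.index.intersection(shared)] \
                                .groupby(pathway_map).groups.items():
        genes = pd.Index(genes).intersection(shared)
        if len(genes) < min_genes:
            continue
        rho, p = correlations(levels_a[genes], levels_b[genes], "pearson")
        rows.append({"pathway": pw, "n_genes": len(genes), "rho": rho,
                     "p_value": p, "significant": p < 0.05})
    return pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame(
        columns=["n_genes", "rho", "p_value", "significant"])


def _quantile_5pct(values: pd.Series) -> pd.Series:
    """Empirical quantile (rank-1)/(n-1), mean ranks for ties, 5% grid."""
    n = values.size
    if n == 1:
        return pd.Series([0.5], index=values.index)
    q = (values.rank(method="average") - 1) / (n - 1)
    return (q * 20).round() / 20


def pathway_matrix(columns: dict[str, tuple[pd.DataFrame, pd.DataFrame, pd.Series]],
                   min_detected_fraction: float = 1 / 3,
                   ) -> tuple[pd.DataFrame, list[str] | None]:
    """Pathway x (site, sublineage) quantile matrix for heat-map display.

    ``columns`` maps a column name to (levels, detected_flags, pathway_map)
    where ``levels`` is genes x samples (intensity or read count — any
    monotone scale), ``detected_flags`` genes x samples booleans, and
    ``pathway_map`` gene -> pathway.  Per column: a pathway's level is the
    median level of its detected genes over samples; levels become
    empirical quantiles on a 5% grid, which makes mixed intensity/count
    sources comparable.  Pathways detected (>=1 gene) in no more than
    ``min_detected_fraction`` of any column's samples are dropped.

    Returns (matrix, column order from average-linkage 1-correlation
    clustering, or None for < 3 columns).
    """
    col_levels: dict[str, pd.Series] = {}
    keep: set[str] = set()
    for name, (levels, flags, pmap) in columns.items():
        pmap = pmap.reindex(levels.index)
        n_samples = levels.shape[1]
        med, retained = {}, set()
        for pw, genes in pmap.dropna().groupby(pmap.dropna()).groups.items():
            genes = pd.Index(genes)
            det = flags.loc[genes]
            det_any = det.any(axis=1)
            if not det_any.any():
                continue
            # fraction of samples with >=1 detected gene from the pathway
            frac = float(det.any(axis=0).mean())
            vals = levels.loc[genes][det].stack().dropna()
            if vals.empty:
                continue
            med[pw] = float(vals.median())
            if frac > min_detected_fraction:
                retained.add(pw)
        col_levels[name] = pd.Series(med)
        keep |= retained
    mat = pd.DataFrame({name: _quantile_5pct(s.dropna())
                        for name, s in col_levels.items()})
    mat = mat.loc[sorted(keep & set(mat.index))]
    order = None
    if mat.shape[1] >= 3 and mat.shape[0] >= 2:
        filled = mat.fillna(mat.mean().mean())
        c = np.corrcoef(filled.to_numpy().T)
        d = np.clip(1 - np.nan_to_num(c, nan=0.0), 0, 2)
        np.fill_diagonal(d, 0)
        link = hierarchy.linkage(squareform((d + d.T) / 2, checks=False),
                                 method="average")
        order = [mat.columns[i] for i in hierarchy.leaves_list(link)]
    return mat, order


def peak_shift_table(peaks_a: pd.Series, peaks_b: pd.Series,
                     genes=None, daylight: float = 12.0) -> pd.DataFrame:
    """Circular peak-time shifts between two sites, on the 24 h clock.

    ``peaks_*`` map gene -> phase label; shift is the minimal circular
    distance (<= 12 h) between label positions.  Categories: maintained
    (0 h), shifted < 6 h, shifted >= 6 h.
    """
    if genes is None:
        genes = peaks_a.index.intersection(peaks_b.index)
    rows = []
    for g in genes:
        ha = label_cycle_hour(peaks_a[g], daylight)
        hb = label_cycle_hour(peaks_b[g], daylight)
        diff = abs(ha - hb) % 24.0
        shift = min(diff, 24.0 - diff)
        cat = ("maintained" if shift == 0
               else "shifted <6 h" if shift < 6 else "shifted >=6 h")
        rows.append({"gene_id": g, "peak_a": peaks_a[g], "peak_b": peaks_b[g],
                     "shift_h": shift, "category": cat})
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["peak_a", "peak_b", "shift_h", "category"])
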