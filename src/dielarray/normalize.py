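"""Probe-to-gene normalization: quantile normalization across samples,
then Tukey median-polish summarization of each probe set.

The pipeline quantile-normalizes linear-scale probe intensities, log2
transforms, and decomposes each gene's probe x sample block into
overall + probe effect + sample effect + residual; the gene's transcript
level in a sample is overall + that sample's effect (the robust
multi-array-average convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .design import SampleDesign

__all__ = ["quantile_normalize", "median_polish", "median_polish_summarize"]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean order-statistic vector.

    Ties within a column receive the mean of the reference values they
    span, which makes the transform independent of sort order and
    idempotent.
    """
    if m.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return m.copy()
    vals = m.to_numpy(float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values over tied groups
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def median_polish(block: np.ndarray, max_iter: int = 10, tol: float = 0.01
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a 2-D array (rows swept first).

    Returns (overall, row_effects, col_effects, residuals).  Iteration
    stops when the total absolute residual changes by less than ``tol``
    or after ``max_iter`` sweeps.
    """
    r = np.asarray(block, float).copy()
    n_rows, n_cols = r.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    prev = np.abs(r).sum()
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        r -= rmed[:, None]
        row_eff += rmed
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift
        cmed = np.median(r, axis=0)
        r -= cmed[None, :]
        col_eff += cmed
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift
        total = np.abs(r).sum()
        if abs(prev - total) < tol:
            break
        prev = total
    return overall, row_eff, col_eff, r


def median_polish_summarize(m: pd.DataFrame, probe_to_gene: pd.Series,
                            design: list[SampleDesign] | None = None,
                            max_iter: int = 10, tol: float = 0.01,
                            log_transform: bool = True) -> ExpressionMatrix:
    """Summarize probe intensities to one log2 level per gene per sample.

    ``m`` holds (quantile-normalized) linear intensities unless
    ``log_transform`` is False; ``probe_to_gene`` maps probe_id ->
    gene_id.  Probes absent from the map are dropped with a warning.
    """
    mapped = probe_to_gene.reindex(m.index)
    if mapped.isna().any():
        warnings.warn(f"{int(mapped.isna().sum())} probes lack a gene mapping; dropped")
        m = m.loc[mapped.notna()]
        mapped = mapped.dropna()
    log2 = np.log2(m.to_numpy(float)) if log_transform else m.to_numpy(float)
    log2 = pd.DataFrame(log2, index=m.index, columns=m.columns)
    levels, counts = {}, {}
    for gene, idx in log2.groupby(mapped).groups.items():
        block = log2.loc[idx].to_numpy()
        if block.shape[0] == 1:
            levels[gene] = block[0]
        else:
            overall, _, col_eff, _ = median_polish(block, max_iter, tol)
            levels[gene] = overall + col_eff
        counts[gene] = block.shape[0]
    data = pd.DataFrame.from_dict(levels, orient="index", columns=m.columns)
    data = data.sort_index()
    if design is None:
        from .design import SampleDesign as _SD
        design = [_SD(c, 0.0, "", 1, 1, float(i)) for i, c in enumerate(m.columns)]
    return ExpressionMatrix(data, design,
                            probe_counts=pd.Series(counts).sort_index())
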