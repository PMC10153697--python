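"""Spike-in-calibrated gene detection.

A gene is detected when (a) its signal-to-noise ratio exceeds the SNR
threshold (default > 5) in at least one sample, the noise being the
distribution of the sample's dimmest decile of genes, and (b) it beats
the least concentrated ERCC spike-in in strictly more than ``min_samples``
samples, by either raw log2 intensity or by predicted transcript count
from a linear concentration-response model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ERCCSet, ExpressionMatrix

__all__ = [
    "noise_floor",
    "snr",
    "detect_snr",
    "ERCCModel",
    "fit_ercc_model",
    "predict_log2_count",
    "DetectionTable",
    "detect_genes",
]


def noise_floor(levels: pd.Series | np.ndarray, decile: float = 0.10,
                spread: str = "sd") -> tuple[float, float]:
    """Noise location and spread of one sample: its dimmest decile of genes.

    Returns (median, spread) of the lowest ``floor(decile * n_genes)``
    levels (at least 2).  ``spread`` is the sample standard deviation by
    default; ``"mad"`` selects the normal-consistent median absolute
    deviation instead.
    """
    x = np.sort(np.asarray(levels, float))
    if x.size < 20:
        raise ValueError("noise floor needs >= 20 genes per sample")
    k = max(2, int(np.floor(decile * x.size)))
    bottom = x[:k]
    mu = float(np.median(bottom))
    if spread == "sd":
        sig = float(np.std(bottom, ddof=1))
    elif spread == "mad":
        sig = float(stats.median_abs_deviation(bottom, scale="normal"))
    else:
        raise ValueError(f"unknown spread estimator {spread!r}")
    if sig == 0:
        raise ValueError("degenerate noise floor: bottom-decile levels are "
                         "constant; perturb or use a different spread estimator")
    return mu, sig


def snr(level, mu_noise: float, sigma_noise: float):
    """Signal-to-noise z-score: (level - noise median) / noise spread."""
    if sigma_noise <= 0:
        raise ValueError("sigma_noise must be positive")
    return (level - mu_noise) / sigma_noise


def detect_snr(expr: ExpressionMatrix, threshold: float = 5.0,
               decile: float = 0.10, spread: str = "sd"
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-sample SNR values and strict ``snr > threshold`` flags."""
    snr_vals = {}
    for col in expr.data.columns:
        mu, sig = noise_floor(expr.data[col], decile=decile, spread=spread)
        snr_vals[col] = snr(expr.data[col], mu, sig)
    snr_df = pd.DataFrame(snr_vals)
    return snr_df, snr_df > threshold


@dataclass(frozen=True)
class ERCCModel:
    """OLS line predicting log2 transcript count from log2 array intensity."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_ercc_model(ercc: ERCCSet) -> ERCCModel:
    """Fit log2(concentration) on log2(intensity) over all spike/sample pairs.

    Concentration stands in for transcript count (they are proportional
    for a fixed spike volume), so predictions are log2 counts up to a
    shared additive constant that cancels in comparisons.
    """
    if ercc.concentration.size < 3:
        raise ValueError("need >= 3 distinct spike concentrations")
    y = np.repeat(np.log2(ercc.concentration.to_numpy(float)),
                  ercc.log2_intensity.shape[1])
    x = ercc.log2_intensity.to_numpy(float).ravel()
    if np.allclose(x, x[0]):
        raise ValueError("singular fit: spike intensities are constant")
    res = stats.linregress(x, y)
    return ERCCModel(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), x.size)


def predict_log2_count(model: ERCCModel, intensity) -> np.ndarray | float:
    return model.intercept + model.slope * np.asarray(intensity, float)


@dataclass
class DetectionTable:
    """Detection decisions plus the per-sample evidence behind them."""

    snr: pd.DataFrame                   # gene x sample
    snr_flags: pd.DataFrame             # snr > threshold
    above_ercc_intensity: pd.DataFrame  # gene x sample, comparison (i)
    above_ercc_count: pd.DataFrame      # gene x sample, comparison (ii)
    per_gene: pd.DataFrame              # n_samples_snr, n_samples_above_ercc, detected
    ercc_model: ERCCModel

    @property
    def detected(self) -> pd.Index:
        return self.per_gene.index[self.per_gene["detected"]]

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene.copy()


def detect_genes(expr: ExpressionMatrix, ercc: ERCCSet,
                 snr_threshold: float = 5.0, min_samples: int = 3,
                 min_snr_samples: int = 1, decile: float = 0.10,
                 spread: str = "sd") -> DetectionTable:
    """Apply the SNR and ERCC-floor detection rules to every gene.

    Detected genes satisfy SNR > ``snr_threshold`` in at least
    ``min_snr_samples`` samples AND beat the least concentrated spike in
    strictly more than ``min_samples`` samples, where "beat" means higher
    log2 intensity (comparison i) or higher predicted log2 count
    (comparison ii) — either suffices per sample.
    """
    snr_df, snr_flags = detect_snr(expr, snr_threshold, decile, spread)
    model = fit_ercc_model(ercc)
    floor_level = ercc.log2_intensity.loc[ercc.floor_id]   # per sample
    above_i = expr.data.gt(floor_level, axis=1)
    pred_genes = predict_log2_count(model, expr.data.to_numpy(float))
    pred_floor = predict_log2_count(model, floor_level.to_numpy(float))
    above_ii = pd.DataFrame(pred_genes > pred_floor[None, :],
                            index=expr.data.index, columns=expr.data.columns)
    n_above = (above_i | above_ii).sum(axis=1)
    n_snr = snr_flags.sum(axis=1)
    detected = (n_snr >= min_snr_samples) & (n_above > min_samples)
    per_gene = pd.DataFrame({
        "n_samples_snr": n_snr,
        "n_samples_above_ercc": n_above,
        "detected": detected,
    })
    return DetectionTable(snr_df, snr_flags, above_i, above_ii, per_gene, model)
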