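"""Duplicate-based analytical precision, bias and outlier screening.

HPLC analyte concentrations are measured once per sample, so method precision
is estimated from randomly selected duplicate pairs run alongside. Each pair
yields a signed percent difference dᵢ = 200·(x₁ᵢ−x₂ᵢ)/(x₁ᵢ+x₂ᵢ); the
percentile-spread precision is half the central 68.27% spread of the dᵢ (the
robust analogue of one standard deviation) and the bias is their median, so
single gross outliers barely move either statistic. Outliers among the dᵢ are
flagged by a plain Z-score.
"""

from __future__ import annotations

import numpy as np

__all__ = ["duplicate_precision_bias", "zscore_outliers", "percent_differences"]

# Percentiles delimiting the central 68.27% of a distribution
# (±1 SD for a Gaussian).
_P_LOW = 15.865
_P_HIGH = 84.135


def percent_differences(pairs: np.ndarray) -> np.ndarray:
    """Signed percent differences dᵢ = 200·(x₁−x₂)/(x₁+x₂) for an (n, 2) array."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    sums = arr[:, 0] + arr[:, 1]
    if np.any(sums <= 0):
        raise ValueError("each pair must have a positive sum")
    return 200.0 * (arr[:, 0] - arr[:, 1]) / sums


def duplicate_precision_bias(pairs: np.ndarray) -> tuple[float, float]:
    """Percentile-spread precision and median bias, both in percent.

    precision = (P84.135 − P15.865)/2 of the signed percent differences;
    bias = median of the signed percent differences.
    """
    d = percent_differences(pairs)
    if len(d) < 3:
        raise ValueError("need at least three duplicate pairs")
    lo, hi = np.percentile(d, [_P_LOW, _P_HIGH])
    precision = (hi - lo) / 2.0
    bias = float(np.median(d))
    return float(precision), bias


def zscore_outliers(values: np.ndarray, threshold: float = 1.5) -> np.ndarray:
    """Indices of values whose |Z| exceeds the threshold.

    Z-scores are computed once on the full set (mean, population SD);
    a zero-spread set has no outliers.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least three values")
    sd = np.std(v)
    if sd == 0:
        return np.array([], dtype=int)
    z = np.abs(v - np.mean(v)) / sd
    return np.flatnonzero(z > threshold)
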