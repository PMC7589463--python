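"""Intensity statistics family (18 features, raw in-ROI intensities)."""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["STATISTICAL_NAMES", "statistical_features"]

log = logging.getLogger(__name__)

STATISTICAL_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum",
    "p10", "p90", "maximum", "iqr", "range", "mad", "rmad", "medad",
    "cov", "qcod", "energy", "rms",
)


def statistical_features(intensities: np.ndarray) -> dict[str, float]:
    """The 18 intensity statistics.

    Variance is the population variance; kurtosis is excess kurtosis.
    Skewness, kurtosis and the coefficient of variation fall back to 0 on
    zero-variance input (logged).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("statistical features require at least one voxel")
    n = x.size
    mu = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, q25, med, q75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if sd > 0:
        skew = float(np.mean((x - mu) ** 3) / sd**3)
        kurt = float(np.mean((x - mu) ** 4) / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
        log.debug("zero-variance ROI: skewness/kurtosis set to 0")
    cov = sd / mu if mu != 0 else 0.0
    qcod = (q75 - q25) / (q75 + q25) if (q75 + q25) != 0 else 0.0

    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(sub - sub.mean()))) if sub.size else 0.0

    return {
        "mean": mu,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(med),
        "minimum": float(x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(x.max()),
        "iqr": float(q75 - q25),
        "range": float(x.max() - x.min()),
        "mad": float(np.mean(np.abs(x - mu))),
        "rmad": rmad,
        "medad": float(np.mean(np.abs(x - med))),
        "cov": float(cov),
        "qcod": float(qcod),
        "energy": float(np.sum(x**2)),
        "rms": float(np.sqrt(np.mean(x**2))),
    }
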