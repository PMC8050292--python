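"""First-order (intensity histogram) features — 18 values.

All statistics except Entropy and Uniformity operate on the raw HU values of
the ROI; Entropy and Uniformity are computed on the discretised grey levels.
Moment-based statistics (variance, skewness, kurtosis) use population (1/n)
moments, and kurtosis is not excess-corrected (a Gaussian scores ~3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_order_features", "FIRST_ORDER_NAMES"]

_EPS = np.spacing(1.0)

FIRST_ORDER_NAMES = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]


def first_order_features(
    raw_values: np.ndarray, grey_levels: np.ndarray, voxel_volume_mm3: float
) -> dict[str, float]:
    """Compute the 18 first-order features of one ROI.

    Parameters
    ----------
    raw_values : 1D array of the ROI's HU values.
    grey_levels : 1D array of the matching discretised grey levels (1..Ng).
    voxel_volume_mm3 : physical volume of one voxel, for TotalEnergy.
    """
    x = np.asarray(raw_values, dtype=float).ravel()
    gl = np.asarray(grey_levels).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    if x.size != gl.size:
        raise ValueError("raw values and grey levels must align")

    n = x.size
    mean = x.mean()
    centred = x - mean
    m2 = np.mean(centred**2)
    m3 = np.mean(centred**3)
    m4 = np.mean(centred**4)

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    counts = np.bincount(gl)[1:]
    p = counts[counts > 0] / n

    energy = float(np.sum(x**2))
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.abs(centred).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "TotalEnergy": float(voxel_volume_mm3 * energy),
        "Uniformity": float(np.sum(p**2)),
        "Variance": float(m2),
    }
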