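"""Grey-level quantisation analysis.

The number of grey levels used to discretise ROI intensities is a free
parameter of every texture feature.  This module sweeps a set of candidate
bin counts (powers of two, 8..256, plus the data-driven Freedman-Diaconis
optimum), screens each feature for dependence on that choice with the
intraclass correlation coefficient ICC(3,1), and summarises per-setting
variance collapse (sigma_n) and cross-thickness differences (delta_r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GL_SETTINGS",
    "freedman_diaconis_bins",
    "freedman_diaconis_width",
    "icc_3_1",
    "ICCResult",
    "classify_gl_dependent",
    "normalised_sd",
    "GLSweepResult",
    "summarise_gl_sweep",
]

DEFAULT_GL_SETTINGS = (8, 16, 32, 64, 128, 256)


def freedman_diaconis_width(values) -> float:
    """Freedman-Diaconis optimal histogram bin width: 2 * IQR / N^(1/3)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples for the Freedman-Diaconis rule")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate distribution: IQR is zero")
    return float(2.0 * iqr / x.size ** (1.0 / 3.0))


def freedman_diaconis_bins(values) -> int:
    """Optimal number of bins for a sample: (max-min)/width, rounded.

    Rounding is half-away-from-zero and the result is floored at 2 bins so a
    downstream quantiser always has a usable setting.
    """
    x = np.asarray(values, dtype=float).ravel()
    width = freedman_diaconis_width(x)
    n = (x.max() - x.min()) / width
    return max(2, int(math.floor(n + 0.5)))


@dataclass
class ICCResult:
    """ICC(3,1) with the two-way ANOVA mean squares it derives from."""

    icc: float
    ms_rows: float
    ms_error: float
    n: int
    k: int


def icc_3_1(measurements) -> ICCResult:
    """Consistency ICC for a two-way mixed-effects model, single measurement.

    ``measurements`` is an (n subjects x k settings) matrix with no missing
    cells.  ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E) where MS_R is the
    between-subjects (rows) mean square and MS_E the residual mean square of
    the subjects x settings decomposition without interaction.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an (n>=2) x (k>=2) matrix")
    if not np.isfinite(m).all():
        raise ValueError("missing or non-finite cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        raise ValueError("ICC undefined: all measurements identical")
    return ICCResult(float((ms_rows - ms_err) / denom), float(ms_rows), float(ms_err), n, k)


def normalised_sd(values) -> float:
    """sigma_n = sd(values) / |median(values)| (sample sd, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 values")
    med = np.median(x)
    if med == 0:
        raise ValueError("sigma_n undefined: median is zero")
    return float(x.std(ddof=1) / abs(med))


@dataclass
class GLSweepResult:
    """Per-feature value arrays across grey-level settings for one
    (tissue, thickness) stratum, plus derived screens."""

    gl_settings: tuple[int, ...]
    values: dict[str, np.ndarray]  # feature -> (n_subjects, k_settings)
    icc: dict[str, float] = field(default_factory=dict)
    icc_undefined: list[str] = field(default_factory=list)

    def compute_icc(self) -> "GLSweepResult":
        self.icc = {}
        self.icc_undefined = []
        for name, mat in self.values.items():
            if not np.isfinite(mat).all():
                self.icc_undefined.append(name)
                continue
            try:
                self.icc[name] = icc_3_1(mat).icc
            except ValueError:
                self.icc_undefined.append(name)
        return self


def classify_gl_dependent(sweep: GLSweepResult, threshold: float = 0.9) -> dict[str, bool]:
    """Flag features whose ICC(3,1) across grey-level settings is below the
    stability threshold (default 0.9): these are grey-level dependent.

    Shape features are excluded (grey-level independent by construction);
    features with undefined ICC are reported in ``sweep.icc_undefined``, not
    silently dropped here.
    """
    if not sweep.icc and sweep.values:
        sweep.compute_icc()
    return {
        name: icc < threshold
        for name, icc in sweep.icc.items()
        if not name.startswith("shape_")
    }


def summarise_gl_sweep(
    sweep_values: dict[int, pd.DataFrame],
    delta_r_medians: dict[int, pd.Series] | None = None,
    sigma_threshold: float = 0.1,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-setting summary of variance collapse and cross-thickness spread.

    Parameters
    ----------
    sweep_values : mapping ``n_bins -> DataFrame`` (subjects x features) of
        feature values at that grey-level setting.
    delta_r_medians : optional mapping ``n_bins -> Series`` of per-feature
        median delta_r at that setting, used for the boxplot statistics of
        features whose sigma_n exceeds the threshold.

    Returns one row per setting with: the count of features with
    sigma_n < threshold (near-zero variance), median/quartiles of sigma_n, and
    quartiles of delta_r restricted to features with sigma_n > threshold.
    """
    rows = []
    for setting, table in sorted(sweep_values.items()):
        cols = features if features is not None else list(table.columns)
        sigmas = {}
        for col in cols:
            try:
                sigmas[col] = normalised_sd(table[col].to_numpy())
            except ValueError:
                sigmas[col] = np.nan
        s = pd.Series(sigmas)
        collapsed = s < sigma_threshold
        row = {
            "n_bins": setting,
            "n_features": len(cols),
            "n_low_variance": int(collapsed.sum()),
            "sigma_n_median": float(s.median()),
            "sigma_n_q1": float(s.quantile(0.25)),
            "sigma_n_q3": float(s.quantile(0.75)),
        }
        if delta_r_medians is not None and setting in delta_r_medians:
            dr = delta_r_medians[setting]
            varying = s.index[s > sigma_threshold]
            dr = dr.reindex(varying).dropna()
            row.update(
                {
                    "delta_r_median": float(dr.median()) if len(dr) else np.nan,
                    "delta_r_q1": float(dr.quantile(0.25)) if len(dr) else np.nan,
                    "delta_r_q3": float(dr.quantile(0.75)) if len(dr) else np.nan,
                    "n_delta_r": int(len(dr)),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
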