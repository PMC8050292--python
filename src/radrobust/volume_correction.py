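"""Detection and fit-and-invert correction of voxel-count dependencies.

Many texture features depend on the size of the ROI through the number of
voxels entering the grey-level matrices.  The correction works feature by
feature:

1. screen for dependence with Spearman's rank correlation against the voxel
   count (threshold |r_S| >= 0.5; shape features are exempt since volume
   information is inherent to them);
2. combine per-subject measurements into a binned profile over voxel count
   (variable-width divisions with approximately equal occupancy, at least 2
   members each) so each division carries a mean and a standard-deviation
   uncertainty;
3. fit eight invertible two-parameter candidate forms
   ``y = p1 * g(x) + p0`` with ``g`` in {x, x^2, x^3, 1/x, 1/x^2, 1/x^3,
   log x, 1/log x} by weighted least squares, weights 1/sd^2;
4. adopt the candidate with the smallest reduced chi^2 (poor fits, reduced
   chi^2 > 10, are discarded) and correct each measurement by the inverse
   map ``y' = (y - p0) / g(x)``, which on the exact model returns the
   volume-free coefficient p1.

The whole procedure is wrapped as the sklearn-style transformer
:class:`VolumeDependencyCorrector` (fit on a feature table carrying an
``n_voxels`` column, transform to corrected features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FIT_FORMS",
    "FitCandidate",
    "BinnedProfile",
    "spearman_rs",
    "classify_volume_dependent",
    "bin_measurements",
    "fit_candidates",
    "select_best_fit",
    "correct_feature",
    "fit_and_correct",
    "pairwise_feature_correlations",
    "VolumeDependencyCorrector",
]

# the eight candidate basis functions g(x); model is y = p1 * g(x) + p0
FIT_FORMS: dict[int, tuple[str, object]] = {
    1: ("x", lambda x: x),
    2: ("x^2", lambda x: x**2),
    3: ("x^3", lambda x: x**3),
    4: ("1/x", lambda x: 1.0 / x),
    5: ("1/x^2", lambda x: 1.0 / x**2),
    6: ("1/x^3", lambda x: 1.0 / x**3),
    7: ("log(x)", lambda x: np.log(x)),
    8: ("1/log(x)", lambda x: 1.0 / np.log(x)),
}


def _form_valid(form_id: int, x: np.ndarray) -> bool:
    if form_id in (4, 5, 6) and np.any(x == 0):
        return False
    if form_id == 7 and np.any(x <= 0):
        return False
    if form_id == 8 and (np.any(x <= 0) or np.any(np.log(x) == 0)):
        return False
    return True


@dataclass
class FitCandidate:
    """One fitted candidate form with its goodness of fit."""

    form_id: int
    label: str
    p0: float
    p1: float
    chi2: float
    dof: int

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else np.inf

    def predict(self, x) -> np.ndarray:
        g = FIT_FORMS[self.form_id][1]
        return self.p1 * g(np.asarray(x, dtype=float)) + self.p0


@dataclass
class BinnedProfile:
    """Variable-width divisions over voxel count with per-division stats.

    ``x_members`` keeps each division's raw voxel counts: a division's mean
    response to a candidate form g is mean(g(x) over members), so a noiseless
    profile generated by ``y = p1 g(x) + p0`` is fitted exactly by that form
    regardless of the curvature of g within a division.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    counts: np.ndarray
    edges: np.ndarray
    x_members: list

    @property
    def n_divisions(self) -> int:
        return len(self.x_mean)


def spearman_rs(x, y) -> tuple[float, int]:
    """Spearman rank correlation (Pearson correlation of average ranks).

    Returns ``(r_s, n)``.  Constant input raises ValueError (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rs = stats.spearmanr(x, y).statistic
    return float(rs), int(x.size)


def classify_volume_dependent(
    rs_by_config: pd.DataFrame, threshold: float = 0.5
) -> pd.Series:
    """Flag features whose median |r_S| across voxel-size options reaches the
    dependence threshold.

    ``rs_by_config`` is a (config x feature) table of Spearman coefficients
    between feature value and voxel count.  Shape features are never flagged.
    """
    median_abs = rs_by_config.abs().median(axis=0)
    flags = median_abs >= threshold
    for name in flags.index:
        if str(name).startswith("shape_"):
            flags[name] = False
    return flags


def bin_measurements(
    x, y, min_per_bin: int = 2, target_bins: int | None = None
) -> BinnedProfile:
    """Combine measurements into variable-width divisions over ``x``.

    Divisions are quantile-spaced over the sorted x so occupancy is
    approximately constant; equal x values never straddle a boundary, and
    divisions are merged until every one holds at least ``min_per_bin``
    members.  Default target: n // 2 divisions (the minimum occupancy the
    method allows), capped at 10 and floored at 3 — small cohorts need every
    available degree of freedom for the form selection to be meaningful,
    while large cohorts keep ~4 members per division.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 2 * min_per_bin:
        raise ValueError(f"need at least {2 * min_per_bin} paired measurements")
    if target_bins is None:
        target_bins = min(10, max(3, n // 2))
    target_bins = max(1, min(target_bins, n // min_per_bin))

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    # quantile boundaries; push a boundary forward while it would split ties
    bounds = [round(i * n / target_bins) for i in range(target_bins + 1)]
    cleaned = [0]
    for b in bounds[1:-1]:
        while 0 < b < n and xs[b - 1] == xs[b]:
            b += 1
        if b > cleaned[-1] and b < n:
            cleaned.append(b)
    cleaned.append(n)

    # merge undersized divisions into their left neighbour (right for first)
    groups = [(a, b) for a, b in zip(cleaned[:-1], cleaned[1:])]
    merged: list[tuple[int, int]] = []
    for a, b in groups:
        if merged and (b - a) < min_per_bin:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    if len(merged) > 1 and merged[0][1] - merged[0][0] < min_per_bin:
        merged[1] = (merged[0][0], merged[1][1])
        merged.pop(0)

    x_mean, y_mean, y_sd, counts, edges, x_members = [], [], [], [], [xs[0]], []
    for a, b in merged:
        x_mean.append(xs[a:b].mean())
        y_mean.append(ys[a:b].mean())
        y_sd.append(ys[a:b].std(ddof=1) if b - a > 1 else 0.0)
        counts.append(b - a)
        edges.append(xs[b - 1])
        x_members.append(xs[a:b].copy())
    return BinnedProfile(
        np.array(x_mean),
        np.array(y_mean),
        np.array(y_sd),
        np.array(counts),
        np.array(edges),
        x_members,
    )


def _wls(g: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares of y on [1, g]; returns (p0, p1, chi2)."""
    sw = w.sum()
    gw = (w * g).sum() / sw
    yw = (w * y).sum() / sw
    sgg = (w * (g - gw) ** 2).sum()
    if sgg == 0:
        raise np.linalg.LinAlgError("degenerate design: g(x) constant over divisions")
    p1 = (w * (g - gw) * (y - yw)).sum() / sgg
    p0 = yw - p1 * gw
    resid = y - (p0 + p1 * g)
    return float(p0), float(p1), float((w * resid**2).sum())


def fit_candidates(profile: BinnedProfile) -> list[FitCandidate]:
    """Fit every admissible candidate form to a binned profile.

    Division uncertainties are the within-division sample sds, shrunk
    halfway (in variance) toward the profile's median positive sd: sd
    estimates from 2-4 members are so noisy that raw 1/sd^2 weights scatter
    the chi^2 ranking, and the shrinkage materially stabilises form
    selection while still down-weighting genuinely noisy divisions.
    All-zero-spread profiles fall back to unit weights.  Forms whose basis
    is undefined anywhere on the raw measurements are skipped.  Requires at
    least 3 divisions (2 coefficients + 1 degree of freedom).
    """
    if profile.n_divisions < 3:
        raise ValueError("need >= 3 divisions to fit two-parameter forms")
    sd = profile.y_sd.copy()
    positive = sd[sd > 0]
    floor = np.median(positive) if positive.size else 1.0
    sd = np.sqrt(0.5 * sd**2 + 0.5 * floor**2)
    w = 1.0 / sd**2
    all_x = np.concatenate(profile.x_members)
    out: list[FitCandidate] = []
    for form_id, (label, g) in FIT_FORMS.items():
        if not _form_valid(form_id, all_x):
            continue
        # division response to form g is the member mean of g(x), so the
        # exact generating form is recovered exactly on noiseless profiles
        gx = np.array([np.mean(g(xs)) for xs in profile.x_members], dtype=float)
        try:
            p0, p1, chi2 = _wls(gx, profile.y_mean, w)
        except np.linalg.LinAlgError:
            continue
        out.append(FitCandidate(form_id, label, p0, p1, chi2, profile.n_divisions - 2))
    return out


def select_best_fit(
    candidates: list[FitCandidate], max_reduced_chi2: float = 10.0
) -> FitCandidate | None:
    """Adopt the candidate with the smallest reduced chi^2.

    Candidates above the poor-fit ceiling are discarded; returns None
    (uncorrectable) when nothing survives.  Near-ties (within 1e-9) resolve
    to the lowest form id for determinism.
    """
    valid = [c for c in candidates if np.isfinite(c.chi2) and c.reduced_chi2 <= max_reduced_chi2]
    if not valid:
        return None
    best = min(valid, key=lambda c: (round(c.reduced_chi2 / 1e-9) * 1e-9, c.form_id))
    return best


def correct_feature(y, x, best: FitCandidate) -> np.ndarray:
    """Invert the fitted dependency: y' = (y - p0) / g(x).

    On data generated exactly by the fitted form this returns the constant
    p1.  Points where g(x) = 0 are returned as NaN (flagged, not corrected).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = FIT_FORMS[best.form_id][1]
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = np.asarray(g(x), dtype=float)
        out = np.where(gx != 0, (y - best.p0) / gx, np.nan)
    return out


def fit_and_correct(
    x, y, min_per_bin: int = 2, target_bins: int | None = None,
    max_reduced_chi2: float = 10.0,
) -> tuple[np.ndarray, FitCandidate | None]:
    """Convenience: bin, fit all forms, select, and invert in one call.

    Returns ``(corrected, best_fit)``; when no acceptable fit exists the
    values pass through uncorrected with ``best_fit`` None.
    """
    profile = bin_measurements(x, y, min_per_bin=min_per_bin, target_bins=target_bins)
    best = select_best_fit(fit_candidates(profile), max_reduced_chi2=max_reduced_chi2)
    if best is None:
        return np.asarray(y, dtype=float), None
    return correct_feature(y, x, best), best


def pairwise_feature_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise Spearman correlations between features.

    Constant (or all-NaN) features get NaN rows/columns; the diagonal is 1
    for well-defined features.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 subjects")
    data = table.to_numpy(dtype=float)
    constant = np.array([np.all(col == col[0]) or not np.isfinite(col).all() for col in data.T])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rs = stats.spearmanr(data).statistic
    if np.ndim(rs) == 0:  # scipy collapses the 2-column case to a scalar
        rs = np.array([[1.0, float(rs)], [float(rs), 1.0]])
    rs[constant, :] = np.nan
    rs[:, constant] = np.nan
    rs[np.ix_(~constant, ~constant)][np.diag_indices(int((~constant).sum()))] = 1.0
    out = pd.DataFrame(rs, index=table.columns, columns=table.columns)
    for c in out.columns[~constant]:
        out.loc[c, c] = 1.0
    return out


class VolumeDependencyCorrector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer removing voxel-count dependencies.

    Expects a DataFrame whose ``voxel_count_col`` column holds the ROI voxel
    count; every other numeric column is a feature.  ``fit`` screens each
    feature (Spearman |r_S| >= ``rs_threshold``), bins it against voxel count
    and selects the best of the eight invertible forms; ``transform`` applies
    ``(y - p0)/g(x)`` to the features selected at fit time and passes the
    rest through.  Shape features (``shape_`` prefix) are never corrected.

    Attributes
    ----------
    correlated_ : dict of feature -> r_S for features screened as dependent
    fits_ : dict of feature -> FitCandidate adopted for correction
    uncorrectable_ : features screened as dependent but with no viable fit
    """

    def __init__(
        self,
        voxel_count_col: str = "n_voxels",
        rs_threshold: float = 0.5,
        min_per_bin: int = 2,
        target_bins: int | None = None,
        max_reduced_chi2: float = 10.0,
        features: list[str] | None = None,
    ):
        self.voxel_count_col = voxel_count_col
        self.rs_threshold = rs_threshold
        self.min_per_bin = min_per_bin
        self.target_bins = target_bins
        self.max_reduced_chi2 = max_reduced_chi2
        self.features = features

    def _split(self, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with an n_voxels column")
        if self.voxel_count_col not in X.columns:
            raise ValueError(f"column {self.voxel_count_col!r} missing from X")
        x = X[self.voxel_count_col].to_numpy(dtype=float)
        if self.features is not None:
            cols = list(self.features)
        else:
            cols = [
                c
                for c in X.columns
                if c != self.voxel_count_col and pd.api.types.is_numeric_dtype(X[c])
            ]
        return x, cols

    def fit(self, X: pd.DataFrame, y=None) -> "VolumeDependencyCorrector":
        x, cols = self._split(X)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        self.correlated_: dict[str, float] = {}
        self.fits_: dict[str, FitCandidate] = {}
        self.uncorrectable_: list[str] = []
        for col in cols:
            if str(col).startswith("shape_"):
                continue  # volume information is inherent to shape features
            yv = X[col].to_numpy(dtype=float)
            ok = np.isfinite(yv) & np.isfinite(x)
            if ok.sum() < max(3, 2 * self.min_per_bin):
                continue
            try:
                rs, _ = spearman_rs(x[ok], yv[ok])
            except ValueError:
                continue
            if abs(rs) < self.rs_threshold:
                continue
            self.correlated_[col] = rs
            try:
                profile = bin_measurements(
                    x[ok], yv[ok], min_per_bin=self.min_per_bin, target_bins=self.target_bins
                )
                best = select_best_fit(
                    fit_candidates(profile), max_reduced_chi2=self.max_reduced_chi2
                )
            except ValueError:
                best = None
            if best is None:
                self.uncorrectable_.append(col)
            else:
                self.fits_[col] = best
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "fits_")
        x, _ = self._split(X)
        out = X.copy()
        for col, fit in self.fits_.items():
            if col in out.columns:
                assert not str(col).startswith("shape_")
                out[col] = correct_feature(out[col].to_numpy(dtype=float), x, fit)
        return out

    def fit_report(self) -> pd.DataFrame:
        """One row per screened feature: r_S, adopted form, coefficients."""
        check_is_fitted(self, "fits_")
        rows = []
        for col, rs in self.correlated_.items():
            fit = self.fits_.get(col)
            rows.append(
                {
                    "feature": col,
                    "r_s": rs,
                    "corrected": fit is not None,
                    "form_id": fit.form_id if fit else pd.NA,
                    "form": fit.label if fit else pd.NA,
                    "p0": fit.p0 if fit else np.nan,
                    "p1": fit.p1 if fit else np.nan,
                    "reduced_chi2": fit.reduced_chi2 if fit else np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["feature", "r_s", "corrected", "form_id", "form", "p0", "p1", "reduced_chi2"],
        )
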