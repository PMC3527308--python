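"""Long-term trend estimation and smoothing.

Trends are fitted on fractional-year time t = year + (subunit - 0.5)/P,
centred at the series midpoint before any polynomial is evaluated.  Centring
is essential: raw calendar years in the thousands make a cubic Vandermonde
matrix catastrophically ill-conditioned.

Two trend families are provided as scikit-learn style estimators:

* :class:`PolynomialTrend` — ordinary least squares on powers 0..order of
  centred time (cubic by default).  Its coefficients are interpretable; the
  order-1 slope is the comparable "linear trend" parameter.
* :class:`SplineTrend` — a cubic smoothing spline for flexible detrending
  when the trend shape itself is not of interest.  It outputs no parameters,
  only fitted values.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PolynomialTrend", "SplineTrend", "fit_polynomial_trend",
           "fit_spline_trend", "linear_trend_coefficient", "detrend", "smooth"]


def _as_time(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("time axis must be 1-d (or a single-column matrix)")
    return t


class PolynomialTrend(RegressorMixin, BaseEstimator):
    """Polynomial long-term trend fitted by ordinary least squares.

    Parameters
    ----------
    order : int, default 3
        Polynomial order (cubic by default).  Order 1 gives the linear
        trend whose slope, in series units per year, can be compared
        across sites.

    Attributes
    ----------
    coefficients_ : ndarray, shape (order + 1,)
        Ascending-power coefficients over centred time ``t - time_origin_``.
    time_origin_ : float
        Midpoint of the fitted time span, subtracted before evaluation.
    fitted_ : ndarray
        Trend evaluated on the full training calendar (no missing values:
        the trend is defined everywhere, even where observations are not).
    """

    def __init__(self, order: int = 3):
        self.order = order

    def fit(self, X, y):
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        if len(t) != len(y):
            raise ValueError("time and series lengths differ")
        if self.order < 0:
            raise ValueError("polynomial order must be >= 0")
        ok = np.isfinite(y)
        if ok.sum() < self.order + 2:
            raise ValueError(
                f"need >= {self.order + 2} non-missing points for an "
                f"order-{self.order} trend, found {int(ok.sum())}")
        self.time_origin_ = 0.5 * (t.min() + t.max())
        tc = t[ok] - self.time_origin_
        V = np.vander(tc, self.order + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y[ok], rcond=None)
        self.coefficients_ = coef
        self.n_obs_ = int(ok.sum())
        self.fitted_ = self.predict(t)
        return self

    def predict(self, X) -> np.ndarray:
        tc = _as_time(X) - self.time_origin_
        return np.polynomial.polynomial.polyval(tc, self.coefficients_)

    @property
    def slope_per_year_(self) -> float:
        """First-order coefficient (series units per calendar year)."""
        if self.order < 1:
            return 0.0
        return float(self.coefficients_[1])


class SplineTrend(RegressorMixin, BaseEstimator):
    """Cubic smoothing-spline trend.

    ``stiffness`` is the roughness-penalty weight lambda on the integrated
    squared second derivative: as stiffness -> infinity the fit approaches
    the least-squares straight line, as stiffness -> 0 it approaches an
    interpolant.  stiffness = 0 itself is rejected — interpolating every
    point is not detrending and would silently remove all signal.  The
    default of 625 puts the effective smoothing scale near lambda^(1/4) = 5
    years, i.e. roughly one effective degree of freedom per five years of
    data.
    """

    def __init__(self, stiffness: float = 625.0):
        self.stiffness = stiffness

    def fit(self, X, y):
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        if not (self.stiffness > 0):
            raise ValueError("spline stiffness must be a positive real")
        ok = np.isfinite(y)
        if ok.sum() < 8:
            raise ValueError("need >= 8 non-missing points for a spline trend")
        self.time_origin_ = 0.5 * (t.min() + t.max())
        tc = t[ok] - self.time_origin_
        # The penalty's null space (straight lines) is handled exactly by an
        # OLS line, and the spline smooths only the line residual: this keeps
        # the stiffness -> infinity limit (the OLS line) numerically stable,
        # where a direct solve loses the data term to the penalty.
        A = np.column_stack([np.ones_like(tc), tc])
        self._line_coef, *_ = np.linalg.lstsq(A, y[ok], rcond=None)
        self._spline = make_smoothing_spline(tc, y[ok] - A @ self._line_coef,
                                             lam=float(self.stiffness))
        self.n_obs_ = int(ok.sum())
        self.fitted_ = self.predict(t)
        return self

    def predict(self, X) -> np.ndarray:
        tc = _as_time(X) - self.time_origin_
        return self._line_coef[0] + self._line_coef[1] * tc + self._spline(tc)


def fit_polynomial_trend(t, y, order: int = 3) -> PolynomialTrend:
    """OLS polynomial trend on fractional-year time (cubic default)."""
    return PolynomialTrend(order=order).fit(t, y)


def fit_spline_trend(t, y, stiffness: float = 625.0) -> SplineTrend:
    """Cubic smoothing-spline trend with the given roughness weight."""
    return SplineTrend(stiffness=stiffness).fit(t, y)


def linear_trend_coefficient(t, y) -> float:
    """Slope of the order-1 trend, in series units per calendar year."""
    t = _as_time(t)
    if np.isfinite(np.asarray(y, dtype=float)).sum() < 3:
        raise ValueError("need >= 3 non-missing points for a linear trend")
    return PolynomialTrend(order=1).fit(t, y).slope_per_year_


def detrend(y, trend) -> np.ndarray:
    """Observation minus fitted trend; missing stays missing.

    ``trend`` may be a fitted trend estimator or a plain fitted-value vector.
    """
    y = np.asarray(y, dtype=float)
    fitted = getattr(trend, "fitted_", trend)
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != y.shape:
        raise ValueError("series and trend lengths differ")
    return y - fitted


def smooth(y, method: str = "moving_average", window_or_cutoff=3,
           periodicity: int | None = None) -> np.ndarray:
    """Optional pre-smoothing for one-off outbreaks or noisy counts.

    moving_average
        Centred mean over an odd window, shrinking symmetrically at the
        edges; windows renormalise over available (non-missing) points and
        an all-missing window yields missing.
    lowpass
        Zero-phase second-order Butterworth low-pass, applied forward and
        backward (no phase shift).  ``window_or_cutoff`` is the cutoff in
        cycles per year, strictly between 0 and P/2; requires
        ``periodicity`` and a gap-free series.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if method == "moving_average":
        w = int(window_or_cutoff)
        if w != window_or_cutoff or w % 2 == 0 or w < 3 or w > n:
            raise ValueError("moving-average window must be an odd integer "
                             f">= 3 and <= series length, got {window_or_cutoff}")
        half = w // 2
        out = np.empty(n)
        for i in range(n):
            r = min(half, i, n - 1 - i)
            seg = y[i - r:i + r + 1]
            good = np.isfinite(seg)
            out[i] = seg[good].mean() if good.any() else np.nan
        return out
    if method == "lowpass":
        if periodicity is None:
            raise ValueError("lowpass smoothing needs the periodicity "
                             "(samples per year)")
        cutoff = float(window_or_cutoff)
        if not (0 < cutoff < periodicity / 2):
            raise ValueError(f"cutoff must lie strictly between 0 and "
                             f"P/2 = {periodicity / 2} cycles/year")
        if not np.isfinite(y).all():
            raise ValueError("lowpass smoothing requires a gap-free series; "
                             "interpolate or moving-average first")
        b, a = sps.butter(2, cutoff, btype="low", fs=periodicity)
        return sps.filtfilt(b, a, y)
    raise ValueError(f"unknown smoothing method {method!r}")
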