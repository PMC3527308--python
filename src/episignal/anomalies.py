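"""Baseline modelling with exclusion windows, prediction intervals,
anomaly cataloguing and excess-burden estimation.

The baseline is a joint OLS fit of polynomial trend plus seasonal harmonics
on the *non-excluded, non-missing* points only, then evaluated over the
full calendar.  Excluding an atypical span (e.g. pandemic years) before
fitting is what keeps the baseline an estimate of burden "as if the event
had not happened"; fitting through the event would drag the model upward
and hide part of the excess.

Observations are flagged against a prediction interval for a *new*
observation, baseline +/- t * s with s the residual standard deviation of
the fit points — appropriate because individual observations, not the mean
curve, are being judged.  Excess burden over a window is, by default, the
sum of observation minus the interval's upper bound where positive; the
signed observation-minus-baseline sum is offered as a clearly non-default
alternative common in the excess-mortality literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import TimeSeriesPanel
from .seasonality import DEFAULT_FREQUENCIES, HarmonicModel, HarmonicRegression
from .trend import _as_time

__all__ = ["exclusion_mask", "SeasonalBaseline", "fit_baseline",
           "prediction_interval", "detect_anomalies", "excess_burden",
           "AnomalyRecord", "AnomalyCatalogue"]


def exclusion_mask(panel: TimeSeriesPanel, windows=None, years=None) -> np.ndarray:
    """Boolean mask over the panel calendar: True = excluded from fitting.

    ``windows`` is a list of inclusive (start_year, start_subunit,
    end_year, end_subunit) tuples; ``years`` a list of whole calendar years.
    At least two complete years must remain un-excluded.
    """
    mask = np.zeros(panel.n_rows, dtype=bool)
    P = panel.periodicity
    key = panel.years * (P + 1) + panel.subunits
    for (y1, s1, y2, s2) in (windows or []):
        k1, k2 = y1 * (P + 1) + s1, y2 * (P + 1) + s2
        if k1 > k2:
            raise ValueError(f"window ({y1},{s1})-({y2},{s2}) is reversed")
        if k1 < key[0] or k2 > key[-1]:
            raise ValueError(f"window ({y1},{s1})-({y2},{s2}) lies outside "
                             "the panel calendar")
        mask |= (key >= k1) & (key <= k2)
    for y in (years or []):
        hit = panel.years == y
        if not hit.any():
            raise ValueError(f"year {y} lies outside the panel calendar")
        mask |= hit
    # enough complete years must survive
    remaining = 0
    for y in np.unique(panel.years):
        rows = panel.years == y
        if rows.sum() >= P and not mask[rows].any():
            remaining += 1
    if remaining < 2:
        raise ValueError("exclusion leaves fewer than 2 complete years "
                         "for fitting the baseline")
    return mask


class SeasonalBaseline(RegressorMixin, BaseEstimator):
    """Joint trend + harmonic baseline with a prediction interval.

    Parameters
    ----------
    trend_order : polynomial trend order (cubic default).
    frequencies : harmonic frequencies in cycles/year (1, 2, 4 default).
    level : two-sided prediction-interval level (0.95 default).

    Attributes
    ----------
    coefficients_ : full OLS coefficient vector (trend powers, then
        cos/sin pairs per harmonic; the intercept is counted once, as the
        order-0 trend term).
    harmonics_ : the fitted :class:`~episignal.seasonality.HarmonicModel`
        (mean level folded into the trend, so its mean_level is 0).
    residual_scale_ : residual SD of the fit points (ddof = parameter count).
    n_fit_ : number of points used; ``df_`` = n_fit_ - p.
    """

    def __init__(self, trend_order: int = 3, frequencies=DEFAULT_FREQUENCIES,
                 level: float = 0.95, periodicity: int = 12):
        self.trend_order = trend_order
        self.frequencies = frequencies
        self.level = level
        self.periodicity = periodicity

    # ------------------------------------------------------------------
    def _design(self, t) -> np.ndarray:
        tc = np.asarray(t, dtype=float) - self.time_origin_
        V = np.vander(tc, self.trend_order + 1, increasing=True)
        H = HarmonicRegression.design(np.asarray(t, dtype=float),
                                      self.frequencies)[:, 1:]
        return np.column_stack([V, H])

    def fit(self, X, y, exclude=None):
        if not (0 < self.level < 1):
            raise ValueError("interval level must lie in (0, 1)")
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        exclude = np.zeros(len(y), dtype=bool) if exclude is None \
            else np.asarray(exclude, dtype=bool)
        if exclude.shape != y.shape:
            raise ValueError("exclusion mask length mismatch")
        use = np.isfinite(y) & ~exclude
        p = self.trend_order + 1 + 2 * len(tuple(self.frequencies))
        if use.sum() < p + 2:
            raise ValueError(f"need >= {p + 2} usable points to fit the "
                             f"baseline, found {int(use.sum())}")
        self.time_origin_ = 0.5 * (t.min() + t.max())
        Xd = self._design(t[use])
        coef, *_ = np.linalg.lstsq(Xd, y[use], rcond=None)
        self.coefficients_ = coef
        self.n_fit_ = int(use.sum())
        self.n_params_ = p
        self.df_ = self.n_fit_ - p
        resid = y[use] - Xd @ coef
        self.residual_scale_ = float(np.sqrt(resid @ resid / self.df_))
        h = coef[self.trend_order + 1:]
        a, b = h[0::2], h[1::2]
        self.harmonics_ = HarmonicModel(
            mean_level=0.0, frequencies=tuple(self.frequencies),
            amplitudes=np.hypot(a, b),
            phases=np.mod(np.arctan2(b, a), 2 * np.pi),
            periodicity=self.periodicity)
        self.trend_coefficients_ = coef[:self.trend_order + 1]
        self.baseline_ = self.predict(t)
        return self

    def predict(self, X) -> np.ndarray:
        """Baseline evaluated anywhere on the calendar (excluded spans
        included — that is the point of the exclusion)."""
        return self._design(_as_time(X)) @ self.coefficients_

    def prediction_interval(self, X, level: float | None = None):
        """(lower, upper) prediction bounds for a new observation:
        baseline -/+ t_(1-alpha/2, n_fit - p) * residual_scale."""
        level = self.level if level is None else level
        base = self.predict(X)
        q = float(stats.t.ppf(0.5 + level / 2, df=self.df_))
        half = q * self.residual_scale_
        return base - half, base + half


def fit_baseline(t, y, exclude=None, trend_order: int = 3,
                 frequencies=DEFAULT_FREQUENCIES, level: float = 0.95,
                 periodicity: int = 12) -> SeasonalBaseline:
    """Fit the trend+harmonic baseline on non-excluded, non-missing points."""
    return SeasonalBaseline(trend_order=trend_order, frequencies=frequencies,
                            level=level, periodicity=periodicity
                            ).fit(t, y, exclude=exclude)


def prediction_interval(model: SeasonalBaseline, t, level=None):
    return model.prediction_interval(t, level=level)


@dataclass
class AnomalyRecord:
    index: int
    year: int | None
    subunit: int | None
    observed: float
    baseline: float
    lower: float
    upper: float
    direction: str          # "above" | "below"
    magnitude: float        # observed - violated bound (sign carries direction)


@dataclass
class AnomalyCatalogue:
    records: list[AnomalyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_above(self) -> int:
        return sum(r.direction == "above" for r in self.records)

    @property
    def n_below(self) -> int:
        return sum(r.direction == "below" for r in self.records)


def detect_anomalies(y, lower, upper, baseline=None, calendar=None,
                     restrict_to=None) -> AnomalyCatalogue:
    """Catalogue every non-missing observation strictly outside the bounds.

    Boundary points are not anomalies (strict inequality).  ``restrict_to``
    is an optional boolean mask limiting the reported region — typically
    the excluded spans, or any window of interest; ``calendar`` is an
    optional (years, subunits) pair used to annotate records.
    """
    y = np.asarray(y, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    baseline = 0.5 * (lower + upper) if baseline is None \
        else np.asarray(baseline, dtype=float)
    region = np.ones(len(y), dtype=bool) if restrict_to is None \
        else np.asarray(restrict_to, dtype=bool)
    years, subs = (None, None) if calendar is None else calendar
    out = AnomalyCatalogue()
    for i in np.flatnonzero(region & np.isfinite(y)):
        i = int(i)
        if y[i] > upper[i]:
            direction, mag = "above", y[i] - upper[i]
        elif y[i] < lower[i]:
            direction, mag = "below", y[i] - lower[i]
        else:
            continue
        out.records.append(AnomalyRecord(
            index=i,
            year=int(years[i]) if years is not None else None,
            subunit=int(subs[i]) if subs is not None else None,
            observed=float(y[i]), baseline=float(baseline[i]),
            lower=float(lower[i]), upper=float(upper[i]),
            direction=direction, magnitude=float(mag)))
    return out


def excess_burden(y, model: SeasonalBaseline, t, window_mask,
                  reference: str = "upper_bound"):
    """Total burden attributable to an anomalous period.

    reference="upper_bound" (default): sum of max(observed - upper, 0) over
    the window — burden above what regular variability would allow.
    reference="baseline": signed sum of observed - baseline, the common
    alternative in the excess-mortality literature (non-default here).

    Returns ``(total, per_point)`` where ``per_point`` is aligned with the
    window (missing observations contribute 0 and are NaN in per_point).
    """
    y = np.asarray(y, dtype=float)
    t = _as_time(t)
    window_mask = np.asarray(window_mask, dtype=bool)
    if window_mask.shape != y.shape:
        raise ValueError("window mask length mismatch")
    idx = np.flatnonzero(window_mask)
    if len(idx) == 0:
        raise ValueError("excess window is empty")
    if reference == "upper_bound":
        _, upper = model.prediction_interval(t[idx])
        contrib = np.maximum(y[idx] - upper, 0.0)
    elif reference == "baseline":
        contrib = y[idx] - model.predict(t[idx])
    else:
        raise ValueError(f"unknown excess reference {reference!r}")
    good = np.isfinite(contrib)
    total = float(contrib[good].sum())
    return total, contrib
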