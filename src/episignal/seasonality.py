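"""Harmonic (partial Fourier) seasonality: fitting, signature, peaks.

The seasonal component is modelled as a sum of sinusoids at 1, 2 and 4
cycles per year (12-, 6- and 3-month periods) fitted by ordinary least
squares and reported as amplitude and phase rather than sine/cosine
regression coefficients:

    s(t) = m + sum_k A_k * cos(2 pi k t - phi_k),   A_k >= 0, phi_k in [0, 2pi)

with t in fractional years.  Under this convention a pure annual harmonic
peaks at month 12*phi_1/(2*pi) (month 0 = start of January), so phase is
monotone in peak timing.

The *seasonal signature* is this model evaluated over one average year; the
peak/trough statistics of the signature (timing in months, relative
amplitude = wave height / peak value) are the comparable seasonal
parameters.  Because the signature may be bimodal, peak timing is read from
the composite curve by grid search with optional continuous refinement, not
from phi_1 alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import TimeSeriesPanel, fractional_year
from .trend import PolynomialTrend, _as_time, detrend

__all__ = ["HarmonicModel", "HarmonicRegression", "SeasonalSignature",
           "PeakSet", "fit_harmonics", "seasonal_signature", "find_peaks",
           "relative_amplitude", "composite_model", "stationarity_diagnostic",
           "average_year_by_category"]

DEFAULT_FREQUENCIES = (1, 2, 4)  # cycles/year: 12-, 6-, 3-month periods


@dataclass
class HarmonicModel:
    """Mean level plus per-harmonic amplitude/phase ("harmonic parameters")."""

    mean_level: float
    frequencies: tuple
    amplitudes: np.ndarray
    phases: np.ndarray
    periodicity: int = 12

    def __post_init__(self) -> None:
        self.frequencies = tuple(float(f) for f in self.frequencies)
        if len(set(self.frequencies)) != len(self.frequencies):
            raise ValueError("duplicate harmonic frequencies")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 2 * np.pi)
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be non-negative")

    def component(self, t) -> np.ndarray:
        """Seasonal component (without mean) at fractional-year times t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for k, A, phi in zip(self.frequencies, self.amplitudes, self.phases):
            out += A * np.cos(2 * np.pi * k * t - phi)
        return out

    def signature_value(self, u) -> np.ndarray:
        """mean_level + seasonal component at within-year position u in [0, 1)."""
        return self.mean_level + self.component(u)


class HarmonicRegression(RegressorMixin, BaseEstimator):
    """OLS partial Fourier fit of a (detrended) series.

    Regresses the series on {1, cos(2 pi k t), sin(2 pi k t)} for each
    frequency k (cycles per year) and converts each (a_k, b_k) pair to
    amplitude A_k = hypot(a_k, b_k) and phase phi_k = atan2(b_k, a_k) so
    that the k-th component equals A_k * cos(2 pi k t - phi_k).

    Attributes
    ----------
    mean_level_ : float
    amplitudes_, phases_ : ndarray, one entry per frequency
    amplitude_se_ : ndarray
        Delta-method standard error of each amplitude (equals the common
        coefficient SE; cos/sin columns are near-orthonormal on a whole
        number of years).
    """

    def __init__(self, frequencies=DEFAULT_FREQUENCIES, periodicity: int = 12):
        self.frequencies = frequencies
        self.periodicity = periodicity

    @staticmethod
    def design(t, frequencies) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cols = [np.ones_like(t)]
        for k in frequencies:
            w = 2 * np.pi * float(k) * t
            cols.append(np.cos(w))
            cols.append(np.sin(w))
        return np.column_stack(cols)

    def fit(self, X, y):
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        freqs = tuple(float(f) for f in self.frequencies)
        if len(set(freqs)) != len(freqs):
            raise ValueError("duplicate harmonic frequencies")
        ok = np.isfinite(y)
        p = 2 * len(freqs) + 1
        if ok.sum() < 2 * p:
            raise ValueError(f"need >= {2 * p} non-missing points to fit "
                             f"{len(freqs)} harmonics, found {int(ok.sum())}")
        if t[ok].max() - t[ok].min() < 1.0:
            raise ValueError("need at least two years of data "
                             "(about two full seasonal cycles)")
        Xd = self.design(t[ok], freqs)
        coef, *_ = np.linalg.lstsq(Xd, y[ok], rcond=None)
        self.mean_level_ = float(coef[0])
        a = coef[1::2]
        b = coef[2::2]
        self.amplitudes_ = np.hypot(a, b)
        self.phases_ = np.mod(np.arctan2(b, a), 2 * np.pi)
        self.n_obs_, self.n_params_ = int(ok.sum()), p
        resid = y[ok] - Xd @ coef
        dof = max(self.n_obs_ - p, 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(Xd.T @ Xd)
        coef_var = sigma2 * np.diag(XtX_inv)
        # var(A) ~ (a^2 var(a) + b^2 var(b)) / A^2 ; for near-orthonormal
        # harmonic columns var(a) == var(b), so this is just the coef var
        with np.errstate(invalid="ignore", divide="ignore"):
            amp_var = (a**2 * coef_var[1::2] + b**2 * coef_var[2::2]) \
                / np.where(self.amplitudes_ > 0, self.amplitudes_**2, 1.0)
        self.amplitude_se_ = np.sqrt(np.where(self.amplitudes_ > 0, amp_var,
                                              coef_var[1::2]))
        self.residual_sd_ = float(np.sqrt(sigma2))
        return self

    def predict(self, X) -> np.ndarray:
        return self.to_model().signature_value(_as_time(X))

    def to_model(self) -> HarmonicModel:
        return HarmonicModel(mean_level=self.mean_level_,
                             frequencies=tuple(self.frequencies),
                             amplitudes=self.amplitudes_.copy(),
                             phases=self.phases_.copy(),
                             periodicity=self.periodicity)


def fit_harmonics(t, detrended, frequencies=DEFAULT_FREQUENCIES,
                  periodicity: int = 12) -> HarmonicModel:
    """Fit the partial Fourier series to a detrended series; see
    :class:`HarmonicRegression`."""
    return HarmonicRegression(frequencies=frequencies,
                              periodicity=periodicity).fit(t, detrended).to_model()


@dataclass
class SeasonalSignature:
    """The harmonic model evaluated over one average year on a fine grid."""

    grid: np.ndarray    # within-year positions in [0, 1)
    values: np.ndarray
    model: HarmonicModel | None = None

    @property
    def resolution(self) -> int:
        return len(self.grid)


def seasonal_signature(model: HarmonicModel,
                       resolution: int = 1200) -> SeasonalSignature:
    """Evaluate the seasonal signature on a uniform within-year grid."""
    if resolution < 10 * model.periodicity:
        raise ValueError(f"resolution must be >= 10 * P = "
                         f"{10 * model.periodicity}")
    u = np.arange(resolution) / resolution
    return SeasonalSignature(grid=u, values=model.signature_value(u),
                             model=model)


@dataclass
class PeakSet:
    """Peak/trough statistics of a seasonal signature (times in months)."""

    peak_time: float | None
    peak_value: float
    trough_time: float | None
    trough_value: float
    amplitude: float | None            # (peak - trough)/peak, None if undefined
    amplitude_defined: bool = True
    amplitude_exceeds_one: bool = False
    degenerate: bool = False           # flat signature: timings undefined
    secondary_peak_time: float | None = None
    secondary_peak_value: float | None = None
    secondary_amplitude: float | None = None
    notes: list = field(default_factory=list)

    @property
    def bimodal(self) -> bool:
        return self.secondary_peak_time is not None


def relative_amplitude(peak_value: float, trough_value: float) -> float:
    """Wave height divided by the peak value: (peak - trough) / peak.

    Dimensionless seasonal-strength measure in [0, 1] for non-negative
    troughs; values above 1 (negative trough) are returned unclipped — the
    caller flags them.  Undefined (error) for non-positive peaks.
    """
    if peak_value <= 0:
        raise ValueError("amplitude undefined for non-positive peak")
    if trough_value > peak_value:
        raise ValueError("trough exceeds peak")
    return (peak_value - trough_value) / peak_value


def _circular_distance(u1: float, u2: float) -> float:
    d = abs(u1 - u2) % 1.0
    return min(d, 1.0 - d)


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices of strict-ish local maxima on a periodic grid; on plateaus the
    earliest index is kept."""
    prev = np.roll(v, 1)
    nxt = np.roll(v, -1)
    return np.flatnonzero((v > prev) & (v >= nxt))


def _refine_extremum(model: HarmonicModel, u0: float, du: float,
                     kind: str) -> tuple[float, float]:
    sign = -1.0 if kind == "max" else 1.0

    def f(u):
        return sign * float(model.signature_value(np.array([u]))[0])

    res = minimize_scalar(f, bounds=(u0 - du, u0 + du), method="bounded",
                          options={"xatol": 1e-12})
    u = float(res.x) % 1.0
    return u, sign * float(res.fun)


def find_peaks(signature: SeasonalSignature, min_separation_months: float = 1.0,
               prominence_frac: float = 0.05, refine: bool = True) -> PeakSet:
    """Locate primary/secondary peaks and the trough of a seasonal signature.

    The primary peak (trough) is the global maximum (minimum) over the
    periodic grid, wrap-around aware; ties on a plateau report the earliest
    within-year time.  A secondary peak is the highest remaining local
    maximum at least ``min_separation_months`` from the primary on both
    sides whose topographic prominence exceeds ``prominence_frac`` of the
    primary wave height — a signature with one is bimodal.

    When the signature carries its analytic model and ``refine`` is true,
    extremum positions are polished by bounded continuous optimisation
    around the best grid point; with ``refine=False`` grid positions and
    values are reported as-is.

    A (numerically) constant signature yields a degenerate result: zero
    amplitude, undefined timings.
    """
    v = signature.values
    u = signature.grid
    n = len(v)
    mean = float(v.mean())
    rng = float(v.max() - v.min())
    if rng <= 1e-12 * max(1.0, abs(mean)):
        return PeakSet(peak_time=None, peak_value=mean, trough_time=None,
                       trough_value=mean, amplitude=0.0,
                       amplitude_defined=True, degenerate=True,
                       notes=["constant signature: peak timing undefined"])

    i_pk = int(np.argmax(v))
    i_tr = int(np.argmin(v))
    du = 1.0 / n
    if refine and signature.model is not None:
        u_pk, v_pk = _refine_extremum(signature.model, u[i_pk], du, "max")
        u_tr, v_tr = _refine_extremum(signature.model, u[i_tr], du, "min")
    else:
        u_pk, v_pk = float(u[i_pk]), float(v[i_pk])
        u_tr, v_tr = float(u[i_tr]), float(v[i_tr])

    wave_height = v_pk - v_tr
    notes: list[str] = []
    amplitude: float | None
    defined, exceeds = True, False
    if v_pk <= 0:
        amplitude, defined = None, False
        notes.append("amplitude undefined: non-positive peak value")
    else:
        amplitude = relative_amplitude(v_pk, v_tr)
        if amplitude > 1:
            exceeds = True
            notes.append("amplitude exceeds 1 (negative trough); not clipped")

    # ---- secondary peak -------------------------------------------------
    sep = min_separation_months / 12.0
    sec_t = sec_v = sec_a = None
    cand = [i for i in _local_maxima(v)
            if _circular_distance(float(u[i]), float(u[i_pk])) >= sep]
    cand.sort(key=lambda i: -v[i])
    for i in cand:
        prom = v[i] - _key_saddle(v, i, i_pk)
        if prom > prominence_frac * wave_height:
            if refine and signature.model is not None:
                sec_u, sec_v = _refine_extremum(signature.model, float(u[i]),
                                                du, "max")
                if _circular_distance(sec_u, u_pk) < sep:
                    sec_v = None
                    continue
            else:
                sec_u, sec_v = float(u[i]), float(v[i])
            sec_t = 12.0 * sec_u
            sec_a = relative_amplitude(sec_v, v_tr) if sec_v > 0 else None
            break

    return PeakSet(peak_time=12.0 * u_pk, peak_value=v_pk,
                   trough_time=12.0 * u_tr, trough_value=v_tr,
                   amplitude=amplitude, amplitude_defined=defined,
                   amplitude_exceeds_one=exceeds,
                   secondary_peak_time=sec_t, secondary_peak_value=sec_v,
                   secondary_amplitude=sec_a, notes=notes)


def _key_saddle(v: np.ndarray, i_cand: int, i_primary: int) -> float:
    """Topographic prominence saddle on a circular grid: the higher of the
    two path minima connecting the candidate to the primary peak."""
    n = len(v)
    if i_cand <= i_primary:
        lo, hi = i_cand, i_primary
    else:
        lo, hi = i_primary, i_cand
    inner = v[lo:hi + 1].min()
    outer = np.concatenate([v[hi:], v[:lo + 1]]).min() if n else inner
    return max(float(inner), float(outer))


def composite_model(trend, harmonics: HarmonicModel, t) -> np.ndarray:
    """Trend plus harmonic component on the calendar — the fitted model curve
    overlaid on the raw series."""
    t = _as_time(t)
    fitted = getattr(trend, "fitted_", trend)
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != t.shape:
        raise ValueError("trend and calendar lengths differ")
    return fitted + harmonics.component(t)


@dataclass
class StationarityDiagnostic:
    """Per-year peak timings and their drift; large |slope| means the series
    should be split into shorter, stationary segments before comparing
    seasonal parameters."""

    years: np.ndarray
    peak_months: np.ndarray            # raw within-year argmax, months
    unwrapped_months: np.ndarray       # circularly unwrapped
    drift_slope: float                 # months per year


def stationarity_diagnostic(panel_or_t, y=None, periodicity: int = 12,
                            trend_order: int = 3) -> StationarityDiagnostic:
    """Per-year peak times (after detrending) and their drift in months/year.

    Accepts either a :class:`TimeSeriesPanel` plus a site (pass the series as
    ``y``) or explicit ``(t is a panel)`` usage; simplest call:
    ``stationarity_diagnostic(panel, panel.series("A"))``.

    Year-to-year peak differences are mapped circularly to (-6, +6] months
    before the drift slope is estimated, so a peak alternating between
    December and January does not masquerade as a six-month shift.
    """
    if isinstance(panel_or_t, TimeSeriesPanel):
        panel = panel_or_t
        years_all, subs, P = panel.years, panel.subunits, panel.periodicity
        yy = panel.values[:, 0] if y is None else np.asarray(y, dtype=float)
        t = panel.time
    else:
        raise TypeError("pass a TimeSeriesPanel (with an optional series)")
    cyears = panel.complete_years()
    if len(cyears) < 4:
        raise ValueError("need >= 4 complete years for a stationarity "
                         "diagnostic")
    resid = detrend(yy, PolynomialTrend(order=trend_order).fit(t, yy))
    peaks, used_years = [], []
    for cy in cyears:
        rows = np.flatnonzero(years_all == cy)
        vals = resid[rows]
        if not np.isfinite(vals).any():
            continue
        i = int(np.nanargmax(vals))
        peaks.append((subs[rows][i] - 0.5) * 12.0 / P)
        used_years.append(cy)
    peaks = np.asarray(peaks)
    used_years = np.asarray(used_years, dtype=float)
    unwrapped = peaks.copy()
    for i in range(1, len(unwrapped)):
        d = peaks[i] - peaks[i - 1]
        d = (d + 6.0) % 12.0 - 6.0
        if d == -6.0:
            d = 6.0
        unwrapped[i] = unwrapped[i - 1] + d
    slope = float(np.polyfit(used_years, unwrapped, 1)[0]) if len(used_years) > 1 \
        else 0.0
    return StationarityDiagnostic(years=used_years.astype(int),
                                  peak_months=peaks,
                                  unwrapped_months=unwrapped,
                                  drift_slope=slope)


def average_year_by_category(panels: list[TimeSeriesPanel],
                             site=0) -> np.ndarray:
    """Average-year profile per category: cell (m, c) is the mean over years
    of category c's series at sub-year unit m (missing excluded).

    ``panels`` hold one category each (e.g. one workbook sheet per age
    group) and must share the calendar; ``site`` selects the series.
    """
    if not panels:
        raise ValueError("no panels supplied")
    ref = panels[0]
    for p in panels[1:]:
        if (p.periodicity != ref.periodicity
                or not np.array_equal(p.years, ref.years)
                or not np.array_equal(p.subunits, ref.subunits)):
            raise ValueError("panels do not share a calendar")
    P = ref.periodicity
    out = np.full((P, len(panels)), np.nan)
    for c, p in enumerate(panels):
        series = p.series(site)
        for m in range(1, P + 1):
            vals = series[p.subunits == m]
            good = np.isfinite(vals)
            if good.any():
                out[m - 1, c] = vals[good].mean()
    return out
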