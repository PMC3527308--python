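"""End-to-end per-site analysis: read -> trend -> harmonics -> peaks
(-> baseline/anomalies -> wavelet), assembled into the parameter table.

This is the library-level engine behind the command line; everything here
is also directly usable from Python.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anomalies as anom
from . import seasonality as seas
from . import trend as trend_mod
from .panel import GeoTable, TimeSeriesPanel
from .viz import SiteAnalysis, build_parameter_table

__all__ = ["AnalysisOptions", "analyze_site", "analyze_panel"]


@dataclass
class AnalysisOptions:
    """Defaults mirror the out-of-the-box behaviour: cubic polynomial
    detrending, 12/6/3-month harmonics, 95% interval, no exclusions."""

    detrend_method: str = "polynomial"   # "polynomial" | "spline" | "none"
    poly_order: int = 3
    spline_stiffness: float = 625.0
    frequencies: tuple = seas.DEFAULT_FREQUENCIES
    smooth_method: str | None = None     # "moving_average" | "lowpass"
    smooth_param: float = 3
    exclude_years: tuple = ()
    exclude_windows: tuple = ()          # ((y1, s1, y2, s2), ...)
    level: float = 0.95
    run_anomalies: bool | None = None    # None: run iff exclusions given
    excess_reference: str = "upper_bound"
    signature_resolution: int = 1200

    @property
    def anomalies_enabled(self) -> bool:
        if self.run_anomalies is not None:
            return self.run_anomalies
        return bool(self.exclude_years or self.exclude_windows)


@dataclass
class SiteResult:
    """Full per-site machinery (models, peaks, catalogues) for one series."""

    analysis: SiteAnalysis
    trend_model: object | None = None
    harmonic_model: seas.HarmonicModel | None = None
    peaks: seas.PeakSet | None = None
    baseline: anom.SeasonalBaseline | None = None
    catalogue: anom.AnomalyCatalogue | None = None
    composite: np.ndarray | None = None
    issues: list = field(default_factory=list)


def analyze_site(panel: TimeSeriesPanel, site,
                 options: AnalysisOptions) -> SiteResult:
    t = panel.time
    y = panel.series(site).astype(float)
    if not np.isfinite(y).any():
        return SiteResult(analysis=SiteAnalysis(amplitude_flag="all_missing"),
                          issues=["series entirely missing"])
    if options.smooth_method:
        y = trend_mod.smooth(y, method=options.smooth_method,
                             window_or_cutoff=options.smooth_param,
                             periodicity=panel.periodicity)

    # ---- trend ---------------------------------------------------------
    if options.detrend_method == "polynomial":
        tr = trend_mod.PolynomialTrend(order=options.poly_order).fit(t, y)
        linear = trend_mod.linear_trend_coefficient(t, y)
        resid = trend_mod.detrend(y, tr)
    elif options.detrend_method == "spline":
        tr = trend_mod.SplineTrend(stiffness=options.spline_stiffness).fit(t, y)
        linear = trend_mod.linear_trend_coefficient(t, y)
        resid = trend_mod.detrend(y, tr)
    elif options.detrend_method == "none":
        tr, linear, resid = None, None, y
    else:
        raise ValueError(f"unknown detrend method {options.detrend_method!r}")

    # ---- harmonics + signature peaks ----------------------------------
    harm = seas.fit_harmonics(t, resid, frequencies=options.frequencies,
                              periodicity=panel.periodicity)
    overall_mean = float(np.nanmean(y))
    # signature about the series' overall level, so peak/trough values are
    # on the observation scale and the relative amplitude is meaningful
    sig_model = seas.HarmonicModel(
        mean_level=overall_mean if tr is not None else harm.mean_level,
        frequencies=harm.frequencies, amplitudes=harm.amplitudes,
        phases=harm.phases, periodicity=harm.periodicity)
    signature = seas.seasonal_signature(
        sig_model, resolution=max(options.signature_resolution,
                                  10 * panel.periodicity))
    peaks = seas.find_peaks(signature)
    flag = ""
    if peaks.degenerate:
        flag = "degenerate"
    elif not peaks.amplitude_defined:
        flag = "undefined"
    elif peaks.amplitude_exceeds_one:
        flag = "exceeds_1"

    composite = None
    if tr is not None:
        composite = seas.composite_model(tr, harm, t)

    analysis = SiteAnalysis(
        mean_level=overall_mean, linear_trend=linear,
        amplitudes=harm.amplitudes, phases=harm.phases,
        frequencies=harm.frequencies,
        peak_time_months=peaks.peak_time,
        relative_amplitude=peaks.amplitude,
        amplitude_flag=flag,
        secondary_peak_time_months=peaks.secondary_peak_time,
        secondary_relative_amplitude=peaks.secondary_amplitude)
    result = SiteResult(analysis=analysis, trend_model=tr,
                        harmonic_model=harm, peaks=peaks,
                        composite=composite)

    # ---- baseline / anomalies / excess --------------------------------
    if options.anomalies_enabled:
        mask = anom.exclusion_mask(panel,
                                   windows=list(options.exclude_windows),
                                   years=list(options.exclude_years))
        baseline = anom.fit_baseline(
            t, y, exclude=mask, trend_order=options.poly_order,
            frequencies=options.frequencies, level=options.level,
            periodicity=panel.periodicity)
        lower, upper = baseline.prediction_interval(t)
        catalogue = anom.detect_anomalies(
            y, lower, upper, baseline=baseline.baseline_,
            calendar=(panel.years, panel.subunits))
        analysis.anomalies_above = catalogue.n_above
        analysis.anomalies_below = catalogue.n_below
        if mask.any():
            total, _ = anom.excess_burden(y, baseline, t, mask,
                                          reference=options.excess_reference)
            analysis.total_excess = total
        result.baseline = baseline
        result.catalogue = catalogue
    return result


def analyze_panel(panel: TimeSeriesPanel, geo: GeoTable | None = None,
                  options: AnalysisOptions | None = None):
    """Run the per-site analysis over every column of a panel.

    Returns ``(parameter_table, results)``: the per-site export table
    (joined with geography when available) and a dict of full
    :class:`SiteResult` objects keyed by site name.
    """
    options = options or AnalysisOptions()
    results: dict[str, SiteResult] = {}
    for name in panel.site_names:
        results[name] = analyze_site(panel, name, options)
    table = build_parameter_table(
        panel, geo, {name: r.analysis for name, r in results.items()})
    return table, results
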