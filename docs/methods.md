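# Methods

## Time axis and calendar

All fitting happens on fractional-year time `t = year + (subunit − 0.5)/P`,
where `P` is the periodicity (12 for monthly, 52 for weekly data) and the
half-unit offset places each observation at the centre of its interval.
Before any polynomial evaluation the axis is centred at the series
midpoint: with raw calendar years in the thousands a cubic Vandermonde
matrix is catastrophically ill-conditioned, and centring makes fits
invariant (to ~1e−6) under shifting all years by a constant.  Readers
validate strictly — ascending order, gap-free calendar, sub-units in 1..P,
at least two complete years — and *report* defects rather than repairing
them; week-53 rows are accepted with a warning and need no special casing
because everything downstream runs on fractional-year time.

## Trend

Two families, as scikit-learn estimators:

* **PolynomialTrend** (`order`, default 3): OLS on powers 0..order of
  centred time.  Missing observations are excluded from the fit; the trend
  is evaluated on the full calendar, so detrending never creates gaps the
  data did not have.  The order-1 slope (units/year) is the geographically
  comparable trend parameter.
* **SplineTrend** (`stiffness`, default 625): cubic smoothing spline,
  `stiffness` = the roughness-penalty weight λ on ∫f″².  λ → ∞ approaches
  the OLS straight line; λ → 0 approaches interpolation, and λ = 0 itself
  is rejected (interpolating every point is not detrending — it would
  silently remove all signal).  The default 625 puts the smoothing scale
  λ^(1/4) ≈ 5 years, i.e. roughly one effective degree of freedom per five
  years of data.  Numerically the fit is decomposed as (exact OLS line) +
  (spline of the line residual): the penalty's null space is handled in
  closed form, which keeps the large-λ limit stable where a direct
  penalised solve loses the data term to the penalty (observed for
  λ ≳ 1e9 with scipy's banded solver).

Optional pre-smoothing for one-off outbreaks: a centred moving average
(odd window, shrinking symmetrically at edges, renormalising over
available points, all-missing windows stay missing) or a zero-phase
second-order Butterworth low-pass (forward–backward, cutoff in cycles/year
strictly inside (0, P/2)).  The low-pass branch refuses missing values —
the caller chooses the interpolation, same stance as the wavelet module.

## Seasonality

Harmonics at 1, 2 and 4 cycles/year (12-, 6-, 3-month periods) are fitted
by OLS on `{1, cos 2πkt, sin 2πkt}` and reported as amplitude/phase with
the convention `A·cos(2πkt − φ)`, φ ∈ [0, 2π): phase is then monotone in
peak timing, and a pure annual harmonic peaks at month `12·φ₁/2π` (month
0 = start of January).  The frequency set is configurable; duplicates are
rejected.

The seasonal signature is the fitted harmonic sum over one average year,
evaluated on a uniform grid (default resolution 1200, ≥ 10·P enforced).
For peak statistics on the observation scale, the signature is placed
about the series' overall mean when detrending is on.  Peak detection:

* primary peak/trough = global extrema on the periodic grid (wrap-around
  aware; plateau ties report the earliest within-year time);
* when the signature carries its analytic model, extremum positions are
  polished by bounded scalar optimisation (`xatol` 1e−12) around the best
  grid point (`refine=True`, the default).  With multiple harmonics the
  argmax has no closed form, so timing is always read from the composite
  curve, never from φ₁ alone;
* a secondary peak (bimodality) is the highest remaining local maximum at
  least 1 month from the primary on both sides whose topographic
  prominence on the circular domain exceeds 5% of the primary wave height.
  These two thresholds are this package's choice — small enough to keep
  genuinely bimodal signatures, large enough to ignore grid-level ripples.
  Its amplitude uses the global trough, mirroring the primary formula.

Relative amplitude = (peak − trough)/peak.  For `M + A·cos` this is
exactly `2A/(M + A)`.  Values above 1 (negative trough) are flagged, not
clipped; non-positive peaks make the statistic undefined and are flagged
per site rather than silently dropped.

A stationarity diagnostic reports, per complete year, the within-year
argmax of the detrended observations (in months) and the OLS drift slope
of those peak times, with year-to-year differences mapped circularly to
(−6, +6] months so a December/January alternation does not read as a
six-month drift.  The tool only reports drift; splitting the series into
stationary segments is the analyst's decision.

## Baseline, prediction interval, excess

The baseline refits trend and harmonics **jointly** by OLS using only
non-excluded, non-missing points, then evaluates the model over the full
calendar.  It is therefore a pure function of the non-excluded data:
altering excluded observations changes nothing (verified to 1e−12
relative).  Parameter count p = (order + 1) + 2 per harmonic, intercept
counted once; the residual scale is `s² = SSR/(n − p)`.

The interval is a **prediction interval** for a new observation,
`baseline ± t₍₁₋α/₂, n−p₎·s` (level 0.95 default) — the right object for
flagging individual observations, even though interval terminology in the
field is loose.  Residuals are assumed homoscedastic Gaussian; no seasonal
variance model is attempted.  Anomalies are observations *strictly*
outside the bounds (boundary points are not anomalies), catalogued with
direction and magnitude relative to the violated bound, optionally
restricted to the excluded spans or any window.

Excess burden over a window defaults to `Σ max(observed − upper, 0)` —
burden above regular variability.  This under-counts by construction by
roughly (window length) × t-quantile × s; at the package's study
conditions (mean 100, noise 5% of mean, a six-month pulse of 500) the mean
recovery is ≈88%, within the 15% band the simulations check.  The signed
`Σ (observed − baseline)` alternative is nearly unbiased (±5% in the same
simulations) and is provided, clearly non-default.

## Wavelets

Standard Morlet (ω₀ = 6) continuous transform: mean removal, zero-padding
to the next power of two, frequency-domain product with analytic daughter
spectra at scales `s_j = s0·2^(j·dj)` (s0 = 2dt, dj = 0.25), power = |W|²,
Fourier period ≈ 1.033·s, cone of influence from the √2·s e-folding time
(zero at the series ends).  The global spectrum averages power over times
inside the cone only.  Missing values are refused rather than imputed —
wavelet power is sensitive to the imputation scheme, so that choice stays
with the caller.  Tests cross-check the FFT implementation against an
explicit O(N²) time-domain circular convolution with the same daughter
kernels (agreement ~1e−13, asserted at 1e−6).

## Synthetic data

`SynthConfig`/`generate_panel` emulate exactly the structure the
decomposition assumes: polynomial trend + stationary harmonics +
homoscedastic Gaussian noise + optional injected pulses + optional
missingness (never inside an injection, so injected totals stay exact),
with sites on a latitude gradient in peak timing.  Default conditions,
chosen once as a plausible pneumonia-and-influenza mortality panel: mean
level 100 per month, amplitudes (3, 1, 0.5) at 1/2/4 cycles/year, noise 5%
of the mean, peak timing 6 − 0.1·latitude months, higher harmonics
phase-locked to the annual peak so default signatures are unimodal.
`truth_peak_parameters` supplies the independent peak oracle: plain
exhaustive argmax/argmin on a 100 000-point grid of the configured
signature.

Because the generator matches the model, passing tests demonstrate
correctness of the machinery, not robustness to real-data violations:
overdispersed counts, seasonally varying variance, autocorrelated
residuals, reporting artefacts and irregular calendars are all outside
what these simulations exercise.

## Problem sizes and numerical choices

The test suite and the acceptance script run in seconds: the heaviest
checks use 200 replicates of 50-year monthly panels (interval coverage,
pooled over 120 000 points; the fit is a single 600×10 least squares per
replicate) and 100 random signatures against the 1e5-point grid oracle.
A 1e5-grid oracle's peak *value* sits below the analytic maximum by up to
½·f″·(step/2)² ≈ 2e−8 for these amplitudes, so value agreement at 1e−9 is
asserted detector-vs-oracle on the same grid (`refine=False`), while
refined times are additionally required to stay within one oracle step;
the closed-form amplitude checks (`2A/(M+A)` to 1e−9) exercise the refined
path.  Least squares uses `numpy.linalg.lstsq` throughout; t quantiles
come from scipy.

## Known limitations

* No forecasting/extrapolation, reproductive-number estimation, or
  covariate regression — deliberately out of scope.
* One fixed integer periodicity per panel; no irregular or sub-daily
  cadences.
* Homoscedastic Gaussian residuals; counts are not modelled as counts.
* Maps draw plain lat/lon axes (no basemap assets, no network).
* The wavelet module offers only the Morlet ω₀ = 6 mother.
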