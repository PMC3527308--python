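# episignal

Epidemiological surveillance series — monthly or weekly counts of deaths or
cases collected over many years at many sites — can be described by three
components: a long-term **trend**, a recurring **seasonal** pattern, and
**anomalies** (epidemics, pandemics, artefacts).  `episignal` decomposes
multi-site panels of such series, extracts comparable seasonal parameters
per site, estimates excess burden against an exclusion-window baseline,
computes Morlet wavelet power spectra, and renders geographic comparison
figures (bubble maps, latitudinal scatterplots, heat grids).  It is aimed
at epidemiologists and public-health analysts who want these standard
descriptive analyses scriptable and reproducible.

## The model

Observations on a fractional-year axis *t* (one column per site) are fitted
as

```
y(t) = p(t) + m + Σₖ Aₖ·cos(2πk·t − φₖ) + ε,      k ∈ {1, 2, 4} cycles/year
```

* `p(t)` — polynomial trend (cubic by default; a smoothing-spline
  alternative is available for flexible detrending).  The order-1 slope is
  the comparable "linear trend" in units per year.
* The harmonics (12-, 6- and 3-month periods) form a partial Fourier
  series, reported as amplitude `Aₖ` and phase `φₖ` rather than sine/cosine
  coefficients; a pure annual harmonic peaks at month `12·φ₁/2π`.
* The **seasonal signature** `m + Σₖ Aₖ·cos(2πk·u − φₖ)` over one average
  year yields the headline parameters: primary (and, for bimodal
  signatures, secondary) peak timing, and the **relative amplitude**
  `(peak − trough) / peak`.
* The **baseline** refits trend + harmonics jointly while *excluding*
  user-specified spans (e.g. pandemic years); a prediction interval
  `baseline ± t₍₁₋α/₂, n−p₎ · s` flags anomalies, and the excess burden over
  a window is `Σ max(observed − upper bound, 0)` (a signed
  observed − baseline alternative is provided).
* The Morlet (ω₀ = 6) continuous wavelet transform localises spectral power
  in time, revealing e.g. a shift from annual to biennial epidemics.

Estimators follow scikit-learn conventions (`PolynomialTrend`,
`SplineTrend`, `HarmonicRegression`, `SeasonalBaseline`: `fit` /
`predict` / `get_params`, fitted attributes with trailing underscores), so
they compose with sklearn tooling; thin functions (`fit_harmonics`,
`fit_baseline`, …) wrap them.

## Input layout

* **Time-series file** (CSV or workbook, one header row): column 1 = year,
  column 2 = sub-year unit (1..P, e.g. month 1–12), columns 3+ = one series
  per site.  Rows must be in ascending order with no calendar gaps; missing
  observations are `NaN` (also accepted: `nan`, `NA`, empty).  Workbook
  sheets can carry a third dimension such as age groups.
* **Geolocation file** (headerless): site name (matching the series
  headers), latitude, longitude in decimal degrees, optional group label.

## Worked example

```python
import episignal as ep

cfg = ep.SynthConfig(
    seed=42, n_sites=5, years=15,
    injections=[ep.Injection(site=2, start=(2009, 5), end=(2010, 4), total=600.0)],
)
panel, geo, truth = ep.generate_panel(cfg)

opts = ep.AnalysisOptions(exclude_years=(2009, 2010))
table, results = ep.analyze_panel(panel, geo, opts)
print(table[["site", "latitude", "peak_time_months", "relative_amplitude",
             "linear_trend", "total_excess", "anomalies_above"]]
      .round(3).to_string(index=False))
```

```
 site  latitude  peak_time_months  relative_amplitude  linear_trend  total_excess  anomalies_above
siteA     -35.0             9.773               0.052         0.758         3.743                6
siteB     -25.0             8.701               0.073         0.823         3.192                5
siteC     -15.0             7.946               0.068         1.233       494.756               14
siteD      -5.0             6.473               0.078         0.535         1.334                5
siteE       5.0             5.810               0.072         0.627         0.000                4
```

The five simulated sites have true peak months 9.5, 8.5, 7.5, 6.5, 5.5 (a
−0.1 month/degree latitudinal gradient) and a true relative amplitude of
0.068; the fitted peak timings and amplitudes recover these up to noise.
Site C received an injected pandemic of 600 excess deaths inside the
excluded 2009–2010 window; the upper-bound excess estimate recovers ≈495
(it deliberately counts only burden *above* the prediction interval, so it
under-counts by about the interval margin), and the site stands out in the
anomaly counts.  The same analysis runs from the shell:

```bash
episignal simulate --config sim.yaml --out sim/
episignal analyze --timeseries sim/timeseries.csv --geo sim/geolocation.csv \
    --exclude-years 2009,2010 --wavelet --out results/
```

writing `parameters.csv`, a bubble map, a latitude scatterplot, a heat
grid, wavelet global spectra and a checksummed `manifest.json`.

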