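"""Harmonic fitting, seasonal signature, peak detection, stationarity."""

import numpy as np
import pytest

import episignal as ep
from episignal.seasonality import HarmonicModel

from conftest import make_panel


def monthly_time(years=10):
    n = years * 12
    return 2000 + (np.arange(n) // 12) + ((np.arange(n) % 12) + 0.5) / 12


def grid_oracle(model, resolution=100_000):
    """Independent exhaustive-search oracle: plain global argmax/argmin."""
    u = np.arange(resolution) / resolution
    v = model.signature_value(u)
    i, j = int(np.argmax(v)), int(np.argmin(v))
    return u[i], v[i], u[j], v[j]


def circ_diff(a, b, period=2 * np.pi):
    return (a - b + period / 2) % period - period / 2


class TestHarmonicFit:
    def test_pure_annual_sinusoid_recovered(self):
        t = monthly_time(10)
        y = 3 * np.cos(2 * np.pi * t - np.pi / 3)
        m = ep.fit_harmonics(t, y)
        assert m.amplitudes[0] == pytest.approx(3.0, abs=1e-6)
        assert circ_diff(m.phases[0], np.pi / 3) == pytest.approx(0, abs=1e-6)
        assert m.amplitudes[1] == pytest.approx(0.0, abs=1e-6)
        assert m.amplitudes[2] == pytest.approx(0.0, abs=1e-6)
        assert m.mean_level == pytest.approx(0.0, abs=1e-6)

    def test_zero_series_gives_zero_model(self):
        m = ep.fit_harmonics(monthly_time(4), np.zeros(48))
        np.testing.assert_allclose(m.amplitudes, 0, atol=1e-10)
        assert m.mean_level == pytest.approx(0.0, abs=1e-10)

    def test_pure_semiannual_lands_on_second_harmonic(self):
        t = monthly_time(10)
        m = ep.fit_harmonics(t, 2 * np.cos(4 * np.pi * t))
        assert m.amplitudes[1] == pytest.approx(2.0, abs=1e-6)
        assert m.amplitudes[0] == pytest.approx(0.0, abs=1e-6)
        assert m.amplitudes[2] == pytest.approx(0.0, abs=1e-6)

    def test_duplicate_frequencies_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ep.fit_harmonics(monthly_time(4), np.ones(48),
                             frequencies=(1, 1, 2))

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            ep.fit_harmonics(monthly_time(1), np.ones(12))

    @pytest.mark.parametrize("sigma", [0.0, 0.5])
    def test_parameter_recovery_improves_with_less_noise(self, sigma):
        rng = np.random.default_rng(17)
        t = monthly_time(20)
        true = HarmonicModel(mean_level=5.0, frequencies=(1, 2, 4),
                             amplitudes=[3.0, 1.0, 0.5],
                             phases=[1.0, 2.0, 3.0])
        y = true.signature_value(t) + rng.normal(0, sigma, len(t))
        m = ep.fit_harmonics(t, y)
        se = sigma * np.sqrt(2 / len(t))
        tol = 1e-6 if sigma == 0 else 4 * se
        np.testing.assert_allclose(m.amplitudes, true.amplitudes, atol=tol)
        for k in range(3):
            # circular phase SE ~ coefficient SE / amplitude
            ptol = 1e-6 if sigma == 0 else 4 * se / true.amplitudes[k]
            assert abs(circ_diff(m.phases[k], true.phases[k])) < ptol


class TestSignature:
    def test_flat_for_zero_amplitudes(self):
        m = HarmonicModel(4.2, (1, 2, 4), [0, 0, 0], [0, 0, 0])
        sig = ep.seasonal_signature(m)
        np.testing.assert_allclose(sig.values, 4.2)

    def test_maximum_at_phase_zero(self):
        m = HarmonicModel(0.0, (1,), [1.0], [0.0])
        sig = ep.seasonal_signature(m)
        assert sig.grid[np.argmax(sig.values)] < 1 / sig.resolution + 1e-12

    def test_half_year_symmetry_of_pure_semiannual(self):
        m = HarmonicModel(1.0, (2,), [0.7], [1.3])
        sig = ep.seasonal_signature(m, resolution=1200)
        half = sig.resolution // 2
        np.testing.assert_allclose(sig.values, np.roll(sig.values, half),
                                   atol=1e-9)

    def test_resolution_floor_enforced(self):
        m = HarmonicModel(1.0, (1,), [1.0], [0.0], periodicity=52)
        with pytest.raises(ValueError, match="resolution"):
            ep.seasonal_signature(m, resolution=300)


class TestFindPeaks:
    def test_pure_annual_peak_in_july(self):
        phi = 2 * np.pi * 6.5 / 12
        m = HarmonicModel(10.0, (1,), [2.0], [phi])
        pk = ep.find_peaks(ep.seasonal_signature(m))
        assert pk.peak_time == pytest.approx(6.5, abs=0.02)
        assert pk.secondary_peak_time is None
        assert pk.amplitude == pytest.approx(4 / 12, abs=1e-9)

    def test_bimodal_signature_reports_secondary(self):
        m = HarmonicModel(5.0, (1, 2), [1.0, 0.8], [0.0, 0.0])
        sig = ep.seasonal_signature(m, resolution=2400)
        pk = ep.find_peaks(sig)
        u_pk, v_pk, _, _ = grid_oracle(m)
        assert abs(circ_diff(pk.peak_time, 12 * u_pk, period=12.0)) \
            <= 12 / 100_000
        assert pk.peak_value == pytest.approx(v_pk, abs=1e-6)
        assert pk.bimodal
        assert pk.secondary_peak_time == pytest.approx(6.0, abs=0.05)
        assert pk.peak_value >= pk.secondary_peak_value

    def test_constant_signature_degenerate(self):
        m = HarmonicModel(3.0, (1,), [0.0], [0.0])
        pk = ep.find_peaks(ep.seasonal_signature(m))
        assert pk.degenerate
        assert pk.amplitude == 0.0
        assert pk.peak_time is None

    def test_agrees_with_exhaustive_oracle_on_random_models(self):
        rng = np.random.default_rng(42)
        res = 100_000
        for _ in range(30):
            m = HarmonicModel(mean_level=rng.uniform(5, 15),
                              frequencies=(1, 2, 4),
                              amplitudes=rng.uniform(0.2, 3.0, 3),
                              phases=rng.uniform(0, 2 * np.pi, 3))
            sig = ep.seasonal_signature(m, resolution=res)
            pk = ep.find_peaks(sig, refine=False)
            u_pk, v_pk, u_tr, v_tr = grid_oracle(m, res)
            assert pk.peak_time == pytest.approx(12 * u_pk, abs=12 / res)
            assert pk.peak_value == pytest.approx(v_pk, abs=1e-9)
            assert pk.trough_value == pytest.approx(v_tr, abs=1e-9)
            # refined times stay within one oracle step of the grid argmax
            pk_r = ep.find_peaks(sig, refine=True)
            assert abs(circ_diff(pk_r.peak_time, 12 * u_pk, period=12.0)) \
                <= 12 / res

    def test_phase_convention_peak_time_of_pure_annual(self):
        rng = np.random.default_rng(3)
        for phi in rng.uniform(0, 2 * np.pi, 10):
            m = HarmonicModel(10.0, (1,), [1.0], [phi])
            pk = ep.find_peaks(ep.seasonal_signature(m))
            expect = 12 * phi / (2 * np.pi)
            assert abs(circ_diff(pk.peak_time, expect, period=12.0)) < 1e-6


class TestRelativeAmplitude:
    def test_direct_formula(self):
        assert ep.relative_amplitude(13, 7) == pytest.approx(6 / 13)

    def test_flat_wave_is_zero(self):
        assert ep.relative_amplitude(4.0, 4.0) == 0.0

    def test_negative_trough_exceeds_one_unclipped(self):
        assert ep.relative_amplitude(4, -1) == pytest.approx(1.25)
        m = HarmonicModel(1.0, (1,), [2.0], [0.0])  # trough at -1
        pk = ep.find_peaks(ep.seasonal_signature(m))
        assert pk.amplitude_exceeds_one
        assert pk.amplitude == pytest.approx(4 / 3, abs=1e-6)

    def test_non_positive_peak_rejected(self):
        with pytest.raises(ValueError, match="non-positive peak"):
            ep.relative_amplitude(0.0, -1.0)

    def test_closed_form_two_a_over_m_plus_a(self):
        # for M + A*cos the peak is M+A, trough M-A: amplitude = 2A/(M+A)
        rng = np.random.default_rng(8)
        for _ in range(20):
            M = rng.uniform(1, 20)
            A = rng.uniform(0.01, 1) * M
            m = HarmonicModel(M, (1,), [A], [rng.uniform(0, 2 * np.pi)])
            pk = ep.find_peaks(ep.seasonal_signature(m))
            assert pk.amplitude == pytest.approx(2 * A / (M + A), abs=1e-9)


class TestComposite:
    def test_zero_harmonics_equals_trend(self):
        t = monthly_time(5)
        tr = ep.fit_polynomial_trend(t, 1 + 0.1 * t, order=1)
        h = HarmonicModel(0.0, (1, 2, 4), [0, 0, 0], [0, 0, 0])
        np.testing.assert_allclose(ep.composite_model(tr, h, t), tr.fitted_)

    def test_zero_trend_plus_sinusoid(self):
        t = monthly_time(5)
        h = HarmonicModel(0.0, (1,), [2.0], [0.5])
        comp = ep.composite_model(np.zeros(len(t)), h, t)
        np.testing.assert_allclose(comp, 2 * np.cos(2 * np.pi * t - 0.5),
                                   atol=1e-9)

    def test_composite_tracks_noisefree_truth(self):
        cfg = ep.SynthConfig(seed=12, n_sites=1, years=20,
                             noise_frac_of_mean=0.002)  # sigma ~5% of seasonal amp
        panel, _, truth = ep.generate_panel(cfg)
        t, y = panel.time, panel.series(0)
        tr = ep.fit_polynomial_trend(t, y)
        harm = ep.fit_harmonics(t, ep.detrend(y, tr))
        comp = ep.composite_model(tr, harm, t)
        rho = np.corrcoef(comp, truth.deterministic[:, 0])[0, 1]
        assert rho > 0.999

    def test_misaligned_calendars_rejected(self):
        h = HarmonicModel(0.0, (1,), [1.0], [0.0])
        with pytest.raises(ValueError, match="length"):
            ep.composite_model(np.zeros(10), h, monthly_time(1))


class TestStationarity:
    @staticmethod
    def _panel_with_drift(drift_months_per_year, seed=21, years=12,
                          peak0=6.0):
        n = years * 12
        yy = 2000 + np.arange(n) // 12
        ss = np.arange(n) % 12 + 1
        t = yy + (ss - 0.5) / 12
        rng = np.random.default_rng(seed)
        peak_month = (peak0 + drift_months_per_year * (yy - yy[0])) % 12
        phi = 2 * np.pi * peak_month / 12
        y = 100 + 10 * np.cos(2 * np.pi * t - phi) + rng.normal(0, 0.5, n)
        return ep.TimeSeriesPanel(years=yy, subunits=ss, periodicity=12,
                                  site_names=["A"], values=y)

    def test_stationary_series_small_drift(self):
        panel = self._panel_with_drift(0.0)
        d = ep.stationarity_diagnostic(panel)
        assert abs(d.drift_slope) < 0.1

    def test_drifting_peak_detected(self):
        panel = self._panel_with_drift(0.5)
        d = ep.stationarity_diagnostic(panel)
        assert d.drift_slope == pytest.approx(0.5, abs=0.1)

    def test_december_january_alternation_unwraps(self):
        panel = self._panel_with_drift(0.0)
        n = panel.n_rows
        t = panel.time
        # peak alternates between late December and early January
        phis = np.where((panel.years - 2000) % 2 == 0,
                        2 * np.pi * 11.8 / 12, 2 * np.pi * 0.2 / 12)
        y = 100 + 10 * np.cos(2 * np.pi * t - phis)
        panel = ep.TimeSeriesPanel(panel.years, panel.subunits, 12, ["A"], y)
        d = ep.stationarity_diagnostic(panel)
        assert abs(d.drift_slope) < 1.0  # nowhere near +/- 6 months/year

    def test_too_few_years_rejected(self):
        panel = self._panel_with_drift(0.0, years=3)
        with pytest.raises(ValueError, match="4 complete years"):
            ep.stationarity_diagnostic(panel)


class TestAverageYear:
    def test_two_identical_years(self):
        year = np.arange(1.0, 13.0)
        panel = make_panel(years=2, values=np.tile(year, 2)[:, None])
        out = ep.average_year_by_category([panel])
        np.testing.assert_allclose(out[:, 0], year)

    def test_constant_categories(self):
        p1 = make_panel(values=np.full((24, 1), 2.0))
        p2 = make_panel(values=np.full((24, 1), 5.0))
        out = ep.average_year_by_category([p1, p2])
        np.testing.assert_allclose(out[:, 0], 2.0)
        np.testing.assert_allclose(out[:, 1], 5.0)

    def test_missing_january_excluded_from_mean(self):
        vals = np.tile(np.arange(1.0, 13.0), 3)[:, None].copy()
        vals[0, 0] = np.nan          # first January missing
        vals[12, 0] = 7.0            # second January differs
        panel = make_panel(years=3, values=vals)
        out = ep.average_year_by_category([panel])
        assert out[0, 0] == pytest.approx((7.0 + 1.0) / 2)

    def test_calendar_mismatch_rejected(self):
        p1 = make_panel(years=2)
        p2 = make_panel(years=3)
        with pytest.raises(ValueError, match="calendar"):
            ep.average_year_by_category([p1, p2])
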