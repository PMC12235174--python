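"""Periodogram, cosinor and classification behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from circalum.rhythm import (
    ConstantTraceError,
    PeriodogramSpec,
    RhythmCall,
    RhythmError,
    classify,
    cosinor_fit,
    find_peak_phases,
    lomb_scargle,
    percent_rhythmic,
)
from helpers import make_cosine_trace


class TestLombScargle:
    def test_single_tone_peak_within_one_grid_step(self):
        for period in (20.0, 24.0, 27.0, 30.0):
            tr = make_cosine_trace(period=period, duration=120.0)
            pg = lomb_scargle(tr)
            assert abs(pg.peak_period - period) <= pg.grid_step

    def test_dominant_tone_wins(self):
        t = np.arange(0, 120, 0.5)
        y = 2.0 * np.cos(2 * np.pi * t / 27.0) + 1.0 * np.cos(2 * np.pi * t / 24.0)
        tr = make_cosine_trace().with_values(y)
        pg = lomb_scargle(tr)
        assert abs(pg.peak_period - 27.0) <= pg.grid_step

    def test_matches_dft_periodogram_on_even_sampling(self):
        """At the Fourier frequencies of an evenly sampled record, the LS
        power equals the classical DFT periodogram (independent oracle)."""
        rng = np.random.default_rng(5)
        dt, n = 0.5, 240
        t = np.arange(n) * dt
        y = 1.5 * np.cos(2 * np.pi * t / 24.0 + 0.7) + rng.normal(0, 0.5, n)
        yc = y - y.mean()
        span = t[-1] - t[0]
        # Fourier frequencies inside the search window (k/(n*dt))
        ks = [k for k in range(1, n // 2) if 18.0 <= n * dt / k <= 37.0]
        var = np.var(y, ddof=1)
        for k in ks:
            f = k / (n * dt)
            dft = np.abs(np.sum(yc * np.exp(-2j * np.pi * f * t))) ** 2 / n
            spec = PeriodogramSpec(period_min=1 / f - 1e-9, period_max=1 / f + 1e-9,
                                   oversampling=1.0)
            tr = make_cosine_trace(duration=n * dt).with_values(y)
            ls = lomb_scargle(tr, spec)
            # classical Scargle power at a Fourier freq = DFT periodogram / variance
            assert ls.powers[0] == pytest.approx(dft / var, abs=1e-8)
        assert span > 0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        tr = make_cosine_trace(noise_sd=0.3, seed=7)
        p0 = lomb_scargle(tr).powers
        p1 = lomb_scargle(tr.with_values(a * tr.values + b)).powers
        np.testing.assert_allclose(p0, p1, rtol=1e-9)

    def test_time_translation_invariance(self):
        tr = make_cosine_trace(noise_sd=0.2, seed=3)
        shifted = make_cosine_trace().with_values(tr.values)
        shifted.times = tr.times + 13.0
        np.testing.assert_allclose(
            lomb_scargle(tr).powers, lomb_scargle(shifted).powers, rtol=1e-9
        )

    def test_constant_trace_errors(self):
        tr = make_cosine_trace().with_values(np.full(240, 3.0))
        with pytest.raises(ConstantTraceError):
            lomb_scargle(tr)

    def test_short_trace_errors(self):
        tr = make_cosine_trace(duration=10.0)
        with pytest.raises(RhythmError):
            lomb_scargle(tr)


class TestCosinor:
    def test_exact_recovery_noiseless(self):
        tr = make_cosine_trace(period=24.0, peak_time=6.0, mesor=5.0, amplitude=2.0)
        fit = cosinor_fit(tr, period_init=24.0)
        assert fit.mesor == pytest.approx(5.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.period == pytest.approx(24.0, abs=1e-5)
        assert fit.acrophase_zt == pytest.approx(6.0, abs=1e-5)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("period", [20.0, 24.0, 27.0, 30.0])
    def test_free_period_recovery_across_taus(self, period):
        tr = make_cosine_trace(period=period, duration=120.0)
        fit = cosinor_fit(tr, period_init=period + 0.5)
        assert fit.period == pytest.approx(period, rel=1e-4)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-4)
        assert fit.mesor == pytest.approx(5.0, rel=1e-4)

    def test_negative_cosine_reported_as_positive_amplitude(self):
        t = np.arange(0, 120, 0.5)
        tr = make_cosine_trace().with_values(5.0 - 2.0 * np.cos(2 * np.pi * t / 24.0))
        fit = cosinor_fit(tr, period_init=24.0, free_period=False)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_zt == pytest.approx(12.0, abs=1e-6)

    def test_fixed_tau_closed_form_matches_iterative_minimizer(self):
        tr = make_cosine_trace(noise_sd=0.4, seed=11)
        fit = cosinor_fit(tr, period_init=24.0, free_period=False)

        def resid(params):
            m, bc, bs = params
            w = 2 * np.pi / 24.0
            return tr.values - (m + bc * np.cos(w * tr.times) + bs * np.sin(w * tr.times))

        sol = least_squares(resid, x0=[0.0, 1.0, 0.0])
        assert fit.sse == pytest.approx(2 * sol.cost, abs=1e-8)

    def test_noisy_fit_beats_grid_search_oracle(self):
        """Free-tau profile fit reaches the SSE of an exhaustive (tau, phi)
        grid search on a seeded noisy trace."""
        tr = make_cosine_trace(period=24.7, noise_sd=0.4, seed=13, duration=120.0)
        fit = cosinor_fit(tr, period_init=24.0)
        t, y = tr.times, tr.values
        best = np.inf
        best_tau = best_phi = None
        for tau in np.arange(23.5, 26.0, 0.01):
            w = 2 * np.pi / tau
            for phi in np.arange(0.0, tau, 0.05):
                model_shape = np.cos(w * (t - phi))
                X = np.column_stack([np.ones_like(t), model_shape])
                coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = float(res[0]) if res.size else float(
                    np.sum((y - X @ coef) ** 2))
                if sse < best:
                    best, best_tau, best_phi = sse, tau, phi
        assert fit.sse <= best * (1 + 1e-3)
        assert fit.period == pytest.approx(best_tau, abs=0.02)
        assert fit.acrophase_abs == pytest.approx(best_phi, abs=0.06)

    def test_constant_trace_errors(self):
        tr = make_cosine_trace().with_values(np.full(240, 1.0))
        with pytest.raises(ConstantTraceError):
            cosinor_fit(tr, period_init=24.0)


class TestClassification:
    @pytest.mark.parametrize(
        "condition,tau,r2,expected",
        [
            ("freerun", 24.9, 0.8, "Circadian"),
            ("freerun", 24.9, 0.5, "Circadian"),  # R^2 boundary inclusive
            ("freerun", 24.9, 0.499, "Arrhythmic"),
            ("freerun", 18.0, 0.9, "Circadian"),  # period bounds inclusive
            ("freerun", 37.0, 0.9, "Circadian"),
            ("freerun", 17.5, 0.9, "Arrhythmic"),
            ("freerun", 37.5, 0.9, "Arrhythmic"),
            ("entrained", 24.0, 0.5, "Synchronized"),
            ("entrained", 25.0, 0.9, "Synchronized"),  # |tau-24| <= tol inclusive
            ("entrained", 25.1, 0.9, "Arrhythmic"),
            ("entrained", 24.0, 0.4, "Arrhythmic"),
        ],
    )
    def test_rule_table(self, condition, tau, r2, expected):
        fit = _fake_fit(tau, r2)
        assert classify(fit, condition).label == expected

    def test_labels_respect_condition(self):
        fit = _fake_fit(24.0, 0.9)
        assert classify(fit, "entrained").label == "Synchronized"
        assert classify(fit, "freerun").label == "Circadian"

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(r2_lo=st.floats(0.0, 1.0), r2_hi=st.floats(0.0, 1.0),
           tau=st.floats(18.0, 37.0))
    def test_monotone_in_r_squared(self, r2_lo, r2_hi, tau):
        lo, hi = sorted([r2_lo, r2_hi])
        if classify(_fake_fit(tau, lo), "freerun").label == "Circadian":
            assert classify(_fake_fit(tau, hi), "freerun").label == "Circadian"


def _fake_fit(tau, r2):
    from circalum.rhythm import CosinorFit

    return CosinorFit(mesor=0.0, amplitude=1.0, period=tau, acrophase_abs=0.0,
                      acrophase_zt=0.0, r_squared=r2, sse=0.0, n=100)


class TestPeakPhases:
    def test_noiseless_cosine_peaks_at_acrophase(self):
        tr = make_cosine_trace(period=24.0, peak_time=18.0, zt_offset=0.0)
        phases = find_peak_phases(tr, (0.0, 96.0))
        assert len(phases) == 4
        for ph in phases:
            assert ph == pytest.approx(18.0, abs=0.25 + 1e-9)

    def test_two_day_window_two_peaks(self):
        tr = make_cosine_trace(period=24.0, peak_time=6.0, zt_offset=0.0)
        assert len(find_peak_phases(tr, (0.0, 48.0))) == 2

    def test_first_only_returns_first_cycle_peak(self):
        tr = make_cosine_trace(period=24.0, peak_time=6.0, zt_offset=0.0)
        assert find_peak_phases(tr, (0.0, 96.0), first_only=True) == [
            pytest.approx(6.0, abs=0.25)
        ]

    def test_constant_trace_errors(self):
        tr = make_cosine_trace().with_values(np.full(240, 1.0))
        with pytest.raises(ConstantTraceError):
            find_peak_phases(tr, (0.0, 48.0))

    def test_sub_day_window_errors(self):
        tr = make_cosine_trace()
        with pytest.raises(RhythmError):
            find_peak_phases(tr, (0.0, 12.0))


class TestPercentRhythmic:
    def _calls(self, k, n, condition="freerun"):
        good = "Circadian" if condition == "freerun" else "Synchronized"
        return [
            RhythmCall(label=good if i < k else "Arrhythmic", condition=condition)
            for i in range(n)
        ]

    def test_exact_fraction(self):
        assert percent_rhythmic(self._calls(3, 10)) == 30.0

    def test_zero_and_full(self):
        assert percent_rhythmic(self._calls(0, 10), decimals=0) == 0.0
        assert percent_rhythmic(self._calls(10, 10), decimals=0) == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percent_rhythmic([])
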