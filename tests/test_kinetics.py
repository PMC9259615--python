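"""Rate extraction: normalization, differencing, Gaussian window, logistic fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from penosome import kinetics as K
from penosome.errors import ConfigError, NumericalError
from penosome.traces import KineticTrace

from conftest import make_logistic


class TestNormalize:
    def test_to_point_on_constant_trace_gives_ones(self):
        tr = KineticTrace(t=np.arange(10.0), A=np.full(10, 7.0))
        out = K.normalize_trace(tr, "to_point", t_ref=5.0)
        np.testing.assert_array_equal(out.A, 1.0)

    def test_minmax_three_points(self):
        tr = KineticTrace(t=np.arange(3.0), A=np.array([0.0, 5.0, 10.0]))
        out = K.normalize_trace(tr, "minmax")
        np.testing.assert_allclose(out.A, [0.0, 0.5, 1.0])

    def test_zero_reference_raises(self):
        tr = KineticTrace(t=np.arange(5.0), A=np.zeros(5))
        with pytest.raises(NumericalError):
            K.normalize_trace(tr, "to_point", t_ref=0.0)

    def test_rate_invariant_under_positive_scaling(self):
        tr = make_logistic(L=100.0, k=-0.08, x0=60.0, normalized=False)
        r1 = K.estimate_rate(tr)
        r2 = K.estimate_rate(tr.with_signal(3.5 * tr.A))
        assert r1.rate == pytest.approx(r2.rate, rel=1e-6)

    def test_rate_invariant_under_time_shift(self):
        t = np.linspace(0, 150, 151)
        tr1 = make_logistic(k=-0.08, x0=60.0, t=t)
        tr2 = KineticTrace(t=t, A=make_logistic(k=-0.08, x0=90.0, t=t).A,
                           normalized=True)
        r1, r2 = K.estimate_rate(tr1), K.estimate_rate(tr2)
        assert r1.rate == pytest.approx(r2.rate, rel=1e-4)
        assert r2.x0 - r1.x0 == pytest.approx(30.0, abs=0.5)


class TestDifferences:
    def test_linear_trace_gives_constant_differences(self):
        t = np.arange(0.0, 30.0, 3.0)
        tr = KineticTrace(t=t, A=2.5 * t)
        tm, d = K.difference_series(tr)
        np.testing.assert_allclose(d, 2.5 * 3.0)
        np.testing.assert_allclose(tm, t[:-1] + 1.5)

    def test_constant_trace_gives_zeros(self):
        tr = KineticTrace(t=np.arange(5.0), A=np.full(5, 3.0))
        _, d = K.difference_series(tr)
        np.testing.assert_array_equal(d, 0.0)

    def test_difference_peak_sits_at_logistic_inflection(self):
        tr = make_logistic(k=-0.1, x0=60.0)
        tm, d = K.difference_series(tr)
        dt = tr.t[1] - tr.t[0]
        assert abs(tm[np.argmax(d)] - 60.0) <= dt

    def test_too_short_series_raises(self):
        with pytest.raises(ConfigError):
            K.difference_series(KineticTrace(t=[0.0, 1.0], A=[0.0, 1.0]))


class TestGaussianWindow:
    def test_exact_gaussian_recovered(self):
        x = np.linspace(0, 25, 120)
        d = 2.0 * np.exp(-(((x - 10.0) / 4.0) ** 2))
        fit = K.fit_gaussian_difference(x, d)
        assert fit.converged
        assert fit.a1 == pytest.approx(2.0, abs=1e-6)
        assert fit.b1 == pytest.approx(10.0, abs=1e-6)
        assert fit.c1 == pytest.approx(4.0, abs=1e-6)

    def test_zero_series_does_not_converge(self):
        fit = K.fit_gaussian_difference(np.arange(10.0), np.zeros(10))
        assert not fit.converged

    def test_logistic_differences_center_on_inflection(self):
        tr = make_logistic(k=-0.1, x0=60.0)
        tm, d = K.difference_series(tr)
        fit = K.fit_gaussian_difference(tm, d)
        assert fit.converged
        assert abs(fit.b1 - 60.0) <= tr.t[1] - tr.t[0]

    def test_midpoint_at_full_threshold_is_center(self):
        fit = K.GaussianDiffFit(2.0, 10.0, 4.0, converged=True)
        assert K.midpoint_to_decay(fit, 2.0) == pytest.approx(10.0)

    def test_zero_width_collapses_to_center(self):
        fit = K.GaussianDiffFit(2.0, 10.0, 0.0, converged=True)
        assert K.midpoint_to_decay(fit, 1.0) == pytest.approx(10.0)

    def test_half_maximum_crossing_matches_numeric_inversion(self):
        fit = K.GaussianDiffFit(2.0, 10.0, 4.0, converged=True)
        closed = K.midpoint_to_decay(fit, 1.0)
        g = lambda x: 2.0 * np.exp(-(((x - 10.0) / 4.0) ** 2)) - 1.0
        numeric = optimize.brentq(g, 10.0, 50.0, xtol=1e-12)
        assert closed == pytest.approx(10.0 + 4.0 * np.sqrt(np.log(2.0)),
                                       abs=1e-9)
        assert closed == pytest.approx(numeric, abs=1e-9)
        assert closed == pytest.approx(13.331, abs=1e-3)

    def test_threshold_above_amplitude_rejected(self):
        fit = K.GaussianDiffFit(2.0, 10.0, 4.0, converged=True)
        with pytest.raises(ConfigError):
            K.midpoint_to_decay(fit, 3.0)

    @settings(deadline=None, max_examples=50)
    @given(a1=st.floats(0.1, 10), b1=st.floats(-50, 200), c1=st.floats(0.5, 50),
           frac=st.floats(0.05, 1.0))
    def test_inversion_property(self, a1, b1, c1, frac):
        """The closed form inverts the Gaussian exactly at any threshold."""
        f = frac * a1
        t_f = K.midpoint_to_decay(K.GaussianDiffFit(a1, b1, c1, True), f)
        val = a1 * np.exp(-(((t_f - b1) / c1) ** 2))
        assert val == pytest.approx(f, rel=1e-9)


class TestLogisticFit:
    def test_truncated_exponential_phase_recovers_rate(self):
        """Data ending well before the inflection still pin down |k|."""
        t = np.arange(0.0, 90.1, 3.0)
        tr = make_logistic(L=1.0, k=-0.1, x0=120.0, t=t)
        fit = K.fit_logistic(tr, t_f=90.0)
        assert fit.rate == pytest.approx(0.1, abs=1e-3)

    def test_constant_trace_flags_no_growth(self):
        tr = KineticTrace(t=np.arange(20.0), A=np.full(20, 5.0))
        est = K.estimate_rate(tr)
        assert est.no_growth and est.rate == 0.0

    def test_monte_carlo_recovery_at_buffer_rate(self):
        """Replicates at the reference buffer rate 0.092/min with 2% noise."""
        rates = []
        for i in range(100):
            tr = make_logistic(L=1.0, k=-0.092, x0=80.0,
                               t=np.linspace(0, 180, 121),
                               noise_sd=0.02, seed=i)
            rates.append(K.estimate_rate(tr).rate)
        assert np.mean(rates) == pytest.approx(0.092, rel=0.05)

    def test_full_pipeline_on_simulated_autocatalysis(self, autocat_traceset):
        tr = autocat_traceset.compartment_traces()[0]
        est = K.estimate_rate(tr, rate_mode="slope")
        assert est.window_source == "gaussian"
        assert est.rate > 0
        # window end lies beyond the inflection of the fitted sigmoid
        assert est.t_f > est.x0

    def test_truncated_trace_falls_back(self):
        t = np.arange(0.0, 60.1, 3.0)
        tr = make_logistic(k=-0.1, x0=120.0, t=t)
        est = K.estimate_rate(tr)
        assert est.window_source == "fallback"

    def test_gaussian_window_rate_matches_truth_exactly(self):
        """Noiseless logistic through the full pipeline: t_f > x0 and the
        windowed fit reproduces the generating rate."""
        for k in (0.03, 0.1, 0.3):
            x0 = 12.0 / k
            t = np.linspace(0, x0 + 8 / k, 200)
            tr = make_logistic(k=-k, x0=x0, t=t)
            est = K.estimate_rate(tr)
            assert est.window_source == "gaussian"
            assert est.t_f > x0
            assert est.rate == pytest.approx(k, rel=1e-3)


class TestDerivedAnalyses:
    def test_exact_line_through_origin(self):
        pts = [(0.1, 14.45), (0.2, 28.9), (0.4, 57.8)]
        fit = K.rate_vs_template_slope(pts)
        assert fit.slope == pytest.approx(144.5)
        assert fit.stderr_slope == pytest.approx(0.0, abs=1e-9)

    def test_point_order_irrelevant(self):
        pts = [(0.1, 2.0), (0.3, 5.0), (0.2, 3.1), (0.5, 9.0)]
        a, b = K.rate_vs_template_slope(pts), K.rate_vs_template_slope(pts[::-1])
        assert a.slope == pytest.approx(b.slope)
        assert a.intercept == pytest.approx(b.intercept)

    def test_noisy_line_within_three_stderr(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.1, 1.0, 12)
        y = 144.5 * x + 3.0 + rng.normal(0, 5.0, x.size)
        fit = K.rate_vs_template_slope(list(zip(x, y)))
        assert abs(fit.slope - 144.5) < 3 * fit.stderr_slope

    def test_degenerate_template_rejected(self):
        with pytest.raises(ConfigError):
            K.rate_vs_template_slope([(0.1, 1.0), (0.1, 2.0), (0.1, 3.0)])

    def test_tukey_hand_example(self):
        s = K.tukey_summary([1.0, 2.0, 3.0, 4.0, 100.0])
        assert s.median == 3.0
        assert s.outside_points == [100.0]
        assert s.upper_adjacent == 4.0

    def test_tukey_against_percentile_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            v = rng.normal(size=rng.integers(5, 200))
            s = K.tukey_summary(v)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            assert (s.q1, s.median, s.q3) == pytest.approx((q1, med, q3))
            assert s.q1 <= s.median <= s.q3
            assert v.min() <= s.lower_adjacent <= s.upper_adjacent <= v.max()

    def test_identical_traces_have_zero_spread(self):
        tr = make_logistic(k=-0.1, x0=60.0)
        t, mean, sd, rates, summary = K.population_kinetics([tr, tr, tr])
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        assert summary.q1 == summary.median == summary.q3


class TestClassification:
    def test_constant_is_flat(self):
        tr = KineticTrace(t=np.arange(20.0), A=np.full(20, 3.0))
        assert K.classify_profile(tr) == "flat"

    def test_logistic_is_sigmoidal(self):
        assert K.classify_profile(make_logistic(k=-0.1, x0=60.0)) == "sigmoidal"

    def test_rise_then_fall_is_pulse(self):
        t = np.linspace(0, 100, 101)
        A = np.exp(-((t - 30.0) ** 2) / 300.0)
        tr = KineticTrace(t=t, A=A)
        assert K.classify_profile(tr) == "pulse"

    def test_simulated_linear_node_is_pulse(self, params):
        from penosome.synth import (NetworkLayout, PopulationSpec,
                                    simulate_compartment_network)
        layout = NetworkLayout(
            (PopulationSpec("linear", n_compartments=1, label="pop1"),
             PopulationSpec("autocatalytic", n_compartments=1, label="pop2")),
            volume_fraction=0.01)
        ts = simulate_compartment_network(params, layout, 50.0, 450.0, 2.0)
        tr = ts.by_population()["pop1"][0]
        assert K.classify_profile(tr) == "pulse"
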