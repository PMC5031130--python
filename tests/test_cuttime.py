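"""The cut-time algorithm: second-difference profiles, exponential-phase
detection against closed-form oracles, doubling targets, capping and
monotonicity properties."""

import numpy as np
import pytest

from platedrc import (
    CutTimeError,
    CutTimeParams,
    calculate_cut_time,
    cut_time_diagnostics,
    exponential_phase_end,
    fit_growth_curves_grouped,
    second_difference_profile,
)
from platedrc.cuttime import moving_average
from platedrc.growth import control_model

from conftest import control_set, logistic

TIMES = np.arange(0.0, 97.0, 2.0)


def fitted_control(fn, times, span=0.5):
    s = control_set(fn, times)
    fit_growth_curves_grouped(s, span=span)
    return s, control_model(s)


class TestSecondDifferenceProfile:
    def test_affine_curve_gives_zero(self):
        _, m = fitted_control(lambda t: 5.0 + 1.5 * t, TIMES)
        _, d2 = second_difference_profile(m, 2.0)
        np.testing.assert_allclose(d2, 0.0, atol=1e-8)

    def test_quadratic_curve_constant_second_difference(self):
        times = np.arange(0.0, 21.0, 1.0)
        _, m = fitted_control(lambda t: t ** 2, times)
        _, d2 = second_difference_profile(m, 1.0)
        np.testing.assert_allclose(d2, 2.0, atol=1e-6)

    def test_logistic_sign_matches_closed_form(self):
        """Discrete curvature agrees in sign with the analytic y'' on at
        least 95% of grid points (smoothing blurs the crossing slightly)."""
        K, y0, r = 100.0, 2.0, 0.1
        times = np.arange(0.0, 121.0, 2.0)
        _, m = fitted_control(lambda t: logistic(t, K, y0, r), times, span=0.25)
        tt, d2 = second_difference_profile(m, 2.0)
        y = logistic(tt, K, y0, r)
        ypp = r ** 2 * y * (1 - y / K) * (1 - 2 * y / K)
        agree = np.sign(d2) == np.sign(ypp)
        assert agree.mean() >= 0.95

    def test_grid_too_short(self):
        _, m = fitted_control(lambda t: t, TIMES)
        with pytest.raises(CutTimeError, match="grid_step_h"):
            second_difference_profile(m, 50.0)


class TestMovingAverage:
    def test_window_one_is_identity(self):
        v = np.array([3.0, -1.0, 4.0, 1.0, -5.0])
        np.testing.assert_array_equal(moving_average(v, 1), v)

    def test_truncated_ends(self):
        v = np.arange(5.0)
        ma = moving_average(v, 3)  # half-width 1
        np.testing.assert_allclose(ma, [0.5, 1.0, 2.0, 3.0, 3.5])


class TestExponentialPhaseEnd:
    def test_pure_exponential_falls_back_to_end(self):
        """Strictly accelerating growth has its curvature minimum at the
        left edge, which means no deceleration: end of data is returned."""
        s, m = fitted_control(lambda t: 10 * 2 ** (t / 24.0), TIMES)
        with pytest.warns(UserWarning, match="no deceleration"):
            t_end = exponential_phase_end(m, window_n=30, grid_step_h=2.0)
        assert t_end == pytest.approx(96.0)

    def test_flat_profile_warns(self):
        _, m = fitted_control(lambda t: 5.0 + 1.5 * t, TIMES)
        with pytest.warns(UserWarning):
            assert exponential_phase_end(m, 30, 2.0) == pytest.approx(96.0)

    def test_window_one_equals_raw_argmin(self):
        times = np.arange(0.0, 121.0, 2.0)
        _, m = fitted_control(lambda t: logistic(t), times)
        tt, d2 = second_difference_profile(m, 2.0)
        t1 = exponential_phase_end(m, window_n=1, grid_step_h=2.0)
        assert t1 == pytest.approx(tt[np.argmin(d2)])

    @pytest.mark.parametrize(
        "K,y0,r", [(100, 2, 0.1), (100, 5, 0.08), (80, 1, 0.12), (120, 3, 0.06)]
    )
    def test_matches_analytic_curvature_minimiser(self, K, y0, r):
        """Detected phase end within 2 moving-average window widths of the
        analytic minimiser of y'': inflection + ln(2+sqrt(3))/r."""
        t_star = np.log((K - y0) / y0) / r + np.log(2 + np.sqrt(3)) / r
        T = t_star * 1.6
        times = np.linspace(0.0, T, 80)
        step = float(times[1] - times[0])
        _, m = fitted_control(lambda t: logistic(t, K, y0, r), times, span=0.3)
        found = exponential_phase_end(m, window_n=30, grid_step_h=step)
        assert abs(found - t_star) <= 2 * 30 * step


class TestCalculateCutTime:
    def test_exponential_two_doublings(self, exponential_set):
        fit_growth_curves_grouped(exponential_set)
        with pytest.warns(UserWarning):
            res = calculate_cut_time(exponential_set, CutTimeParams(0.0, 2.0, 80.0))
        assert res.capped is False
        assert res.cut_time_h == pytest.approx(48.0, abs=0.5)
        assert res.achieved_doublings == pytest.approx(2.0, abs=1e-6)
        assert exponential_set.cut_time_h == res.cut_time_h

    def test_exponential_capped_at_max_val(self, exponential_set):
        """Four doublings would need y=160 > max_val: the 80-crossing
        (t=72 h) is returned with ~3 achieved doublings."""
        fit_growth_curves_grouped(exponential_set)
        with pytest.warns(UserWarning):
            res = calculate_cut_time(exponential_set, CutTimeParams(0.0, 4.0, 80.0))
        assert res.capped is True
        assert res.cut_time_h == pytest.approx(72.0, abs=0.5)
        assert res.achieved_doublings == pytest.approx(3.0, abs=0.05)
        assert res.achieved_doublings < 4.0

    def test_zero_doublings_returns_baseline(self, exponential_set):
        fit_growth_curves_grouped(exponential_set)
        with pytest.warns(UserWarning):
            res = calculate_cut_time(exponential_set, CutTimeParams(12.0, 0.0, 80.0))
        assert res.capped is False
        assert res.cut_time_h == pytest.approx(12.0, abs=1e-9)

    def test_max_val_below_baseline_rejected(self, exponential_set):
        fit_growth_curves_grouped(exponential_set)
        with pytest.raises(CutTimeError, match="max_val"):
            calculate_cut_time(exponential_set, CutTimeParams(48.0, 1.0, 30.0))

    def test_baseline_outside_domain_rejected(self, exponential_set):
        fit_growth_curves_grouped(exponential_set)
        with pytest.raises(CutTimeError, match="baseline"):
            calculate_cut_time(exponential_set, CutTimeParams(200.0, 1.0, 80.0))

    def test_requires_grouped_fit(self, exponential_set):
        with pytest.raises(Exception, match="grouped"):
            calculate_cut_time(exponential_set, CutTimeParams())

    def test_monotone_in_doublings_and_baseline(self, logistic_set):
        """cut_time is non-decreasing in no_doublings and baseline_time."""
        fit_growth_curves_grouped(logistic_set)
        cuts = []
        for nd in [0.5, 1.0, 1.5, 2.0, 3.0]:
            res = calculate_cut_time(logistic_set, CutTimeParams(0.0, nd, 80.0))
            cuts.append(res.cut_time_h)
        assert all(a <= b + 1e-9 for a, b in zip(cuts, cuts[1:]))
        cuts = []
        for bt in [0.0, 8.0, 16.0, 24.0]:
            res = calculate_cut_time(logistic_set, CutTimeParams(bt, 1.0, 80.0))
            cuts.append(res.cut_time_h)
        assert all(a <= b + 1e-9 for a, b in zip(cuts, cuts[1:]))

    def test_raising_max_val_never_shrinks_truncation(self, logistic_set):
        fit_growth_curves_grouped(logistic_set)
        truncs = [
            calculate_cut_time(logistic_set, CutTimeParams(0.0, 2.0, mv)).truncation_time_h
            for mv in [40.0, 60.0, 80.0, 95.0]
        ]
        assert all(a <= b + 1e-9 for a, b in zip(truncs, truncs[1:]))

    def test_capped_prediction_respects_max_val(self, logistic_set):
        fit_growth_curves_grouped(logistic_set)
        res = calculate_cut_time(logistic_set, CutTimeParams(0.0, 8.0, 60.0))
        assert res.capped is True
        m = control_model(logistic_set)
        assert m.predict([res.cut_time_h])[0] <= 60.0 + 0.5

    def test_parameter_recovery_on_noisy_exponential(self):
        """With growth rate r, an uncapped cut time sits near
        baseline + no_doublings * ln2 / r, across noisy replicates."""
        rng = np.random.default_rng(11)
        hits = []
        for _ in range(10):
            noise = lambda t: 8.0 * 2 ** (t / 20.0) + rng.normal(0, 1.0, t.size)
            s = control_set(noise, TIMES, n_wells=3)
            fit_growth_curves_grouped(s)
            with pytest.warns(UserWarning):
                res = calculate_cut_time(s, CutTimeParams(4.0, 2.0, 80.0))
            assert res.capped is False
            hits.append(abs(res.cut_time_h - (4.0 + 2.0 * 20.0)))
        assert np.median(hits) < 2.0 and max(hits) < 4.0


class TestDiagnostics:
    def test_markers_match_result(self, logistic_set):
        fit_growth_curves_grouped(logistic_set)
        params = CutTimeParams(0.0, 2.0, 80.0)
        res = calculate_cut_time(logistic_set, params)
        diag = cut_time_diagnostics(logistic_set, params)
        m = diag["markers"]
        assert set(m) == {
            "baseline_time_h", "max_val", "truncation_time_h", "cut_time_h",
            "target_value",
        }
        assert m["cut_time_h"] == res.cut_time_h
        assert m["truncation_time_h"] == res.truncation_time_h
        assert m["target_value"] == res.target_value
        lo, hi = control_model(logistic_set).time_domain
        assert lo <= m["cut_time_h"] <= hi

    def test_capped_flag_propagates(self, exponential_set):
        fit_growth_curves_grouped(exponential_set)
        params = CutTimeParams(0.0, 4.0, 80.0)
        with pytest.warns(UserWarning):
            calculate_cut_time(exponential_set, params)
        diag = cut_time_diagnostics(exponential_set, params)
        assert diag["capped"] is True

    def test_requires_prior_cut_time(self, logistic_set):
        fit_growth_curves_grouped(logistic_set)
        with pytest.raises(CutTimeError, match="calculate_cut_time"):
            cut_time_diagnostics(logistic_set, CutTimeParams())
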