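"""Finite-difference stencils: exactness classes, bias laws, orders."""

import numpy as np
import pytest

from isgel.errors import GridError, InsufficientDataError
from isgel.finite_differences import (
    central_diff4,
    check_uniform_grid,
    forward_diff,
    resample_uniform,
)
from isgel.release_core import FirstOrderModel, ReleaseSeries, evaluate_release_curve


class TestUniformGrid:
    def test_accepts_uniform(self):
        assert check_uniform_grid([0.0, 1.0, 2.0, 3.0]) == 1.0

    def test_rejects_nonuniform_naming_worst_interval(self):
        with pytest.raises(GridError, match=r"not uniform: interval \["):
            check_uniform_grid([0.0, 1.0, 2.5])

    def test_tolerance_absorbs_float_jitter(self):
        t = [0.0, 0.1, 0.2 + 1e-12]
        assert check_uniform_grid(t) == pytest.approx(0.1, rel=1e-9)


class TestResample:
    def test_idempotent_on_matching_uniform_grid(self):
        t = np.linspace(0.0, 7.0, 8)
        s = ReleaseSeries(times=t, values=t**2)
        out = resample_uniform(s, 1.0)
        np.testing.assert_allclose(out.times, t, atol=1e-12)
        np.testing.assert_allclose(out.values, s.values, atol=1e-12)

    def test_reproduces_linear_data_exactly(self):
        s = ReleaseSeries(times=np.array([0.0, 1.0, 2.5, 4.0, 7.0]),
                          values=np.array([5.0, 7.0, 10.0, 13.0, 19.0]))
        out = resample_uniform(s, 0.5)
        np.testing.assert_allclose(out.values, 5.0 + 2.0 * out.times, rtol=1e-12)

    def test_accuracy_on_exponential_release_schedule(self):
        model = FirstOrderModel(C2_edge=100.0, rate_a=0.5)
        sched = np.array([0.5, 1, 2, 3, 4, 5, 6, 7], dtype=float)
        s = evaluate_release_curve(model, sched)
        out = resample_uniform(s, 0.05)
        exact = evaluate_release_curve(model, out.times).values
        assert np.max(np.abs(out.values - exact)) < 0.5

    def test_preserves_monotonicity(self):
        model = FirstOrderModel(C2_edge=100.0, rate_a=0.9)
        s = evaluate_release_curve(model, [0.5, 1, 2, 3, 4, 5, 6, 7])
        out = resample_uniform(s, 0.01)
        assert np.all(np.diff(out.values) >= 0)

    def test_step_larger_than_span_rejected(self):
        s = ReleaseSeries(times=np.arange(4.0), values=np.arange(4.0))
        with pytest.raises(GridError):
            resample_uniform(s, 10.0)


class TestForwardDiff:
    def test_hand_worked_quadratic(self):
        est = forward_diff([0.0, 1.0, 4.0, 9.0], 1.0)
        np.testing.assert_allclose(est.values, [1.0, 3.0, 5.0])
        np.testing.assert_array_equal(est.node_indices, [0, 1, 2])

    def test_exact_for_affine(self):
        t = np.linspace(0, 5, 11)
        est = forward_diff(2 * t + 5, 0.5)
        np.testing.assert_allclose(est.values, 2.0, rtol=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            forward_diff([1.0], 1.0)

    def test_closed_form_bias_on_exponential_release(self):
        # forward differences of C(1 - e^{-at}) equal
        # C (1 - e^{-ah})/h * e^{-a t_i} exactly
        a, C, h = 0.7081, 103.5, 0.05
        t = np.arange(0, 7, h)
        y = C * (1 - np.exp(-a * t))
        est = forward_diff(y, h)
        expected = C * (1 - np.exp(-a * h)) / h * np.exp(-a * t[:-1])
        np.testing.assert_allclose(est.values, expected, rtol=1e-9)


class TestCentralDiff4:
    def test_symmetric_stencil_on_even_quartic(self):
        t = np.arange(-2.0, 3.0)
        est = central_diff4(t**4, 1.0)
        assert est.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_quadratic(self):
        t = np.arange(-1.0, 4.0)
        est = central_diff4(t**2, 1.0)
        np.testing.assert_allclose(est.values, [2.0])
        np.testing.assert_array_equal(est.node_indices, [2])

    def test_exact_for_quartic_polynomials(self):
        t = np.linspace(0, 4, 17)
        h = t[1] - t[0]
        y = 3 * t**4 - t**3 + 2 * t - 7
        est = central_diff4(y, h)
        exact = 12 * t**3 - 3 * t**2 + 2
        np.testing.assert_allclose(est.values, exact[2:-2], rtol=1e-10)

    def test_four_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            central_diff4([1.0, 2.0, 3.0, 4.0], 1.0)


class TestConvergenceOrders:
    @staticmethod
    def _max_error(diff, h, order_drop):
        t = np.arange(0.0, 4.0 + h / 2, h)
        y = np.exp(-t)
        est = diff(y, h)
        exact = -np.exp(-t[est.node_indices])
        return np.max(np.abs(est.values - exact))

    @pytest.mark.parametrize(
        "diff,expected_slope",
        [(forward_diff, 1.0), (central_diff4, 4.0)],
        ids=["forward-O(h)", "central-O(h4)"],
    )
    def test_empirical_order_on_smooth_function(self, diff, expected_slope):
        hs = np.array([0.1, 0.05, 0.025, 0.0125])
        errs = [self._max_error(diff, h, expected_slope) for h in hs]
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(expected_slope, abs=0.2)

    def test_richardson_halving_for_central(self):
        e1 = self._max_error(central_diff4, 0.1, 4)
        e2 = self._max_error(central_diff4, 0.05, 4)
        assert e1 / e2 == pytest.approx(16.0, rel=0.15)
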