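"""Rate/plateau estimation: exactness identities, recovery, diagnostics."""

import numpy as np
import pytest

from isgel.errors import (
    DegenerateDesignError,
    GridError,
    InsufficientDataError,
    NonPhysicalFitError,
    UndefinedMetricError,
)
from isgel.first_order_fit import (
    fit_linear_rate,
    fit_release,
    r_squared,
    relative_error,
    to_model,
)
from isgel.formulations import (
    CENTRAL4,
    FORWARD,
    REFERENCE_PARAMETERS,
    reference_model,
)
from isgel.release_core import FirstOrderModel, ReleaseSeries, evaluate_release_curve
from isgel.synthetic_data import CupProtocol, NoiseSpec, make_dataset


class TestLinearRate:
    def test_exact_on_analytic_derivative_pairs(self):
        a, C = 0.5, 100.0
        t = np.linspace(0, 7, 30)
        y = C * (1 - np.exp(-a * t))
        dy = a * C * np.exp(-a * t)  # = b - a*y exactly
        a_hat, b_hat = fit_linear_rate(y, dy)
        assert a_hat == pytest.approx(0.5, rel=1e-10)
        assert b_hat == pytest.approx(50.0, rel=1e-10)

    def test_two_exact_points_define_the_line(self):
        a_hat, b_hat = fit_linear_rate([10.0, 20.0], [8.0, 6.0])
        assert a_hat == pytest.approx(0.2)
        assert b_hat == pytest.approx(10.0)

    def test_constant_y_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear_rate([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_nonphysical_rate_carries_raw_estimates(self):
        # increasing dy with increasing y implies a negative rate
        with pytest.raises(NonPhysicalFitError) as err:
            fit_linear_rate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert err.value.a_hat < 0


class TestToModel:
    def test_reference_row_identification(self):
        model = to_model(a_hat=0.7081, b_hat=0.7081 * 103.5, V3=80.0)
        assert model.K32 == pytest.approx(56.648, abs=5e-3)
        assert model.C2_edge == pytest.approx(103.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(NonPhysicalFitError):
            to_model(a_hat=-0.1, b_hat=1.0)


class TestMetrics:
    def test_relative_error_perfect_and_total(self):
        assert relative_error([3.0, 4.0], [3.0, 4.0]) == 0.0
        assert relative_error([3.0, 4.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_relative_error_orthogonal_case(self):
        assert relative_error([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.4142, abs=1e-4)

    def test_relative_error_zero_norm_undefined(self):
        with pytest.raises(UndefinedMetricError):
            relative_error([0.0, 0.0], [1.0, 1.0])

    def test_r_squared_perfect_mean_and_halfway(self):
        y = [1.0, 2.0, 3.0]
        assert r_squared(y, y) == 1.0
        assert r_squared(y, [2.0, 2.0, 2.0]) == 0.0
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_r_squared_constant_y_undefined(self):
        with pytest.raises(UndefinedMetricError):
            r_squared([2.0, 2.0], [1.0, 2.0])


class TestFitRelease:
    def test_central_scheme_near_machine_recovery(self):
        model = FirstOrderModel(C2_edge=100.0, rate_a=0.5)
        t = np.arange(0.0, 7.0 + 5e-3, 0.01)
        fit = fit_release(evaluate_release_curve(model, t), method=CENTRAL4, V3=80.0)
        assert fit.model.K32 == pytest.approx(40.0, rel=1e-6)
        assert fit.model.C2_edge == pytest.approx(100.0, rel=1e-6)

    def test_forward_rate_bias_follows_closed_form(self):
        # a_hat = (1 - e^{-ah})/h exactly on noise-free exponential data
        model = reference_model("Lv20ZD", FORWARD)
        for h in (0.1, 0.01, 0.001):
            t = np.arange(0.0, 7.0 + h / 2, h)
            fit = fit_release(evaluate_release_curve(model, t), method=FORWARD)
            expected = (1 - np.exp(-model.rate_a * h)) / h
            assert fit.a_hat == pytest.approx(expected, rel=1e-8)
            # plateau is recovered with zero bias at any step
            assert fit.model.C2_edge == pytest.approx(model.C2_edge, rel=1e-8)

    def test_central_plateau_exact_at_coarse_step(self):
        model = reference_model("Lv25ZG", CENTRAL4)
        t = np.arange(0.0, 7.0 + 0.05, 0.1)
        fit = fit_release(evaluate_release_curve(model, t), method=CENTRAL4)
        assert fit.model.C2_edge == pytest.approx(model.C2_edge, rel=1e-8)

    def test_full_reference_table_recovery(self, row):
        """Each published (K32, C2) row is reproduced by regenerating
        noise-free data from its release equation and re-fitting with
        the matching scheme."""
        (label, method), (k32, c2) = row
        h = 0.001 if method == FORWARD else 0.01
        t = np.arange(0.0, 7.0 + h / 2, h)
        series = evaluate_release_curve(reference_model(label, method), t)
        fit = fit_release(series, method=method, V3=80.0)
        assert fit.model.K32 == pytest.approx(k32, rel=5e-3)
        assert fit.model.C2_edge == pytest.approx(c2, rel=1e-3)
        assert fit.r_squared > 0.999999
        assert fit.rel_err < 1e-3

    def test_rate_convergence_orders(self):
        model = FirstOrderModel(C2_edge=100.0, rate_a=0.5)
        hs = np.array([0.1, 0.05, 0.025, 0.0125])
        for method, expected in ((FORWARD, 1.0), (CENTRAL4, 4.0)):
            errs = []
            for h in hs:
                t = np.arange(0.0, 7.0 + h / 2, h)
                fit = fit_release(evaluate_release_curve(model, t), method=method)
                errs.append(abs(fit.a_hat - 0.5))
            slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
            assert slope == pytest.approx(expected, abs=0.2)

    def test_nonuniform_grid_requires_resampling(self):
        model = FirstOrderModel(C2_edge=100.0, rate_a=0.5)
        series = evaluate_release_curve(model, [0.5, 1, 2, 3, 4, 5, 6, 7])
        with pytest.raises(GridError):
            fit_release(series, method=FORWARD)
        fit = fit_release(series, method=FORWARD, resample_h=0.02)
        assert fit.model.C2_edge == pytest.approx(100.0, rel=0.02)
        assert fit.model.K32 == pytest.approx(40.0, rel=0.05)

    def test_all_zero_series_degenerate(self):
        series = ReleaseSeries(times=np.arange(5.0), values=np.zeros(5))
        with pytest.raises(DegenerateDesignError):
            fit_release(series, method=FORWARD)

    def test_too_few_points_for_central_stencil(self):
        series = ReleaseSeries(times=np.arange(4.0), values=np.arange(4.0) ** 0.5)
        with pytest.raises(InsufficientDataError):
            fit_release(series, method=CENTRAL4)

    def test_noise_robustness_seed_averaged_rate(self):
        """With 2% multiplicative assay noise the seed-averaged rate
        estimate stays within 3 standard errors of the generator rate."""
        model = reference_model("Lv20ZD", FORWARD)
        h = 0.1
        protocol = CupProtocol(schedule=tuple(np.arange(h, 7.0 + h / 2, h)))
        a_hats = []
        for rep in range(200):
            noise = NoiseSpec(kind="multiplicative-normal", sd=0.02, seed=1000 + rep)
            _, observed, _ = make_dataset(model, protocol, noise)
            fit = fit_release(observed, method=CENTRAL4, V3=80.0)
            a_hats.append(fit.a_hat)
        a_hats = np.asarray(a_hats)
        se = a_hats.std(ddof=1) / np.sqrt(a_hats.size)
        assert abs(a_hats.mean() - model.rate_a) < 3 * se
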