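import numpy as np
import pytest

from cinpipe.errors import NoDoseEffectError, NoLogPhaseError
from cinpipe.growth import (GrowthCurve, curve_auc, curves_from_frame,
                            doubling_time, fit_dose_response)
from cinpipe.simulate import DrugEffect, GrowthModel, simulate_growth


def four_pl(c, top, bottom, hill, ic50):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


class TestDoublingTime:
    def test_exact_exponential_returns_24h(self):
        t = np.arange(0, 73.0)
        fit = doubling_time(GrowthCurve(t, 100 * 2 ** (t / 24)))
        assert fit.doubling_time_h == pytest.approx(24.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_plateaued_logistic_recovered_within_10pct(self):
        model = GrowthModel(initial_count=100, doubling_time=24,
                            carrying_capacity=10_000, noise_cv=0.0)
        df = simulate_growth(model, [0.0], np.arange(0, 241, 2.0), seed=0)
        curve = next(curves_from_frame(df))
        fit = doubling_time(curve)
        assert abs(fit.doubling_time_h - 24.0) / 24.0 < 0.10

    def test_decreasing_curve_has_no_log_phase(self):
        t = np.arange(0, 48.0, 4)
        with pytest.raises(NoLogPhaseError):
            doubling_time(GrowthCurve(t, 1000 * 2 ** (-t / 24)))

    def test_invariant_to_value_rescaling(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 73.0, 3)
        v = 50 * 2 ** (t / 30) * np.exp(rng.normal(0, 0.02, t.size))
        a = doubling_time(GrowthCurve(t, v))
        b = doubling_time(GrowthCurve(t, v * 123.4))
        assert a.doubling_time_h == pytest.approx(b.doubling_time_h)
        assert a.window == b.window

    def test_explicit_window_is_respected(self):
        t = np.arange(0, 73.0)
        v = 100 * 2 ** (t / 24)
        fit = doubling_time(GrowthCurve(t, v), log_phase=(10.0, 40.0))
        assert fit.window == (10.0, 40.0)
        assert fit.doubling_time_h == pytest.approx(24.0, abs=1e-9)


class TestCurveAUC:
    def test_rectangle(self):
        c = GrowthCurve(np.array([0.0, 72.0]), np.array([1.0, 1.0]))
        assert curve_auc(c) == pytest.approx(72.0)

    def test_triangle(self):
        c = GrowthCurve(np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        assert curve_auc(c) == pytest.approx(50.0)

    def test_hand_trapezoid(self):
        c = GrowthCurve(np.array([0.0, 1, 3, 4]), np.array([0.0, 2, 2, 0]))
        assert curve_auc(c) == pytest.approx(6.0)

    def test_additive_over_adjacent_ranges(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 100, 30))
        t[0], t[-1] = 0.0, 100.0
        c = GrowthCurve(t, rng.uniform(1, 5, 30))
        whole = curve_auc(c, (0.0, 100.0))
        split = curve_auc(c, (0.0, 37.5)) + curve_auc(c, (37.5, 100.0))
        assert whole == pytest.approx(split)

    def test_out_of_range_is_an_error(self):
        c = GrowthCurve(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            curve_auc(c, (0.0, 20.0))


class TestDoseResponse:
    CONCS = 0.6 * 10.0 ** (0.5 * (np.arange(9) - 4))  # 9 half-log steps

    def test_exact_4pl_recovered_to_6_significant_figures(self):
        y = four_pl(self.CONCS, top=100.0, bottom=8.0, hill=1.3, ic50=0.6)
        fit = fit_dose_response(list(zip(self.CONCS, y)), vehicle_auc=100.0)
        assert fit.converged
        assert fit.ic50_uM == pytest.approx(0.6, rel=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.bottom == pytest.approx(8.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.3, rel=1e-6)

    def test_noisy_simulation_recovers_ic50_within_15pct(self):
        model = GrowthModel(initial_count=100, doubling_time=24,
                            drug_effect=DrugEffect(ec50_uM=0.6), noise_cv=0.05)
        df = simulate_growth(model, [0.0, *self.CONCS], np.arange(0, 73, 4.0),
                             replicates=3, seed=1)
        aucs = {}
        for curve in curves_from_frame(df):
            aucs.setdefault(curve.concentration_uM, []).append(curve_auc(curve))
        mean_auc = {c: np.mean(v) for c, v in aucs.items()}
        vehicle = mean_auc.pop(0.0)
        fit = fit_dose_response(sorted(mean_auc.items()), vehicle_auc=vehicle)
        assert fit.converged
        assert abs(fit.ic50_uM - 0.6) / 0.6 < 0.15

    def test_flat_response_is_no_dose_effect(self):
        y = np.full(9, 95.0)
        with pytest.raises(NoDoseEffectError):
            fit_dose_response(list(zip(self.CONCS, y)), vehicle_auc=100.0)

    def test_invariant_to_joint_rescaling(self):
        y = four_pl(self.CONCS, 100, 10, 1.0, 0.6)
        a = fit_dose_response(list(zip(self.CONCS, y)), vehicle_auc=100.0)
        b = fit_dose_response(list(zip(self.CONCS, y * 55.0)), vehicle_auc=5500.0)
        assert a.ic50_uM == pytest.approx(b.ic50_uM)
        assert a.top == pytest.approx(b.top)

    def test_median_ic50_bias_under_5pct(self):
        # 200 seeded parameter-recovery replicates of the full AUC route
        # (growth curves at 5% multiplicative measurement noise)
        model = GrowthModel(initial_count=100, doubling_time=24,
                            drug_effect=DrugEffect(ec50_uM=0.6), noise_cv=0.05)
        t = np.arange(0, 73, 6.0)
        errors = []
        for rep in range(200):
            df = simulate_growth(model, [0.0, *self.CONCS], t, replicates=3,
                                 seed=1000 + rep)
            aucs = {}
            for curve in curves_from_frame(df):
                aucs.setdefault(curve.concentration_uM, []).append(curve_auc(curve))
            mean_auc = {c: np.mean(v) for c, v in aucs.items()}
            vehicle = mean_auc.pop(0.0)
            fit = fit_dose_response(sorted(mean_auc.items()), vehicle_auc=vehicle)
            if fit.converged:
                errors.append(abs(fit.ic50_uM - 0.6) / 0.6)
        assert len(errors) > 190
        assert np.median(errors) < 0.05

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([(0.1, 90.0), (1.0, 50.0), (10.0, 10.0)], 100.0)
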