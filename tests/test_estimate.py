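import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixedmeal import (FitConfig, MealResponse, MealSpec, NoiseModel,
                       SubjectSpec, cost, design, fit, generate_response,
                       lhs_starts, preset, regularized_residuals)


@pytest.fixture(scope="module")
def metflex_data(metflex_fixture):
    return metflex_fixture


class TestCost:
    def test_single_point_hand_oracle(self):
        """One metabolite, one sample: y_obs = 5, simulated value 6, max = 5
        gives ((6 - 5)/5)^2 = 0.04 by direct evaluation of the formula."""
        subject = SubjectSpec(G_b=6.0)  # simulated glucose at t=0 is G_b = 6
        data = MealResponse(times={"glucose": np.array([0.0])},
                            values={"glucose": np.array([5.0])},
                            subject=subject, meal=MealSpec(0, 0, 0))
        assert cost(subject_params(), data) == pytest.approx(0.04, abs=1e-9)

    def test_self_fit_cost_is_zero(self, metflex_data):
        p = preset("metflex_population").parameters()
        assert cost(p, metflex_data) < 1e-10

    def test_max_normalization_scale_invariance(self, metflex_data):
        """Scaling one metabolite's observations and simulations by 10 leaves
        its cost contribution unchanged; verified by comparing per-metabolite
        residual blocks directly."""
        from mixedmeal.estimate import (_data_residuals, _simulate_for)
        p = preset("metflex_population").parameters()
        res = _simulate_for(p, metflex_data, regularize=False)
        r = _data_residuals(res, metflex_data)
        # rescale glucose by hand: residuals (y_sim*10 - y_obs*10)/(10*max)
        g = metflex_data
        y_obs = g.values["glucose"]
        y_sim = res.interp("glucose", g.times["glucose"])
        r_scaled = (10 * y_sim - 10 * y_obs) / (10 * y_obs.max())
        np.testing.assert_allclose(r[:y_obs.size], r_scaled, atol=1e-14)


def subject_params():
    from mixedmeal import default_parameters
    return default_parameters()


class TestRegularizedResiduals:
    def test_disabling_regularization_reproduces_cost(self, metflex_data):
        p = preset("metflex_population").parameters()
        r = regularized_residuals(p, metflex_data,
                                  FitConfig(regularize=False))
        assert float(r @ r) == pytest.approx(cost(p, metflex_data), abs=1e-15)

    def test_four_penalties_appended(self, metflex_data):
        p = preset("metflex_population").parameters()
        r_plain = regularized_residuals(p, metflex_data,
                                        FitConfig(regularize=False))
        r_reg = regularized_residuals(p, metflex_data, FitConfig())
        assert r_reg.size == r_plain.size + 4

    def test_slow_gut_cascade_gives_negative_auc_penalty(self):
        """Delivering only ~80% of the meal glucose by 240 min must produce a
        glucose-AUC penalty residual of ~ -0.2 (closed-form cascade oracle)."""
        from scipy.optimize import brentq

        def frac(k1, k2=0.06, t=240.0):
            return 1 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)

        k1_slow = brentq(lambda k: frac(k) - 0.80, 1e-4, 0.05)
        p = subject_params().with_values({"k1": k1_slow})
        data = generate_response(design("nutritech"),
                                 preset("nutritech_population"),
                                 noise=NoiseModel.noiseless(), seed=0,
                                 params=p)
        r = regularized_residuals(p, data)
        assert r[-4] == pytest.approx(-0.2, abs=0.01)

    def test_penalty_weights_scale_residuals(self, metflex_data):
        p = subject_params().with_values({"k1": 0.008})
        r1 = regularized_residuals(p, metflex_data, FitConfig())
        r2 = regularized_residuals(
            p, metflex_data, FitConfig(penalty_weights=(2.0, 1.0, 1.0, 1.0)))
        assert r2[-4] == pytest.approx(2 * r1[-4])

    def test_zero_meal_mass_skips_penalty_with_warning(self, params, subject):
        data = MealResponse(times={"glucose": np.array([0.0, 60.0])},
                            values={"glucose": np.array([5.0, 5.0])},
                            subject=subject, meal=MealSpec(0.0, 0.0, 0.0))
        with pytest.warns(UserWarning):
            r = regularized_residuals(params, data)
        assert r[-4] == 0.0 and r[-3] == 0.0


class TestLhsStarts:
    def test_each_parameter_stratified_into_n_log_bins(self):
        bounds = {"k5": (0.005, 1.0), "k16": (0.0015, 0.15)}
        pts = lhs_starts(25, bounds, seed=3)
        assert pts.shape == (25, 2)
        for j, (lo, hi) in enumerate(bounds.values()):
            z = (np.log10(pts[:, j]) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
            bins = np.floor(z * 25).astype(int)
            assert sorted(bins) == list(range(25))

    @given(n=st.integers(1, 40), seed=st.integers(0, 2 ** 16))
    @settings(max_examples=25, deadline=None)
    def test_within_bounds_and_reproducible(self, n, seed):
        bounds = {"a": (0.1, 10.0), "b": (1e-5, 1e-2)}
        p1 = lhs_starts(n, bounds, seed=seed)
        p2 = lhs_starts(n, bounds, seed=seed)
        np.testing.assert_array_equal(p1, p2)
        for j, (lo, hi) in enumerate(bounds.values()):
            assert np.all((p1[:, j] >= lo) & (p1[:, j] <= hi))

    def test_degenerate_bounds_give_fixed_coordinate(self):
        pts = lhs_starts(5, {"a": (2.0, 2.0), "b": (0.1, 1.0)}, seed=0)
        np.testing.assert_allclose(pts[:, 0], 2.0)


class TestFit:
    def test_recovers_generating_parameters_from_noiseless_data(
            self, metflex_data):
        """Multi-start regularized estimation on noiseless MetFlex-design
        data must recover the generating free parameters within 5%."""
        free = ("k5", "k6", "k11", "K_ATL", "k16")
        result = fit(metflex_data, FitConfig(free=free, n_starts=25, seed=0))
        truth = preset("metflex_population").parameters()
        for name in free:
            assert result.params[name] == pytest.approx(truth[name], rel=0.05)

    def test_warm_start_at_truth_converges_immediately(self, metflex_data):
        from mixedmeal.estimate import _make_residual_fn
        from scipy.optimize import least_squares

        truth = preset("metflex_population").parameters()
        free = ("k5", "k16")
        cfg = FitConfig(free=free)
        n_res = sum(len(v) for v in metflex_data.values.values()) + 4
        fn = _make_residual_fn(truth, metflex_data, cfg, free, n_res)
        z0 = np.log10([truth["k5"], truth["k16"]])
        sol = least_squares(fn, z0, method="trf", max_nfev=30,
                            diff_step=1e-3)
        assert float(sol.fun[:-4] @ sol.fun[:-4]) < 1e-4
        np.testing.assert_allclose(10 ** sol.x, [truth["k5"], truth["k16"]],
                                   rtol=0.02)

    def test_glucose_only_data_insensitive_to_k11(self, metflex_data):
        """TG-side parameters are unconstrained by glucose-only data: the
        cost barely moves when k11 changes several-fold."""
        g_only = MealResponse(
            times={"glucose": metflex_data.times["glucose"]},
            values={"glucose": metflex_data.values["glucose"]},
            subject=metflex_data.subject, meal=metflex_data.meal)
        p = preset("metflex_population").parameters()
        c0 = cost(p, g_only)
        c1 = cost(p.with_values({"k11": 1.3e-4}), g_only)
        assert abs(c1 - c0) < 1e-6

    def test_best_cost_non_increasing_in_starts(self, metflex_data):
        free = ("k5", "k6")
        costs = []
        for n in (2, 6):
            r = fit(metflex_data, FitConfig(free=free, n_starts=n, seed=7,
                                            max_nfev=60))
            costs.append(r.best_cost)
        assert costs[1] <= costs[0] + 1e-12

    def test_reported_parameters_within_bounds(self, metflex_data):
        r = fit(metflex_data, FitConfig(free=("k5", "k6"), n_starts=3,
                                        seed=1, max_nfev=40))
        for name in r.free:
            lo, hi = r.params.bounds(name)
            assert lo <= r.params[name] <= hi
        assert r.best_cost == min(s.cost for s in r.starts if s.converged)
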