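import numpy as np
import pytest

from mixedmeal import (MealSpec, NUTRITECH_MEAL,
                       cumulative_appearance, simulate, steady_state_check)

ZERO_MEAL = MealSpec(0.0, 0.0, 0.0)


def _two_stage_fraction(t, k1, k2):
    """Closed-form fraction of a stomach->gut cascade delivered by time t."""
    return 1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)


def _erlang3_cdf(t, k):
    """Closed-form fraction of the 3-stage TG transit delivered by time t."""
    kt = k * t
    return 1.0 - np.exp(-kt) * (1 + kt + kt ** 2 / 2)


class TestEquilibrium:
    def test_zero_meal_trajectories_constant(self, params, subject):
        res = simulate(params, subject, ZERO_MEAL, t_end=720)
        for m, b in subject.basal.items():
            assert np.max(np.abs(res.plasma[m] - b)) < 1e-6

    def test_steady_state_check_zero_meal(self, params, subject):
        res = simulate(params, subject, ZERO_MEAL, t_end=720)
        dev = steady_state_check(res, subject, 700.0)
        assert all(v < 1e-6 for v in dev.values())

    def test_grid_validation(self, params, subject):
        with pytest.raises(ValueError):
            simulate(params, subject, ZERO_MEAL, t_end=100,
                     grid=np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            simulate(params, subject, ZERO_MEAL, t_end=50,
                     grid=np.array([0.0, 100.0]))


@pytest.fixture(scope="module")
def res(params, subject):
    return simulate(params, subject, NUTRITECH_MEAL, t_end=900,
                    grid=np.arange(0.0, 901.0))


class TestMealDynamics:
    def test_nefa_dip_then_overshoot_then_return(self, res, subject):
        nefa = res.plasma["nefa"]
        t_min = int(np.argmin(nefa))
        assert nefa[t_min] < subject.NEFA_b * 0.95
        post = nefa[t_min:]
        t_max = t_min + int(np.argmax(post))
        assert nefa[t_max] > subject.NEFA_b * 1.02
        assert t_max > t_min
        assert abs(nefa[-1] - subject.NEFA_b) < 0.1 * subject.NEFA_b

    def test_glucose_insulin_peak_before_tg(self, res):
        t_g = np.argmax(res.plasma["glucose"])
        t_i = np.argmax(res.plasma["insulin"])
        t_tg = np.argmax(res.plasma["tg"])
        assert t_g < t_tg and t_i < t_tg

    def test_states_non_negative(self, res):
        assert np.all(res.states >= 0)

    def test_tolerance_refinement_stable(self, params, subject, res):
        fine = simulate(params, subject, NUTRITECH_MEAL, t_end=900,
                        grid=np.arange(0.0, 901.0), rtol=5e-7, atol=5e-9)
        for m in ("glucose", "insulin", "tg", "nefa"):
            scale = np.max(np.abs(res.plasma[m]))
            assert np.max(np.abs(fine.plasma[m] - res.plasma[m])) < 1e-3 * scale


class TestCumulativeAppearance:
    def test_zero_meal_is_zero(self, params, subject):
        res = simulate(params, subject, ZERO_MEAL, t_end=720)
        assert cumulative_appearance(res, "glucose", 720) == pytest.approx(0.0)
        assert cumulative_appearance(res, "tg", 600) == pytest.approx(0.0)

    def test_glucose_appearance_matches_cascade_closed_form(self, params,
                                                            subject):
        res = simulate(params, subject, NUTRITECH_MEAL, t_end=720)
        for t in (120.0, 240.0, 720.0):
            expected = 75.0 * params["f_G"] * _two_stage_fraction(
                t, params["k1"], params["k2"])
            assert cumulative_appearance(res, "glucose", t) == pytest.approx(
                expected, rel=2e-3)

    def test_tg_appearance_matches_erlang_closed_form(self, params, subject):
        res = simulate(params, subject, NUTRITECH_MEAL, t_end=720)
        for t in (240.0, 600.0):
            expected = 60.0 * _erlang3_cdf(t, params["k13"])
            assert cumulative_appearance(res, "tg", t) == pytest.approx(
                expected, rel=2e-3)

    def test_monotone_in_time(self, params, subject):
        res = simulate(params, subject, NUTRITECH_MEAL, t_end=720)
        vals = [cumulative_appearance(res, "glucose", t)
                for t in (60, 120, 240, 480, 720)]
        assert np.all(np.diff(vals) > 0)

    def test_horizon_guard(self, params, subject):
        res = simulate(params, subject, NUTRITECH_MEAL, t_end=480)
        with pytest.raises(ValueError):
            cumulative_appearance(res, "glucose", 600)
        with pytest.raises(ValueError):
            cumulative_appearance(res, "unknown")


class TestMonotonicity:
    def test_higher_k5_lowers_incremental_glucose_auc(self, params, subject):
        iaucs = []
        for k5 in (0.05, 0.102, 0.2):
            res = simulate(params.with_values({"k5": k5}), subject,
                           NUTRITECH_MEAL, t_end=480)
            iaucs.append(np.trapezoid(
                np.maximum(res.plasma["glucose"] - subject.G_b, 0), res.t))
        assert iaucs[0] > iaucs[1] > iaucs[2]

    def test_higher_k16_raises_tg_under_frozen_basal_constants(self, params,
                                                               subject):
        """Raising hepatic secretion with the basal LPL activity frozen at
        its reference value pushes the fasting TG balance upward."""
        from mixedmeal.model import basal_closure, basal_state, pack_constants
        from mixedmeal.model import _rhs_c
        from scipy.integrate import odeint

        ref = basal_closure(params, subject)
        levels = []
        for k16 in (0.015, 0.03):
            c = pack_constants(params.with_values({"k16": k16}), subject,
                               ZERO_MEAL, basal=ref)
            y = odeint(_rhs_c, basal_state(subject),
                       np.linspace(0, 720, 100), args=(c,), tfirst=True)
            levels.append(y[-1, 11])
        assert levels[1] > levels[0]
        assert levels[0] == pytest.approx(subject.TG_b, rel=1e-6)

    def test_random_parameter_draws_keep_states_non_negative(self, params,
                                                             subject, rng):
        """Randomized draws within the registry box (seeded) must keep every
        state non-negative over the full horizon."""
        from mixedmeal import BasalInfeasibleError

        n_ok = 0
        while n_ok < 15:
            values = {}
            for name in params:
                lo, hi = params.bounds(name)
                values[name] = float(np.exp(rng.uniform(np.log(lo),
                                                        np.log(hi))))
            try:
                res = simulate(params.with_values(values), subject,
                               NUTRITECH_MEAL, t_end=720,
                               grid=np.arange(0.0, 721.0, 5.0))
            except (BasalInfeasibleError, ValueError, RuntimeError):
                continue
            assert np.all(res.states >= 0)
            n_ok += 1


def test_misspecified_k16_diverges_from_fasting_tg(params, subject):
    """Hepatic secretion far above the lipolysis capacity implied by the
    reference closure drives TG steadily upward."""
    from mixedmeal.model import basal_closure, basal_state, pack_constants
    from mixedmeal.model import _rhs_c
    from scipy.integrate import odeint

    ref = basal_closure(params, subject)
    c = pack_constants(params.with_values({"k16": 0.1}), subject, ZERO_MEAL,
                       basal=ref)
    t = np.linspace(0, 720, 200)
    y = odeint(_rhs_c, basal_state(subject), t, args=(c,), tfirst=True)
    dev = np.abs(y[:, 11] - subject.TG_b)
    assert dev[-1] > dev[len(dev) // 2] > dev[10]
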