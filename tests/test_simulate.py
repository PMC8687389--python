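import numpy as np
import pytest

from aemglucose.design import REFERENCE_K, REFERENCE_L
from aemglucose.model import NOMINAL_PATIENT, build_matrices
from aemglucose.simulate import (
    MealEvent,
    ParamModulation,
    SimConfig,
    control_law,
    modulated_params,
    observer_rhs,
    run_closed_loop,
    run_scenario_1,
    run_scenario_2,
    scenario_2_meals,
)


class TestModulation:
    def test_zero_amplitude_is_identity(self):
        mod = ParamModulation(amplitude=0.0)
        for t in (0.0, 123.4, 1440.0):
            assert modulated_params(t, NOMINAL_PATIENT, mod) == NOMINAL_PATIENT

    def test_peak_hits_upper_range_value(self):
        # 30% above nominal c4 = 0.26, the upper end of its range
        mod = ParamModulation(amplitude=0.30, period=1440.0)
        p = modulated_params(360.0, NOMINAL_PATIENT, mod)  # sin = 1
        assert p.c4 == pytest.approx(0.26)
        assert p.c2 == pytest.approx(0.0195)

    def test_extrema_match_range_endpoints(self):
        mod = ParamModulation(amplitude=0.30, period=1440.0)
        ts = np.linspace(0.0, 1440.0, 2001)
        c4 = [modulated_params(t, NOMINAL_PATIENT, mod).c4 for t in ts]
        assert min(c4) == pytest.approx(0.14, rel=1e-4)
        assert max(c4) == pytest.approx(0.26, rel=1e-4)

    def test_amplitude_validation(self):
        with pytest.raises(ValueError):
            ParamModulation(amplitude=1.2)


class TestControlLaw:
    def test_zero_estimate_zero_insulin(self):
        assert control_law(np.zeros(4), REFERENCE_K) == 0.0

    def test_hyperglycemic_dose(self):
        # pure glucose deviation of 120 mg/dl at the reference gain
        u = control_law(np.array([120.0, 0.0, 0.0, 0.0]), REFERENCE_K)
        assert u == pytest.approx(0.16 * 120.0)

    def test_clamp(self):
        xhat = np.array([0.0, 0.001, 0.0, 0.0])
        assert control_law(xhat, REFERENCE_K) == 0.0
        assert control_law(xhat, REFERENCE_K, clamp=False) == pytest.approx(-0.72741)


class TestObserver:
    def test_injection_vanishes_on_exact_estimate(self, mats):
        xd = np.array([12.0, 0.001, 3.0, 1.0])
        u = 0.7
        plant = mats.A @ xd + mats.B * u + np.array([-xd[0] * xd[1], 0, 0, 0])
        obs = observer_rhs(0.0, xd, u, xd[0], mats, REFERENCE_L)
        np.testing.assert_allclose(obs, plant, rtol=1e-12)

    def test_zero_initial_error_stays_zero(self):
        """Certain case, observer started at the true state: estimates track."""
        cfg = SimConfig(K=REFERENCE_K, L=REFERENCE_L, t_end=200.0,
                        x0_abs=(80.0, 0.0, 7.0), d0=0.0)
        traj = run_closed_loop(cfg)
        err = traj.deviated() - traj.deviated_estimates()
        assert np.abs(err).max() < 1e-6


class TestClosedLoop:
    def test_equilibrium_is_invariant(self):
        cfg = SimConfig(K=REFERENCE_K, L=REFERENCE_L, t_end=300.0,
                        x0_abs=(80.0, 0.0, 7.0), d0=0.0)
        traj = run_closed_loop(cfg)
        np.testing.assert_allclose(traj.glucose, 80.0, atol=1e-6)
        np.testing.assert_allclose(traj.u, 0.0, atol=1e-8)

    def test_insulin_nonnegative_and_glucose_positive(self, scenario1_traj):
        assert (scenario1_traj.u >= 0).all()
        assert (scenario1_traj.glucose > 0).all()
        assert (scenario1_traj.glucose > 50.0).all()

    def test_meal_resets_disturbance_state(self):
        cfg = SimConfig(K=REFERENCE_K, L=REFERENCE_L, t_end=120.0,
                        x0_abs=(80.0, 0.0, 7.0))
        meals = [MealEvent(time=60.0, magnitude=6.0)]
        traj = run_closed_loop(cfg, meals=meals)
        i = np.searchsorted(traj.t, 60.0)
        assert traj.d[i - 1] < 0.5
        assert traj.d[i + 1] == pytest.approx(6.0, rel=0.05)
        # decay rate afterwards follows -c5 d
        j = np.searchsorted(traj.t, 100.0)
        assert traj.d[j] == pytest.approx(6.0 * np.exp(-0.05 * (traj.t[j] - 60.0)), rel=1e-3)

    def test_clamp_equivalence_where_unsaturated(self):
        """Disabling the clamp changes nothing while the raw control is >= 0."""
        kw = dict(K=REFERENCE_K, L=REFERENCE_L, t_end=60.0, x0_abs=(200.0, 0.001, 7.0))
        on = run_closed_loop(SimConfig(clamp=True, **kw))
        off = run_closed_loop(SimConfig(clamp=False, **kw))
        raw = off.deviated_estimates() @ REFERENCE_K
        same = raw >= 0
        # the first saturation happens later than 60 min in this setup
        assert same.all()
        np.testing.assert_allclose(on.glucose, off.glucose, rtol=1e-9)

    def test_meal_after_end_rejected(self):
        cfg = SimConfig(K=REFERENCE_K, L=REFERENCE_L, t_end=100.0)
        with pytest.raises(ValueError):
            run_closed_loop(cfg, meals=[MealEvent(time=200.0, magnitude=5.0)])


class TestScenario1:
    def test_reference_recovery(self, scenario1_traj):
        from aemglucose.metrics import glycemic_metrics

        gm = glycemic_metrics(scenario1_traj)
        assert gm.t_below_180 == pytest.approx(110.0, abs=25.0)
        assert gm.t_to_basal == pytest.approx(400.0, abs=80.0)
        assert gm.u_max <= 30.0
        assert not gm.hypo

    def test_grid_refinement_stability(self):
        """Halving integrator tolerances moves crossing times < 1 min."""
        from aemglucose.metrics import glycemic_metrics

        a = glycemic_metrics(run_scenario_1(rtol=1e-8, atol=1e-10, dt_out=0.5))
        b = glycemic_metrics(run_scenario_1(rtol=5e-9, atol=5e-11, dt_out=0.5))
        assert abs(a.t_below_180 - b.t_below_180) < 1.0
        assert abs(a.t_to_basal - b.t_to_basal) < 1.0


class TestScenario2:
    def test_deterministic_under_seed(self):
        t1 = run_scenario_2(seed=11, days=1)
        t2 = run_scenario_2(seed=11, days=1)
        np.testing.assert_array_equal(t1.glucose, t2.glucose)
        np.testing.assert_array_equal(t1.u, t2.u)

    def test_meal_protocol(self):
        rng = np.random.default_rng(5)
        meals = scenario_2_meals(rng, days=3)
        assert len(meals) == 9
        assert all(5.0 <= m.magnitude <= 10.0 for m in meals)
        windows = [(420, 540), (660, 780), (1140, 1260)]
        for day in range(3):
            day_meals = [m for m in meals if day * 1440 <= m.time < (day + 1) * 1440]
            assert len(day_meals) == 3
            for m, (lo, hi) in zip(sorted(day_meals, key=lambda m: m.time), windows):
                assert lo + 1440 * day <= m.time <= hi + 1440 * day

    def test_starts_at_basal(self):
        traj = run_scenario_2(seed=2, days=1)
        assert traj.glucose[0] == pytest.approx(80.0)
        assert (traj.u >= 0).all()
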