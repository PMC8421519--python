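"""Core model: density, ODE right-hand side, integration, extremum."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from kinresp.model import (
    KineticParams,
    Trajectory,
    extremum,
    perturbation_density,
    predict_temps,
    rhs,
    simulate,
)


def logistic_closed_form(t, T0, r, T_n):
    """Closed-form solution of the pure autoregulation (logistic) dynamics."""
    return T_n / (1.0 + (T_n / T0 - 1.0) * np.exp(-r * np.asarray(t)))


class TestPerturbationDensity:
    def test_exponential_limit_at_zero(self):
        # f(0, 1, k) = k: the s=1 density is the exponential clearance rate
        assert perturbation_density(0.0, 1, 0.4) == pytest.approx(0.4)

    def test_vanishes_at_zero_for_delayed_shapes(self):
        for s in (2, 3, 5):
            assert perturbation_density(0.0, s, 0.4) == 0.0

    @pytest.mark.parametrize("s", [1, 2, 3, 4])
    def test_normalization(self, s):
        total, err = quad(lambda t: perturbation_density(t, s, 0.4), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_by_grid_search(self):
        # mode of the gamma density is (s-1)/k; locate it by brute force
        t = np.arange(0.0, 20.0, 1e-3)
        f = perturbation_density(t, 3, 0.4)
        assert t[np.argmax(f)] == pytest.approx(5.0, abs=5e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(s=0, k=0.4), dict(s=1.5, k=0.4), dict(s=3, k=0.0), dict(s=3, k=-1.0)],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            perturbation_density(1.0, **kwargs)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            perturbation_density(-0.1, 1, 0.4)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(T_n=0.0, r=0.1, p0=0.1, k=0.4),
            dict(T_n=37.5, r=-0.1, p0=0.1, k=0.4),
            dict(T_n=37.5, r=0.1, p0=-0.1, k=0.4),
            dict(T_n=37.5, r=0.1, p0=0.1, k=0.0),
            dict(T_n=37.5, r=0.1, p0=0.1, k=0.4, s=0),
            dict(T_n=37.5, r=0.1, p0=0.1, k=0.4, s=2.5),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)

    def test_shape_coerced_to_int(self):
        assert KineticParams(37.5, 0.1, 0.1, 0.4, s=3.0).s == 3


class TestRHS:
    def test_logistic_equilibrium(self):
        p = KineticParams(T_n=37.5, r=0.04, p0=0.0, k=0.4)
        assert rhs(37.5, 0.0, p) == pytest.approx(0.0)

    def test_logistic_at_half_capacity(self):
        p = KineticParams(T_n=37.5, r=0.04, p0=0.0, k=0.4)
        assert rhs(37.5 / 2, 3.0, p) == pytest.approx(0.04 * 37.5 / 4)

    def test_perturbation_inactive_at_t0_for_delayed_shape(self):
        p = KineticParams(T_n=37.5, r=0.04, p0=5.0, k=0.4, s=3)
        assert rhs(37.5, 0.0, p) == pytest.approx(0.0)


class TestSimulate:
    def test_constant_at_equilibrium(self):
        p = KineticParams(T_n=37.5, r=0.04, p0=0.0, k=0.4)
        traj = simulate(p, np.linspace(0, 24, 25))
        assert np.allclose(traj.temps, 37.5, atol=1e-9)

    @pytest.mark.parametrize("T0", [30.0, 34.0, 40.0])
    @pytest.mark.parametrize("r", [0.02, 0.065, 0.2])
    def test_logistic_closed_form(self, T0, r):
        T_n = 37.5
        p = KineticParams(T_n=T_n, r=r, p0=0.0, k=0.4)
        t = np.linspace(0, 48, 49)
        traj = simulate(p, t, T0=T0)
        expected = logistic_closed_form(t, T0, r, T_n)
        assert np.abs(traj.temps - expected).max() < 1e-6

    def test_separable_closed_form_without_regulation(self):
        # r = 0, s = 1: dT/dt = -p0 k e^{-kt} T integrates to
        # T(t) = T0 exp(-p0 (1 - e^{-kt}))
        p = KineticParams(T_n=37.5, r=0.0, p0=0.3, k=0.4, s=1)
        t = np.linspace(0, 24, 49)
        traj = simulate(p, t)
        expected = 37.5 * np.exp(-0.3 * (1.0 - np.exp(-0.4 * t)))
        assert np.abs(traj.temps / expected - 1.0).max() < 1e-6

    def test_agrees_with_independent_tighter_solve(self, canonical_params):
        # convergence: an independently configured higher-accuracy integration
        # changes temperatures by far less than measurement precision
        t = np.linspace(0, 24, 49)
        traj = simulate(canonical_params, t)
        ref = solve_ivp(
            lambda tt, y: [rhs(y[0], tt, canonical_params)],
            (0, 24.0),
            [canonical_params.T_n],
            t_eval=t,
            method="DOP853",
            rtol=1e-11,
            atol=1e-11,
        )
        assert np.abs(traj.temps - ref.y[0]).max() < 1e-6

    def test_hypothermic_dip_with_plateau_and_recovery(self, canonical_params):
        t = np.arange(0.0, 24.001, 0.01)
        traj = simulate(canonical_params, t)
        T0, T_min, T_end = traj.temps[0], traj.temps.min(), traj.temps[-1]
        assert T_min < canonical_params.T_n - 2.0  # clear dip
        # delayed onset: the first two hours lose <15% of the total drop
        drop_2h = T0 - traj.temps[np.searchsorted(t, 2.0)]
        assert drop_2h < 0.15 * (T0 - T_min)
        assert T_end > T_min + 1.0  # recovery toward T_n

    def test_invalid_grid_rejected(self, canonical_params):
        with pytest.raises(ValueError):
            simulate(canonical_params, [1.0, 2.0])  # must start at 0
        with pytest.raises(ValueError):
            simulate(canonical_params, [0.0, 0.0, 1.0])


class TestPredictTemps:
    def test_matches_adaptive_solver(self, canonical_params):
        t = np.arange(0.0, 24.001, 0.05)
        traj = simulate(canonical_params, t)
        pred = predict_temps(canonical_params, t)
        assert np.abs(traj.temps - pred).max() < 2e-6

    def test_quadrature_step_convergence(self, canonical_params):
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        a = predict_temps(canonical_params, t, grid_step=0.02)
        b = predict_temps(canonical_params, t, grid_step=0.01)
        assert np.abs(a - b).max() < 1e-8

    @pytest.mark.parametrize("p0", [0.0, 0.1, 0.3, 1.0])
    @pytest.mark.parametrize("s", [1, 2, 3, 4])
    def test_positive_and_bounded(self, p0, s):
        p = KineticParams(T_n=37.5, r=0.06, p0=p0, k=0.5, s=s)
        t = np.linspace(0, 48, 97)
        for T0 in (30.0, 37.5, 40.0):
            temps = predict_temps(p, t, T0=T0)
            assert np.all(temps > 0)
            assert temps.max() <= max(T0, 37.5) + 1e-6

    def test_scalar_time(self, canonical_params):
        v = predict_temps(canonical_params, 12.0)
        assert isinstance(v, float) and 25 < v < 38


class TestExtremum:
    def test_constant_trajectory_degenerate(self):
        traj = Trajectory(np.linspace(0, 24, 100), np.full(100, 37.5))
        ex = extremum(traj)
        assert ex.degenerate
        assert ex.T_min == pytest.approx(37.5)

    def _extremum_for(self, params):
        t = np.arange(0.0, 24.001, 0.01)
        return extremum(simulate(params, t))

    def test_damage_strength_shifts_minimum_vertically(self, canonical_params):
        # exact shifts frozen from 1-d minimization of the semi-analytic
        # trajectory: raising p0 0.25 -> 0.35 deepens the minimum by 2.19 degC
        # while moving its time by only 0.109 h
        base = self._extremum_for(canonical_params)
        raised = self._extremum_for(canonical_params.with_(p0=0.35))
        assert base.T_min - raised.T_min == pytest.approx(2.185, abs=0.02)
        assert raised.t_min - base.t_min == pytest.approx(0.109, abs=0.02)

    def test_clearance_rate_shifts_minimum_earlier_and_lower(self, canonical_params):
        base = self._extremum_for(canonical_params)
        faster = self._extremum_for(canonical_params.with_(k=1.2))
        assert faster.t_min < base.t_min - 0.1
        assert faster.T_min < base.T_min
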