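"""Unit and property tests for the kinetic core: temperature gates, heating
law, ODE right-hand side, forward simulation, observables and onset times."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mhckin import (
    HeatingParameters,
    KineticParameters,
    SystemState,
    Trajectory,
    degradation_rate_factor,
    derivatives,
    heating_time_within,
    observe,
    onset_time,
    polymerization_rate_factor,
    simulate,
    step_convergence,
    temperature_at,
)

T1, D = 29.61, 22.34
REF_K = dict(k1=0.044, k2=0.053, T1=T1, d=D, T_opt=60.0, beta=0.214)


class TestRateFactors:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (0.0, 0.0),  # continuity limit at zero temperature
            (T1, 0.5),  # sigmoid midpoint at the inflection
            (60.0, 1.0 - 1.0 / (1.0 + (60.0 / T1) ** D)),  # direct evaluation
        ],
    )
    def test_sigmoid_values(self, T, expected):
        assert polymerization_rate_factor(T, T1, D) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "T, expected",
        [
            (60.0, 1.0),  # Gaussian peak at the optimum
            (60.214, math.exp(-0.5)),  # one width away
            (59.0, math.exp(-1.0 / (2 * 0.214**2))),  # direct evaluation
        ],
    )
    def test_gaussian_values(self, T, expected):
        assert degradation_rate_factor(T, 60.0, 0.214) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "call",
        [
            lambda: polymerization_rate_factor(-1.0, T1, D),
            lambda: polymerization_rate_factor(10.0, -5.0, D),
            lambda: polymerization_rate_factor(10.0, T1, 0.0),
            lambda: degradation_rate_factor(10.0, 60.0, 0.0),
        ],
    )
    def test_domain_errors(self, call):
        with pytest.raises(ValueError):
            call()

    @given(st.floats(min_value=0.0, max_value=99.0))
    def test_sigmoid_strictly_increasing(self, T):
        assert polymerization_rate_factor(T + 1.0, T1, D) > polymerization_rate_factor(
            T, T1, D
        )

    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_gaussian_symmetric_about_optimum(self, dT):
        lo = degradation_rate_factor(60.0 - dT, 60.0, 0.7)
        hi = degradation_rate_factor(60.0 + dT, 60.0, 0.7)
        assert lo == pytest.approx(hi, rel=1e-12)


class TestHeating:
    H = HeatingParameters(alpha=0.3, T_max=60.0, T_init=0.0)

    def test_initial_and_asymptotic_values(self):
        assert temperature_at(0.0, self.H) == 0.0
        assert temperature_at(1e4, self.H) == pytest.approx(60.0, abs=1e-8)

    def test_closed_form_value(self):
        assert temperature_at(16.0, self.H) == pytest.approx(
            60.0 * (1 - math.exp(-4.8)), rel=1e-12
        )

    def test_monotone_increasing(self):
        t = np.linspace(0, 60, 601)
        assert np.all(np.diff(temperature_at(t, self.H)) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            temperature_at(-0.1, self.H)

    def test_time_within_margin(self):
        t = heating_time_within(self.H, 0.5)
        assert 60.0 - temperature_at(t, self.H) == pytest.approx(0.5, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HeatingParameters(alpha=0.0, T_max=60.0)
        with pytest.raises(ValueError):
            HeatingParameters(alpha=0.3, T_max=10.0, T_init=20.0)


class TestDerivatives:
    def test_cold_state_inert(self, reference):
        k, h, _ = reference
        dX, dP, dT = derivatives(SystemState(t=0, X=1, P=0, T=0), k, h)
        # both temperature gates are closed at 0 °C (Gaussian tail underflows)
        assert dX == pytest.approx(0.0, abs=1e-50)
        assert dP == pytest.approx(0.0, abs=1e-50)
        assert dT == pytest.approx(0.3 * 60.0)

    def test_no_reactions_without_rates(self, reference):
        _, h, _ = reference
        k = KineticParameters(**{**REF_K, "k1": 0.0, "k2": 0.0})
        dX, dP, _ = derivatives(SystemState(t=5, X=0.7, P=0.2, T=45.0), k, h)
        assert dX == 0.0 and dP == 0.0

    def test_hot_state_rates(self, reference):
        k, h, _ = reference
        dX, dP, _ = derivatives(SystemState(t=30, X=1, P=0, T=60.0), k, h)
        s60 = polymerization_rate_factor(60.0, k.T1, k.d)
        assert dX == pytest.approx(-(k.k1 * s60 + k.k2), rel=1e-9)
        assert dP == pytest.approx(k.k1 * s60, rel=1e-9)

    def test_total_mass_only_degrades(self, reference):
        k, h, _ = reference
        s = SystemState(t=20, X=0.5, P=0.3, T=58.0)
        dX, dP, _ = derivatives(s, k, h)
        g = degradation_rate_factor(s.T, k.T_opt, k.beta)
        assert dX <= 0
        assert dX + dP == pytest.approx(-k.k2 * g * (s.X + s.P), rel=1e-12)


class TestSimulate:
    def test_initial_condition_and_temperature_track(self, reference, fine_trajectory):
        _, h, _ = reference
        traj = fine_trajectory
        assert traj.X[0] == 1.0 and traj.P[0] == 0.0
        assert np.max(np.abs(traj.T - temperature_at(traj.times, h))) <= 1e-6

    def test_no_reaction_conserves_everything(self, reference):
        _, h, _ = reference
        k = KineticParameters(**{**REF_K, "k1": 0.0, "k2": 0.0})
        traj = simulate(k, h, t_end=60.0, dt_out=1.0)
        assert np.all(traj.X == 1.0) and np.all(traj.P == 0.0)

    def test_polymerization_only_conserves_mass(self, reference):
        _, h, _ = reference
        k = KineticParameters(**{**REF_K, "k2": 0.0})
        traj = simulate(k, h, t_end=60.0, dt_out=0.5)
        assert np.max(np.abs(traj.X + traj.P - 1.0)) <= 1e-9

    def test_total_mass_non_increasing(self, fine_trajectory):
        total = fine_trajectory.X + fine_trajectory.P
        assert np.all(np.diff(total) <= 1e-12)
        assert np.all(np.diff(fine_trajectory.X) <= 1e-12)

    def test_constant_temperature_closed_form(self, reference):
        k, _, _ = reference
        h60 = HeatingParameters(alpha=0.3, T_max=60.0, T_init=60.0)
        traj = simulate(k, h60, t_end=60.0, dt_out=1.0)
        s60 = polymerization_rate_factor(60.0, k.T1, k.d)
        rate = k.k1 * s60 + k.k2  # Gaussian gate is exactly 1 at T_opt
        X_exact = np.exp(-rate * traj.times)
        P_exact = np.exp(-k.k2 * traj.times) - np.exp(-rate * traj.times)
        assert np.max(np.abs(traj.X - X_exact)) <= 1e-8
        assert np.max(np.abs(traj.P - P_exact)) <= 1e-8

    def test_independent_integrator_oracle(self, reference):
        """Default RK4 path vs scipy's DOP853 at tight tolerance."""
        k, h, _ = reference

        def rhs(t, y):
            T = temperature_at(t, h)
            s = polymerization_rate_factor(T, k.T1, k.d)
            g = degradation_rate_factor(T, k.T_opt, k.beta)
            return [
                -k.k1 * s * y[0] - k.k2 * g * y[0],
                k.k1 * s * y[0] - k.k2 * g * y[1],
            ]

        times = np.linspace(0.0, 60.0, 61)
        sol = solve_ivp(
            rhs, (0.0, 60.0), [1.0, 0.0], t_eval=times,
            method="DOP853", rtol=1e-11, atol=1e-13,
        )
        traj = simulate(k, h, times=times)
        assert np.max(np.abs(traj.X - sol.y[0])) <= 1e-6
        assert np.max(np.abs(traj.P - sol.y[1])) <= 1e-6

    def test_step_halving_converged(self, reference):
        k, h, _ = reference
        assert step_convergence(k, h, np.linspace(0, 60, 31)) <= 1e-6

    def test_convergence_check_flags_coarse_step(self, reference):
        k, h, _ = reference
        with pytest.raises(RuntimeError, match="not converged"):
            simulate(k, h, t_end=60.0, dt_out=20.0, dt=20.0, check_convergence=True)

    def test_invalid_grid_rejected(self, reference):
        k, h, _ = reference
        with pytest.raises(ValueError):
            simulate(k, h, t_end=-1.0)
        with pytest.raises(ValueError):
            simulate(k, h, times=[1.0, 2.0])  # must start at 0

    @given(
        k1=st.floats(min_value=0.0, max_value=0.2),
        k2=st.floats(min_value=0.0, max_value=0.2),
        beta=st.floats(min_value=0.05, max_value=2.0),
    )
    def test_monotone_dissipation_property(self, k1, k2, beta):
        k = KineticParameters(k1=k1, k2=k2, T1=T1, d=D, T_opt=60.0, beta=beta)
        h = HeatingParameters(alpha=0.3, T_max=60.0)
        traj = simulate(k, h, t_end=20.0, dt_out=1.0, dt=0.05)
        total = traj.X + traj.P
        assert np.all(np.diff(traj.X) <= 1e-12)
        assert np.all(np.diff(total) <= 1e-12)
        assert np.all(traj.X >= 0) and np.all(traj.P >= 0)


class TestObserveAndOnset:
    def test_channel_definitions(self, fine_trajectory):
        red = observe(fine_trajectory, "reduced")
        non = observe(fine_trajectory, "non_reduced")
        assert np.array_equal(red.values, fine_trajectory.X + fine_trajectory.P)
        assert np.array_equal(non.values, fine_trajectory.X)
        assert np.all(red.values >= non.values)

    def test_unknown_channel_rejected(self, fine_trajectory):
        with pytest.raises(ValueError, match="unknown channel"):
            observe(fine_trajectory, "oxidized")

    def test_never_crossed_returns_infinity(self, reference):
        _, h, _ = reference
        k = KineticParameters(**{**REF_K, "k1": 0.0, "k2": 0.0})
        traj = simulate(k, h, t_end=60.0, dt_out=1.0)
        assert onset_time(traj, "reduced", 0.95) == math.inf

    def test_onset_brackets(self, fine_trajectory):
        """Monomer loss starts minutes after unfolding begins; total MHC only
        declines once the protease gate opens, more than ten minutes later."""
        t_non = onset_time(fine_trajectory, "non_reduced", 0.95)
        t_red = onset_time(fine_trajectory, "reduced", 0.95)
        assert 2.0 < t_non < 5.0
        assert 16.0 < t_red < 20.0

    def test_onset_grid_independent(self, reference, fine_trajectory):
        k, h, _ = reference
        coarse = simulate(k, h, t_end=60.0, dt_out=0.5)
        for channel in ("reduced", "non_reduced"):
            assert onset_time(coarse, channel, 0.95) == pytest.approx(
                onset_time(fine_trajectory, channel, 0.95), abs=5e-3
            )

    def test_fraction_domain(self, fine_trajectory):
        with pytest.raises(ValueError):
            onset_time(fine_trajectory, "reduced", 1.5)

    def test_gate_separation(self, reference):
        """The unfolding gate opens (>0.5) at least 10 min before the
        protease gate reaches even 1% activity."""
        k, h, _ = reference
        t = np.arange(0.0, 60.0, 0.001)
        T = temperature_at(t, h)
        s = polymerization_rate_factor(T, k.T1, k.d)
        g = degradation_rate_factor(T, k.T_opt, k.beta)
        t_poly = t[np.argmax(s > 0.5)]
        t_deg = t[np.argmax(g > 0.01)]
        assert t_deg - t_poly >= 10.0


class TestValidation:
    def test_kinetic_parameter_invariants(self):
        with pytest.raises(ValueError):
            KineticParameters(**{**REF_K, "k1": -0.1})
        with pytest.raises(ValueError):
            KineticParameters(**{**REF_K, "beta": 0.0})
        with pytest.raises(ValueError):
            KineticParameters(**{**REF_K, "T_opt": 150.0})

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            Trajectory(times=[1.0, 2.0], X=[1, 1], P=[0, 0], T=[0, 0])
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 0.0], X=[1, 1], P=[0, 0], T=[0, 0])
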