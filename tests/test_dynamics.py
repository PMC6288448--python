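"""Transfer and selection steps, the full simulation loop, and its oracle."""

import logging
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from hgtsim.compatibility import CompatibilityMatrix
from hgtsim.dynamics import (
    MINUTES_PER_DAY,
    CommunityState,
    MechanismSpec,
    SimulationConfig,
    convergence_check,
    full_spread_time,
    growth_step,
    hgt_step,
    run_simulation,
)
from hgtsim.errors import ConfigurationError, InvalidInputError


def ones_mechanism(n: int, gamma: float, name: str = "conjugation") -> MechanismSpec:
    return MechanismSpec(name, gamma, CompatibilityMatrix(name, np.ones((n, n))))


class TestGrowthStep:
    def test_fixed_points_zero_and_one(self):
        state = CommunityState(np.array([0.0, 1e4]), np.array([1e4, 0.0]))
        out = growth_step(state, fitness_per_min=1e-3, dt=100.0)
        assert out.fractions.tolist() == [0.0, 1.0]

    def test_zero_fitness_is_identity(self):
        state = CommunityState(np.array([3.0, 7.0]), np.array([5.0, 2.0]))
        out = growth_step(state, fitness_per_min=0.0, dt=50.0)
        assert np.array_equal(out.plasmid_pos, state.plasmid_pos)
        assert np.array_equal(out.plasmid_neg, state.plasmid_neg)

    def test_half_fraction_doubling_advantage_gives_two_thirds(self):
        state = CommunityState(np.array([500.0]), np.array([500.0]))
        out = growth_step(state, fitness_per_min=math.log(2) / 30.0, dt=30.0)
        assert out.fractions[0] == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_composition_over_dt_equals_single_double_step(self):
        state = CommunityState(np.array([1.0, 250.0]), np.array([9999.0, 9750.0]))
        m = 2e-4
        twice = growth_step(growth_step(state, m, 75.0), m, 75.0)
        once = growth_step(state, m, 150.0)
        assert np.allclose(twice.fractions, once.fractions, rtol=1e-12)

    def test_totals_preserved(self):
        state = CommunityState(np.array([1.0, 250.0]), np.array([9999.0, 9750.0]))
        out = growth_step(state, 1e-3, 500.0)
        assert np.allclose(out.totals, state.totals, rtol=1e-15)


class TestHgtStep:
    def test_no_donors_no_change(self):
        n = 5
        state = CommunityState(np.zeros(n), np.full(n, 1e4))
        out = hgt_step(state, [ones_mechanism(n, 1e-8)], dt=10.0)
        assert not out.plasmid_pos.any()

    def test_transfer_moves_mass_conservatively(self):
        state = CommunityState(np.array([100.0, 0.0]), np.array([9900.0, 1e4]))
        out = hgt_step(state, [ones_mechanism(2, 1e-6)], dt=1.0)
        assert (out.plasmid_pos > state.plasmid_pos).all()
        assert np.allclose(out.totals, state.totals, rtol=1e-15)

    def test_two_mechanisms_add_linearly(self):
        n = 3
        rng = np.random.default_rng(0)
        a1 = CompatibilityMatrix("conjugation", rng.uniform(size=(n, n)))
        a2 = CompatibilityMatrix("vesicle", rng.uniform(size=(n, n)))
        state = CommunityState(np.array([50.0, 1.0, 0.0]),
                               np.array([9950.0, 9999.0, 1e4]))
        m1 = MechanismSpec("conjugation", 1e-7, a1)
        m2 = MechanismSpec("vesicle", 3e-7, a2)
        both = hgt_step(state, [m1, m2], dt=1.0)
        d1 = hgt_step(state, [m1], dt=1.0).plasmid_pos - state.plasmid_pos
        d2 = hgt_step(state, [m2], dt=1.0).plasmid_pos - state.plasmid_pos
        assert np.allclose(both.plasmid_pos - state.plasmid_pos, d1 + d2, rtol=1e-12)

    def test_disabled_mechanism_contributes_nothing(self):
        state = CommunityState(np.array([100.0, 0.0]), np.array([9900.0, 1e4]))
        mech = ones_mechanism(2, 1e-6)
        mech.enabled = False
        out = hgt_step(state, [mech], dt=1.0)
        assert np.array_equal(out.plasmid_pos, state.plasmid_pos)

    def test_coarse_step_is_capped_and_warned(self, caplog):
        state = CommunityState(np.array([1e4, 0.0]), np.array([0.0, 1e4]))
        with caplog.at_level(logging.WARNING, logger="hgtsim.dynamics"):
            out = hgt_step(state, [ones_mechanism(2, 1e-2)], dt=10.0)
        assert out.plasmid_neg[1] == 0.0  # capped at the available pool
        assert out.plasmid_pos[1] == 1e4
        assert any("cap" in rec.message for rec in caplog.records)

    def test_dimension_mismatch_rejected(self):
        state = CommunityState(np.zeros(3), np.full(3, 1e4))
        with pytest.raises(ConfigurationError):
            hgt_step(state, [ones_mechanism(4, 1e-8)], dt=1.0)

    def test_single_coarse_step_matches_fine_substeps(self):
        # one dt=10 step vs 1000 substeps of the same mass-action law
        gamma, dt = 1e-8, 10.0
        state = CommunityState(np.array([5e3, 10.0]), np.array([5e3, 9990.0]))
        coarse = hgt_step(state, [ones_mechanism(2, gamma)], dt=dt)
        fine = state
        for _ in range(1000):
            fine = hgt_step(fine, [ones_mechanism(2, gamma)], dt=dt / 1000)
        assert np.allclose(coarse.plasmid_pos, fine.plasmid_pos, rtol=1e-3)


class TestRunSimulation:
    def test_no_hgt_follows_logistic_closed_form(self):
        config = SimulationConfig(
            n_species=3, total_time=2e5, n_steps=10_000, fitness=0.02,
            fitness_input_unit="per-day", initial_fraction=1e-4,
        )
        traj = run_simulation(config, [])
        m = config.fitness_per_min
        f0 = config.initial_fraction
        expected = f0 * np.exp(m * traj.times) / (1 + f0 * (np.exp(m * traj.times) - 1))
        assert np.allclose(traj.fractions[:, 0], expected, rtol=1e-9, atol=1e-12)
        assert not traj.fractions[:, 1:].any()
        assert traj.full_spread_time is None

    def test_frozen_community_stays_constant(self):
        config = SimulationConfig(n_species=4, total_time=1e4, n_steps=100, fitness=0.0)
        traj = run_simulation(config, [ones_mechanism(4, 0.0)])
        assert np.array_equal(traj.fractions[0], traj.fractions[-1])

    def test_per_species_totals_conserved_through_mixed_run(self, small_config,
                                                            small_mechanisms):
        traj = run_simulation(small_config, small_mechanisms)
        assert traj.fractions.min() >= 0.0
        assert traj.fractions.max() <= 1.0
        # totals enter fractions; spot-check via an explicit re-run of steps
        assert traj.full_spread_time is not None

    def test_fractions_monotone_in_time(self, small_config, small_mechanisms):
        traj = run_simulation(small_config, small_mechanisms)
        assert (np.diff(traj.fractions, axis=0) >= -1e-12).all()

    def test_deterministic_given_matrices(self, small_config, small_mechanisms):
        t1 = run_simulation(small_config, small_mechanisms)
        t2 = run_simulation(small_config, small_mechanisms)
        assert np.array_equal(t1.fractions, t2.fractions)
        assert t1.full_spread_time == t2.full_spread_time

    def test_enabled_mechanism_without_matrix_rejected(self):
        config = SimulationConfig(n_species=2, total_time=100.0, n_steps=10)
        with pytest.raises(ConfigurationError):
            run_simulation(config, [MechanismSpec("conjugation", 1e-8, None)])

    def test_record_every_thins_but_keeps_endpoints(self, small_config,
                                                    small_mechanisms):
        import dataclasses
        config = dataclasses.replace(small_config, record_every=7)
        traj = run_simulation(config, small_mechanisms)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == pytest.approx(config.total_time)

    def test_two_species_run_matches_continuous_oracle(self):
        # independent fine integration of transfer + selection ODEs
        gamma, density, m = 1e-8, 1e4, 0.02 / MINUTES_PER_DAY
        f0 = 1e-4
        horizon = 90.0 * MINUTES_PER_DAY

        def rhs(_, y):
            bp = y[:2]
            bn = np.array([density, density]) - bp
            transfer = gamma * bn * bp.sum()
            growth = m * bp * bn / density
            return transfer + growth

        sol = solve_ivp(rhs, (0, horizon), [density * f0, 0.0], rtol=1e-10,
                        atol=1e-8, dense_output=True, method="LSODA")

        def min_frac(t):
            return sol.sol(t).min() / density - 0.99

        oracle_time = brentq(min_frac, 1.0, horizon)

        config = SimulationConfig(n_species=2, total_time=horizon, n_steps=10_000,
                                  initial_fraction=f0)
        traj = run_simulation(config, [ones_mechanism(2, gamma)])
        assert traj.full_spread_time == pytest.approx(oracle_time, rel=5e-3)


class TestFullSpreadDetection:
    def make_trajectory(self, fractions):
        fractions = np.asarray(fractions, dtype=float)
        config = SimulationConfig(n_species=fractions.shape[1], total_time=10.0,
                                  n_steps=max(1, fractions.shape[0] - 1))
        times = np.linspace(0, 10.0, fractions.shape[0])
        from hgtsim.dynamics import Trajectory
        return Trajectory(times=times, fractions=fractions, full_spread_time=None,
                          config=config)

    def test_absent_when_any_species_stays_below_threshold(self):
        traj = self.make_trajectory([[0.0, 0.0], [1.0, 0.5], [1.0, 0.9]])
        assert full_spread_time(traj) is None

    def test_first_crossing_reported(self):
        traj = self.make_trajectory([[0.1, 0.2], [0.995, 0.3], [1.0, 0.99], [1.0, 1.0]])
        assert full_spread_time(traj) == pytest.approx(10.0 * 2 / 3)

    def test_zero_threshold_is_first_record(self):
        traj = self.make_trajectory([[0.0, 0.0], [0.5, 0.5]])
        assert full_spread_time(traj, threshold=0.0) == 0.0

    def test_invalid_threshold_rejected(self):
        traj = self.make_trajectory([[0.0, 0.0]])
        with pytest.raises(InvalidInputError):
            full_spread_time(traj, threshold=1.5)


class TestConvergence:
    def test_smooth_scenario_converges(self):
        config = SimulationConfig(n_species=2, total_time=30 * MINUTES_PER_DAY,
                                  n_steps=2000, per_species_density=1e5,
                                  initial_fraction=1e-3)
        report = convergence_check(config, [ones_mechanism(2, 1e-8)], refinements=2)
        assert report.converged
        # first-order scheme plus detection at recording resolution: every
        # refinement moves the result by well under a percent
        assert all(c <= 0.01 for c in report.relative_changes)

    def test_coarse_capped_run_is_flagged(self):
        config = SimulationConfig(n_species=2, total_time=30 * MINUTES_PER_DAY,
                                  n_steps=4, initial_fraction=1e-3)
        report = convergence_check(config, [ones_mechanism(2, 1e-6)], refinements=3)
        assert report.cap_events[0] > 0
        assert not report.converged


class TestValidation:
    def test_negative_densities_rejected(self):
        with pytest.raises(InvalidInputError):
            CommunityState(np.array([-1.0]), np.array([1.0]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 0},
            {"total_time": 0.0},
            {"n_steps": 0},
            {"initial_fraction": 0.0},
            {"initial_fraction": 1.5},
            {"per_species_density": -1.0},
            {"fitness_input_unit": "per-fortnight"},
            {"initial_species": 100},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_negative_gamma_rejected(self):
        with pytest.raises(InvalidInputError):
            MechanismSpec("conjugation", -1e-8)
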