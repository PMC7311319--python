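"""Virion mechanics: walk constants, hazards, infection outcomes, bursts."""

import math

import numpy as np
import pytest

from phagefilm.params import SpaceConfig
from phagefilm.phage import (InfectionOutcome, PhagePopulation,
                             attempt_infection, infection_stage,
                             interaction_check, interaction_probability,
                             interaction_rate_field, lyse_cells,
                             node_interaction_rate, random_walk,
                             remaining_time, removal_check,
                             removal_probability, stay_probability, step_time,
                             steps_per_iteration, sweep_free_phages, TOP_PAD)
from phagefilm.space import build_grid, distance_field

D_P = 38.2  # um^2/s


class TestWalkConstants:
    def test_steps_per_iteration_reference(self):
        assert steps_per_iteration(D_P, 450.0, 3.0) == 955

    def test_zero_diffusivity_means_no_steps(self):
        assert steps_per_iteration(0.0, 450.0, 3.0) == 0

    def test_doubling_dt_doubles_n(self):
        n1 = steps_per_iteration(D_P, 450.0, 3.0)
        n2 = steps_per_iteration(D_P, 900.0, 3.0)
        assert abs(n2 - 2 * n1) <= 1

    def test_step_time_reference(self):
        assert step_time(D_P, 3.0) == pytest.approx(0.4712, abs=1e-4)

    def test_step_time_scales_with_dl_squared(self):
        assert step_time(D_P, 12.0) == pytest.approx(16 * step_time(D_P, 3.0))

    def test_n_dtp_recovers_dt(self):
        n, dtp = steps_per_iteration(D_P, 450.0, 3.0), step_time(D_P, 3.0)
        assert abs(n * dtp - 450.0) <= dtp

    def test_step_time_requires_positive_diffusivity(self):
        with pytest.raises(ValueError):
            step_time(0.0, 3.0)


class TestStayProbability:
    def test_two_dimensional_value(self):
        p = stay_probability(1)
        assert p == pytest.approx(math.erf(1 / math.sqrt(2 * math.pi)))
        assert 0.42 <= p < 0.43  # prints as 0.42 under truncation

    def test_three_dimensional_value(self):
        assert round(stay_probability(4), 2) == 0.22

    def test_decreasing_in_dimension_constant(self):
        assert stay_probability(4) < stay_probability(1)

    def test_invalid_constant_rejected(self):
        with pytest.raises(ValueError):
            stay_probability(2)


class TestNodeInteractionRate:
    def test_empty_node_is_zero(self):
        assert node_interaction_rate([], [], 1e-12) == 0.0

    def test_single_reference_cell(self):
        # one cell of mass m_s at I = 0.067 contributes 0.067 s^-1
        assert node_interaction_rate([1e-12], [0.067], 1e-12) == pytest.approx(0.067)

    def test_additive_in_individuals(self):
        one = node_interaction_rate([1.3e-12], [0.09], 1e-12)
        two = node_interaction_rate([1.3e-12] * 2, [0.09] * 2, 1e-12)
        assert two == pytest.approx(2 * one)


class TestHazards:
    def test_removal_zero_at_contact_or_zero_rate(self):
        assert removal_probability(0.0, 0.1, 1.309e-4) == 0.0
        assert removal_probability(10.0, 0.0, 1.309e-4) == 0.0

    def test_removal_reference_value(self):
        p = removal_probability(10.0, 0.1, 1.309e-4)
        assert p == pytest.approx(1.31e-3, rel=1e-2)

    def test_interaction_reference_value(self):
        p = interaction_probability(2.48e-3, 0.0, 0.4712)
        assert p == pytest.approx(1.168e-3, rel=1e-3)

    def test_interaction_never_without_biomass(self, rng):
        assert not any(interaction_check(0.0, 0.0, 0.4712, rng) for _ in range(100))

    def test_interaction_certain_in_dense_limit(self):
        assert interaction_probability(1e9, 1e9, 0.4712) == pytest.approx(1.0)

    @pytest.mark.parametrize("x", [1e-3, 0.05, 0.5])
    def test_monte_carlo_matches_closed_form(self, x):
        """Empirical frequencies of both checks match 1 - exp(-x) within 3
        binomial sigma (n = 2e4 per point; the acceptance suite repeats this
        at 1e5)."""
        n = 20_000
        p = -math.expm1(-x)
        rng = np.random.default_rng(hash(("hazard", x)) % 2**31)
        dtp_h = 1.309e-4
        d = math.sqrt(x / dtp_h)  # delta_P = 1
        hits_r = sum(removal_check(d, 1.0, dtp_h, rng) for _ in range(n))
        hits_i = sum(interaction_check(x / 0.4712, 0.0, 0.4712, rng) for _ in range(n))
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hits_r - n * p) < 3 * sigma
        assert abs(hits_i - n * p) < 3 * sigma


class TestRemainingTime:
    def test_full_walk_gives_full_dt(self):
        assert remaining_time(0.125, 955, 955) == pytest.approx(0.125)

    def test_no_steps_gives_zero(self):
        assert remaining_time(0.125, 0, 955) == 0.0
        assert remaining_time(0.125, 0, 0) == 0.0

    def test_half_walk_gives_half_dt(self):
        assert remaining_time(0.125, 477.5, 955) == pytest.approx(0.0625)

    def test_remaining_mode(self):
        assert remaining_time(0.125, 200, 955, mode="remaining") == pytest.approx(
            0.125 * 755 / 955
        )


def _one_host_pop(population, strain_code, **kw):
    population.add((3, 3), strain=strain_code, **kw)
    return population


class TestAttemptInfection:
    def test_empty_node_none(self, population, rng):
        out, host = attempt_infection(population, np.array([]), 0.125, 2.92, 0.0, rng)
        assert out is InfectionOutcome.NONE and host == -1

    def test_zero_contact_time_none(self, population, rng):
        _one_host_pop(population, 0)
        out, _ = attempt_infection(population, np.array([0]), 0.0, 2.92, 0.0, rng)
        assert out is InfectionOutcome.NONE

    @pytest.mark.parametrize("strain_code, expected", [
        (0, InfectionOutcome.INFECTED),
        (1, InfectionOutcome.PASS_THROUGH),
        (2, InfectionOutcome.ABORTIVE_KILL),
        (3, InfectionOutcome.PHAGE_NEUTRALIZED),
    ])
    def test_outcome_by_resistance_mode(self, population, rng, strain_code, expected):
        _one_host_pop(population, strain_code)
        # enormous contact time forces the trigger to fire
        out, host = attempt_infection(population, np.array([0]), 1e9, 2.92, 5.0, rng)
        assert out is expected
        if expected is InfectionOutcome.INFECTED:
            assert population.infected[0]
            assert population.infection_time[0] == 5.0

    def test_halt_on_contact_sets_flag(self, population, rng):
        _one_host_pop(population, 4)  # surface-resistant, halting
        out, _ = attempt_infection(population, np.array([0]), 1e9, 2.92, 0.0, rng)
        assert out is InfectionOutcome.PASS_THROUGH
        assert population.halted[0]

    def test_superinfection_consumes_phage_without_reset(self, population, rng):
        _one_host_pop(population, 0, infected=True, infection_time=1.0)
        out, _ = attempt_infection(population, np.array([0]), 1e9, 2.92, 9.0, rng)
        assert out is InfectionOutcome.SUPERINFECTION
        assert population.infection_time[0] == 1.0

    def test_host_draw_weighted_by_mass_times_rate(self, population, rng):
        """Selection frequency proportional to m_i * I_i."""
        population.add((3, 3), strain=0, mass=1e-12)
        population.add((3, 3), strain=0, mass=3e-12)
        picks = np.zeros(2)
        for _ in range(4000):
            _, host = attempt_infection(population, np.array([0, 1]), 0.0, 2.92,
                                        0.0, rng)
            picks[host] += 1
        assert picks[1] / picks.sum() == pytest.approx(0.75, abs=0.03)

    def test_infection_hazard_monte_carlo(self, strain_table):
        """Empirical infection fraction matches 1 - exp(-gamma dtr)."""
        from tests.conftest import make_population

        rng = np.random.default_rng(99)
        n = 20_000
        gamma, dtr = 2.92, 0.125
        p = -math.expm1(-gamma * dtr)
        hits = 0
        pop = make_population(strain_table)
        pop.add((0, 0), strain=0)
        for _ in range(n):
            pop.infected[0] = False
            out, _ = attempt_infection(pop, np.array([0]), dtr, gamma, 0.0, rng)
            hits += out is InfectionOutcome.INFECTED
        assert abs(hits - n * p) < 3 * math.sqrt(n * p * (1 - p))


class TestLysis:
    def test_burst_after_incubation(self, population):
        phages = PhagePopulation(2)
        population.add((4, 4), strain=0, infected=True, infection_time=0.0)
        tau_h = 28.8 / 60
        n, _ = lyse_cells(population, phages, now_h=0.5, tau_h=tau_h, beta=120)
        assert n == 1
        assert len(phages) == 120
        assert np.all(phages.pos == [4, 4])
        assert len(population) == 0

    def test_no_burst_before_incubation(self, population):
        phages = PhagePopulation(2)
        population.add((4, 4), strain=0, infected=True, infection_time=0.0)
        n, _ = lyse_cells(population, phages, now_h=20 / 60, tau_h=28.8 / 60, beta=120)
        assert n == 0 and len(phages) == 0 and len(population) == 1


class TestSweepFreePhages:
    def test_phage_off_biofilm_removed_on_biomass_kept(self, population):
        phages = PhagePopulation(2)
        population.add((2, 2), strain=0)
        phages.add([[2, 2], [7, 7]])
        occ = np.pad(population.node_mass((10, 10)) > 0,
                     ((0, 0), (0, TOP_PAD)), constant_values=False)
        removed = sweep_free_phages(phages, occ)
        assert removed == 1
        assert tuple(phages.pos[0]) == (2, 2)

    def test_empty_grid_removes_all(self):
        phages = PhagePopulation(2)
        phages.add(np.tile([3, 3], (7, 1)))
        occ = np.zeros((10, 10 + TOP_PAD), dtype=bool)
        assert sweep_free_phages(phages, occ) == 7


def _walk_setup(nx, ny, dim=2):
    if dim == 2:
        cfg = SpaceConfig(x_max_um=3 * nx, y_max_um=3 * ny, dl_um=3)
        shape_ext = (nx, ny + TOP_PAD)
    else:
        cfg = SpaceConfig(x_max_um=3 * nx, y_max_um=3 * ny, z_max_um=3 * nx, dl_um=3)
        shape_ext = (nx, ny + TOP_PAD, nx)
    grid = build_grid(cfg)
    ix = np.zeros(shape_ext)
    dist = np.zeros(shape_ext)  # on-biofilm everywhere: no advective removal
    return grid, ix, dist


class TestRandomWalk:
    def test_infinite_interaction_stops_within_one_step(self, rng):
        grid, ix, dist = _walk_setup(10, 10)
        ix[:] = 1e12
        phages = PhagePopulation(2)
        phages.add(np.tile([5, 5], (200, 1)))
        random_walk(phages, grid, ix, dist, 50, 0.4712, 0.0, rng)
        assert np.all(phages.stopped)
        assert np.all(phages.s <= 1)

    def test_single_step_stay_fraction_2d(self, rng):
        grid, ix, dist = _walk_setup(40, 40)
        phages = PhagePopulation(2)
        n = 20_000
        phages.add(np.tile([20, 20], (n, 1)))
        random_walk(phages, grid, ix, dist, 1, 0.4712, 0.0, rng)
        stayed = int((phages.pos == [20, 20]).all(axis=1).sum())
        p = stay_probability(1)
        assert abs(stayed - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_mean_squared_displacement_free_walk(self, rng):
        """MSD after n steps matches n * (1 - p_stay) * dl^2."""
        grid, ix, dist = _walk_setup(120, 120)
        phages = PhagePopulation(2)
        P, n = 4000, 100
        start = np.array([60, 60])
        phages.add(np.tile(start, (P, 1)))
        random_walk(phages, grid, ix, dist, n, 0.4712, 0.0, rng)
        disp = phages.pos - start
        disp[:, 0] = (disp[:, 0] + 60) % 120 - 60  # minimal lateral image
        msd = float(np.mean(np.sum(disp.astype(float) ** 2, axis=1))) * 9.0
        expected = n * (1 - stay_probability(1)) * 9.0
        assert msd == pytest.approx(expected, rel=0.05)

    def test_advection_removes_distant_phages(self, rng):
        grid, ix, dist = _walk_setup(10, 10)
        dist[:] = 1e4  # far from any biofilm
        phages = PhagePopulation(2)
        phages.add(np.tile([5, 5], (100, 1)))
        removed = random_walk(phages, grid, ix, dist, 10, 0.4712, 10.0, rng)
        assert removed == 100
        assert len(phages) == 0


class TestInfectionStage:
    def test_stopped_phage_in_susceptible_node_can_infect(self, population, rng,
                                                          small_grid):
        from phagefilm.params import PhageParams

        population.add((3, 3), strain=0)
        phages = PhagePopulation(2)
        phages.add([[3, 3]])
        phages.stopped[:] = True
        phages.s[:] = 955
        counts = infection_stage(
            phages, population, small_grid,
            PhageParams(gamma_per_h=1e9), 0.125, 955, 1.0, rng,
        )
        assert counts["infections"] == 1
        assert population.infected[0]
        assert len(phages) == 0  # consumed

    def test_abortive_contact_removes_both(self, strain_table, rng, small_grid):
        from tests.conftest import make_population
        from phagefilm.params import PhageParams

        pop = make_population(strain_table)
        pop.add((3, 3), strain=strain_table.code("abortive"))
        phages = PhagePopulation(2)
        phages.add([[3, 3]])
        phages.stopped[:] = True
        phages.s[:] = 955
        counts = infection_stage(phages, pop, small_grid,
                                 PhageParams(gamma_per_h=1e9), 0.125, 955, 0.0, rng)
        assert counts["abortive_kills"] == 1
        assert len(pop) == 0 and len(phages) == 0
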