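"""Agent population setup, disease progression, restrictions, production."""

import numpy as np
import pandas as pd
import pytest

from ricehub.abm import (
    DEAD,
    INFECTED_DETECTED,
    INFECTED_UNDETECTED,
    JOB_CIVIL,
    JOB_PRIVATE,
    JOB_RM,
    JOB_STUDENT,
    RECOVERED,
    SUSCEPTIBLE,
    CitySpec,
    EpiParams,
    SimulationConfig,
    accrue_production,
    attempt_infection,
    evaluate_restrictions,
    initialize_world,
    office_time_share,
    progress_health,
    run_simulation,
    schedule_activities,
)
from ricehub.io import PHASE_COVID, PHASE_NORMAL


def one_city_config(**city_kw):
    kw = dict(n_houses=10, humans_per_house=2, n_rmus=1)
    kw.update(city_kw)
    return SimulationConfig(cities=[CitySpec(name="Solo", **kw)])


class TestInitialization:
    def test_population_count_and_all_susceptible(self):
        world = initialize_world(one_city_config(), seed=0)
        assert world.n_humans == 20
        assert (world.status == SUSCEPTIBLE).all()

    def test_no_rm_workers_anywhere_is_an_error(self):
        cfg = one_city_config(job_mix={"student": 1.0})
        with pytest.raises(ValueError, match="RM workers"):
            initialize_world(cfg, seed=0)

    def test_same_seed_gives_identical_world(self):
        w1 = initialize_world(one_city_config(), seed=7)
        w2 = initialize_world(one_city_config(), seed=7)
        assert np.array_equal(w1.job, w2.job)
        assert np.array_equal(w1.house_xy, w2.house_xy)
        assert np.array_equal(w1.job_xy, w2.job_xy, equal_nan=True)

    def test_zero_houses_rejected(self):
        with pytest.raises(ValueError):
            initialize_world(one_city_config(n_houses=0), seed=0)

    def test_rm_workers_have_rmu_assignment(self):
        world = initialize_world(one_city_config(n_houses=50), seed=1)
        rm = world.job == JOB_RM
        assert rm.any()
        assert (world.job_site[rm] >= 0).all()
        assert (world.job_site[~rm] == -1).all()


class TestInfection:
    def _world_with_neighbours(self, n=200, epi=None, config_kw=None):
        cfg = one_city_config(n_houses=n // 2, **(config_kw or {}))
        cfg.contact_rate = 1.0  # every neighbour is a contact each tick
        world = initialize_world(cfg, seed=3)
        world.phase = PHASE_COVID
        # one infectious agent in every house: everyone has a neighbour
        in_house = pd.Series(range(world.n_humans)).groupby(world.house).first()
        world.status[in_house.to_numpy()] = INFECTED_UNDETECTED
        world.recovery_time[world.status == INFECTED_UNDETECTED] = 10
        schedule_activities(world, block="home")
        return world

    def test_zero_infection_rate_never_infects(self):
        world = self._world_with_neighbours(epi=None)
        epi = EpiParams(infection_rate=0.0)
        before = world.status.copy()
        attempt_infection(world, epi, n_ticks=100)
        assert np.array_equal(world.status, before)

    def test_no_infected_neighbour_means_no_change(self):
        cfg = one_city_config(n_houses=50)
        world = initialize_world(cfg, seed=3)
        world.phase = PHASE_COVID
        schedule_activities(world, block="home")
        attempt_infection(world, EpiParams(), n_ticks=24)
        assert (world.status == SUSCEPTIBLE).all()

    def test_normal_phase_is_a_no_op(self):
        world = self._world_with_neighbours()
        world.phase = PHASE_NORMAL
        before = world.status.copy()
        attempt_infection(world, EpiParams(), n_ticks=24)
        assert np.array_equal(world.status, before)

    def test_certain_contact_infects_and_detects_at_the_configured_ratio(self):
        world = self._world_with_neighbours(n=20000)
        epi = EpiParams(infection_rate=1.0, detected_ratio=0.51)
        attempt_infection(world, epi, n_ticks=50)
        detected = (world.status == INFECTED_DETECTED).sum()
        undetected_new = (
            (world.status == INFECTED_UNDETECTED).sum() - world.n_humans // 2
        )
        total_new = detected + undetected_new
        assert total_new > 5000
        frac = detected / total_new
        sd = np.sqrt(0.51 * 0.49 / total_new)
        assert abs(frac - 0.51) < 3 * sd

    def test_new_infections_draw_recovery_time_in_bounds(self):
        world = self._world_with_neighbours(n=2000)
        epi = EpiParams(infection_rate=1.0, recovery_min_days=14, recovery_max_days=42)
        attempt_infection(world, epi, n_ticks=50)
        infected = (world.status == INFECTED_UNDETECTED) | (world.status == INFECTED_DETECTED)
        times = world.recovery_time[infected]
        assert times.min() >= 1 and times.max() <= 42


class TestProgression:
    def _infected_world(self, n_infected, recovery_time=1):
        cfg = one_city_config(n_houses=(n_infected + 1) // 2)
        world = initialize_world(cfg, seed=5)
        world.phase = PHASE_COVID
        world.status[:n_infected] = INFECTED_UNDETECTED
        world.recovery_time[:n_infected] = recovery_time
        return world

    def test_death_fraction_matches_ifr_binomially(self):
        n = 20000
        world = self._infected_world(n)
        epi = EpiParams(ifr=0.0188, resusceptible_prob=0.0, detection_mode="onset_only")
        progress_health(world, epi)
        dead = (world.status == DEAD).sum()
        sd = np.sqrt(0.0188 * (1 - 0.0188) / n)
        assert abs(dead / n - 0.0188) < 3 * sd

    def test_zero_ifr_and_zero_resusceptibility_recovers_everyone(self):
        world = self._infected_world(500, recovery_time=3)
        epi = EpiParams(ifr=0.0, resusceptible_prob=0.0, detection_mode="onset_only")
        for _ in range(3):
            progress_health(world, epi)
        assert (world.status[:500] == RECOVERED).all()
        assert world.cum_deaths.sum() == 0
        assert world.cum_recoveries.sum() == 500

    def test_full_resusceptibility_returns_everyone_to_susceptible(self):
        world = self._infected_world(300)
        epi = EpiParams(ifr=0.0, resusceptible_prob=1.0)
        progress_health(world, epi)
        assert (world.status[:300] == SUSCEPTIBLE).all()
        assert world.cum_recoveries.sum() == 300  # still counted as recoveries

    def test_daily_hazard_detects_at_the_configured_rate(self):
        n = 20000
        world = self._infected_world(n, recovery_time=10)
        epi = EpiParams(detected_ratio=0.51, detection_mode="daily_hazard")
        progress_health(world, epi)
        frac = (world.status == INFECTED_DETECTED).sum() / n
        sd = np.sqrt(0.51 * 0.49 / n)
        assert abs(frac - 0.51) < 3 * sd

    def test_dead_agents_never_change_state(self):
        world = self._infected_world(10)
        world.status[:10] = DEAD
        before = world.status.copy()
        for _ in range(5):
            progress_health(world, EpiParams())
        assert np.array_equal(world.status, before)


class TestRestrictions:
    def _two_city_world(self):
        cfg = SimulationConfig(
            cities=[CitySpec(name="A", n_houses=20), CitySpec(name="B", n_houses=20)]
        )
        world = initialize_world(cfg, seed=2)
        world.phase = PHASE_COVID
        return world

    def test_higher_death_rate_city_is_restricted(self):
        world = self._two_city_world()
        pop = world.population
        world.cum_deaths = np.array([int(0.1 * pop[0]), int(0.3 * pop[1])])
        world.cum_recoveries = np.zeros(2, dtype=int)
        flags = evaluate_restrictions(world)
        assert list(flags) == [False, True]

    def test_identical_cities_are_never_restricted(self):
        world = self._two_city_world()
        flags = evaluate_restrictions(world)
        assert not flags.any()  # strict inequalities against the mean

    def test_city_with_above_average_active_cases_is_restricted(self):
        world = self._two_city_world()
        in_b = np.flatnonzero(world.city == 1)[:10]
        world.status[in_b] = INFECTED_UNDETECTED
        flags = evaluate_restrictions(world)
        assert list(flags) == [False, True]

    def test_below_average_recovery_rate_triggers_restriction(self):
        world = self._two_city_world()
        world.cum_recoveries = np.array([0, 20])
        flags = evaluate_restrictions(world)
        assert list(flags) == [True, False]


class TestSchedulingAndProduction:
    def test_office_time_shares(self):
        assert office_time_share(JOB_PRIVATE, restricted=True) == 0.25
        assert office_time_share(JOB_CIVIL, restricted=True) == 0.25
        assert office_time_share(JOB_STUDENT, restricted=True) == 0.0
        assert office_time_share(JOB_RM, restricted=True) == 1.0
        assert office_time_share(JOB_PRIVATE, restricted=False) == 1.0

    def test_restricted_office_attendance_is_about_a_quarter(self):
        cfg = one_city_config(n_houses=2000)
        world = initialize_world(cfg, seed=9)
        world.phase = PHASE_COVID
        world.restricted[:] = True
        office = np.isin(world.job, (JOB_CIVIL, JOB_PRIVATE))
        n = int(office.sum())
        attended = np.zeros(world.n_humans)
        schedule_activities(world, block="work")
        at_job = np.isclose(world.current_xy, world.job_xy).all(axis=1)
        frac = at_job[office].mean()
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_restricted_students_stay_home(self):
        world = initialize_world(one_city_config(n_houses=200), seed=9)
        world.phase = PHASE_COVID
        world.restricted[:] = True
        schedule_activities(world, block="work")
        students = world.job == JOB_STUDENT
        home = world.house_xy[world.house]
        assert np.allclose(world.current_xy[students], home[students])

    def test_quarantined_rm_worker_stays_home_all_blocks(self):
        world = initialize_world(one_city_config(n_houses=100), seed=4)
        world.phase = PHASE_COVID
        rm = np.flatnonzero(world.job == JOB_RM)[0]
        world.status[rm] = INFECTED_DETECTED
        home = world.house_xy[world.house[rm]]
        for block in ("home", "work"):
            schedule_activities(world, block=block)
            assert np.allclose(world.current_xy[rm], home)

    def test_production_counts_staffed_workers_only(self):
        world = initialize_world(one_city_config(n_houses=100), seed=4)
        rm = np.flatnonzero(world.job == JOB_RM)
        assert len(rm) >= 10
        world.status[rm[:2]] = INFECTED_DETECTED  # quarantined
        tons = accrue_production(world, rate_per_worker=1.0)
        assert tons.sum() == pytest.approx(len(rm) - 2)

    def test_undetected_infected_workers_still_produce(self):
        world = initialize_world(one_city_config(n_houses=100), seed=4)
        rm = np.flatnonzero(world.job == JOB_RM)
        world.status[rm] = INFECTED_UNDETECTED
        tons = accrue_production(world, rate_per_worker=1.0)
        assert tons.sum() == pytest.approx(len(rm))

    def test_all_workers_quarantined_produce_nothing(self):
        world = initialize_world(one_city_config(n_houses=100), seed=4)
        rm = world.job == JOB_RM
        world.status[rm] = INFECTED_DETECTED
        tons = accrue_production(world, rate_per_worker=1.0)
        assert tons.sum() == 0.0

    def test_negative_rate_rejected(self):
        world = initialize_world(one_city_config(), seed=0)
        with pytest.raises(ValueError):
            accrue_production(world, rate_per_worker=-1.0)

    def test_production_monotone_in_quarantined_workers(self):
        world = initialize_world(one_city_config(n_houses=100), seed=4)
        rm = np.flatnonzero(world.job == JOB_RM)
        previous = np.inf
        for n_quarantined in range(len(rm) + 1):
            world.status[:] = SUSCEPTIBLE
            world.status[rm[:n_quarantined]] = INFECTED_DETECTED
            tons = float(accrue_production(world, 1.0).sum())
            assert tons <= previous
            previous = tons


class TestRunSimulation:
    def test_population_conserved_every_day(self, tiny_config):
        res = run_simulation(tiny_config, n_repetitions=1, seed=6)
        epi = res.epidemic[res.epidemic.phase == PHASE_COVID]
        # susceptible is implicit; check dead+recovered tallies are monotone
        for _, grp in epi.groupby("city"):
            assert grp["deaths"].is_monotonic_increasing
            assert grp["recoveries"].is_monotonic_increasing

    def test_zero_infection_rate_equalizes_phases_exactly(self, tiny_config):
        tiny_config.epi = EpiParams(infection_rate=0.0)
        tiny_config.initial_infections_per_city = 0
        res = run_simulation(tiny_config, n_repetitions=1, seed=8)
        means = res.production.groupby("phase")["production_tons"].mean()
        assert means[PHASE_COVID] == means[PHASE_NORMAL]

    def test_same_seed_bitwise_identical_output(self, tiny_config):
        r1 = run_simulation(tiny_config, n_repetitions=2, seed=11)
        r2 = run_simulation(tiny_config, n_repetitions=2, seed=11)
        pd.testing.assert_frame_equal(r1.production, r2.production)
        pd.testing.assert_frame_equal(r1.epidemic, r2.epidemic)

    def test_production_nonnegative_and_complete(self, tiny_config):
        res = run_simulation(tiny_config, n_repetitions=2, seed=12)
        prod = res.production
        assert (prod["production_tons"] >= 0).all()
        days = tiny_config.n_normal_days + tiny_config.n_covid_days
        assert len(prod) == 2 * 2 * days  # reps x cities x days

    def test_conservation_against_world_invariant(self, tiny_config):
        """Direct per-tick invariant: compartment counts sum to population."""
        world = initialize_world(tiny_config, seed=13)
        world.phase = PHASE_COVID
        world.status[:10] = INFECTED_UNDETECTED
        world.recovery_time[:10] = 5
        epi = tiny_config.epi
        pop0 = world.population.copy()
        for day in range(30):
            schedule_activities(world, block="work")
            attempt_infection(world, epi, n_ticks=8)
            progress_health(world, epi)
            counts = world.status_counts()
            total = sum(counts.values())
            assert np.array_equal(total, pop0)
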