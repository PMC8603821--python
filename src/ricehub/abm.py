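"""Agent-based SIRD epidemic and rice-production simulator.

A spatial population of human agents lives in houses, works at rice milling
units (RMUs), offices or schools, and spreads an infection by proximity.
Health states follow susceptible -> infected (detected/undetected) ->
recovered or dead, with detected cases quarantined and recovered agents
possibly returning to the susceptible pool.  RMU workers are the essential
workforce: each staffed, non-quarantined worker produces a fixed tonnage of
rice per day, so quarantine directly depresses the daily production series.

A run covers one normal year (no disease) followed by one pandemic year.
During the pandemic, city-level travel restrictions trigger whenever a
city's death rate, recovery rate or active-case count is worse than the
cross-city average; restrictions send students home and cut office
attendance of civil servants and private employees to 25% of work time,
while RMU workers keep commuting.

Time is discretised into 24 one-hour ticks per day, grouped into a home
block and a work block of ticks with static agent positions; the infection
step aggregates the per-tick per-contact Bernoulli trials of a block into a
single escape probability (1 - contact_rate * IR)^(neighbours x ticks),
which is exact and keeps 100-repetition experiments fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import EPI_COLUMNS, PHASE_COVID, PHASE_NORMAL, PROD_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "EpiParams",
    "CitySpec",
    "SimulationConfig",
    "World",
    "SimulationResult",
    "initialize_world",
    "attempt_infection",
    "progress_health",
    "evaluate_restrictions",
    "schedule_activities",
    "accrue_production",
    "office_time_share",
    "run_simulation",
    "default_config",
]

# job codes
JOBS = ("rm_worker", "civil_servant", "private_employee", "student", "freelancer")
JOB_RM, JOB_CIVIL, JOB_PRIVATE, JOB_STUDENT, JOB_FREELANCER = range(5)

# health status codes
SUSCEPTIBLE, INFECTED_UNDETECTED, INFECTED_DETECTED, RECOVERED, DEAD = range(5)

_CITY_FRAME_OFFSET = 1e4  # shift per-city coordinate frames so cities never mix


@dataclass
class EpiParams:
    """Epidemic input parameters.

    Defaults are the Indonesian estimates used throughout: per-contact
    infection rate 0.337, detected-case ratio 0.51, recovery time uniform
    in 14..42 days, infection fatality rate 0.0188 and recovered-to-
    susceptible probability 0.90.
    """

    infection_rate: float = 0.337
    detected_ratio: float = 0.51
    recovery_min_days: int = 14
    recovery_max_days: int = 42
    ifr: float = 0.0188
    resusceptible_prob: float = 0.90
    quarantine_on_detection: bool = True  # fixed policy: detected => quarantined
    #: "onset_only": detection decided once at infection, so 49% of cases
    #: are never detected and circulate for their full recovery time;
    #: "daily_hazard": undetected agents additionally re-test every day
    #: with the same ratio (detection then nears certainty within days).
    detection_mode: str = "onset_only"

    def __post_init__(self):
        for name in ("infection_rate", "detected_ratio", "ifr", "resusceptible_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0 < self.recovery_min_days <= self.recovery_max_days):
            raise ValueError("need 0 < recovery_min_days <= recovery_max_days")
        if self.detection_mode not in ("onset_only", "daily_hazard"):
            raise ValueError(f"unknown detection_mode {self.detection_mode!r}")


def _default_job_mix() -> dict[str, float]:
    return {
        "rm_worker": 0.10,
        "civil_servant": 0.15,
        "private_employee": 0.30,
        "student": 0.30,
        "freelancer": 0.15,
    }


@dataclass
class CitySpec:
    """Size and layout of one city (an abstract rectangle)."""

    name: str
    n_houses: int = 100
    humans_per_house: int = 3
    n_rmus: int = 2
    n_offices: int = 4
    n_schools: int = 2
    width: float = 10.0
    height: float = 10.0
    job_mix: dict[str, float] = field(default_factory=_default_job_mix)


@dataclass
class SimulationConfig:
    cities: list[CitySpec]
    epi: EpiParams = field(default_factory=EpiParams)
    contact_radius: float = 0.8  # same abstract units as the city rectangle
    #: probability per tick that a given pair within the contact radius has a
    #: transient contact event ("near or passing"); each event transmits with
    #: probability ``epi.infection_rate``
    contact_rate: float = 0.04
    #: sd of each worker's fixed workstation offset around the job site
    workplace_jitter: float = 2.0
    rate_per_worker: float = 1.0  # tons per staffed RMU worker per day
    n_normal_days: int = 365
    n_covid_days: int = 365
    restriction_cadence_days: int = 7
    initial_infections_per_city: int = 5
    work_ticks: int = 8  # work block length; the other 16 ticks are at home
    restricted_office_share: float = 0.25


def default_config(n_cities: int = 5, **kwargs) -> SimulationConfig:
    """A five-city configuration mirroring the West Java case regions."""
    from .fixtures import REGIONS

    names = (REGIONS * ((n_cities // len(REGIONS)) + 1))[:n_cities]
    if n_cities > len(REGIONS):
        names = [f"City {c + 1}" for c in range(n_cities)]
    return SimulationConfig(cities=[CitySpec(name=n) for n in names], **kwargs)


@dataclass
class World:
    """Full simulation state: agent arrays plus per-city tallies.

    Houses and RMUs are static agents (coordinate arrays); humans are the
    dynamic agents, stored as parallel numpy arrays indexed by agent id.
    """

    config: SimulationConfig
    rng: np.random.Generator
    # static agents
    house_xy: np.ndarray  # (n_houses_total, 2)
    house_city: np.ndarray
    rmu_xy: np.ndarray  # (n_rmus_total, 2)
    rmu_city: np.ndarray
    rmu_quantity: np.ndarray  # tons accumulated per RMU, resets daily
    # human agents
    city: np.ndarray  # city index per human
    house: np.ndarray  # house index per human
    job: np.ndarray  # job code per human
    job_xy: np.ndarray  # workplace coordinates (NaN for freelancers)
    job_site: np.ndarray  # RMU index for RM workers, -1 otherwise
    status: np.ndarray  # health status code
    recovery_time: np.ndarray  # remaining infected days
    current_xy: np.ndarray  # position during the current activity block
    # phase / time / tallies
    phase: str = PHASE_NORMAL
    day: int = 0
    restricted: np.ndarray | None = None  # per-city flag
    cum_cases: np.ndarray | None = None
    cum_deaths: np.ndarray | None = None
    cum_recoveries: np.ndarray | None = None
    today_new_detected: np.ndarray | None = None

    @property
    def n_cities(self) -> int:
        return len(self.config.cities)

    @property
    def n_humans(self) -> int:
        return self.city.shape[0]

    @property
    def population(self) -> np.ndarray:
        return np.bincount(self.city, minlength=self.n_cities)

    @property
    def quarantined(self) -> np.ndarray:
        # fixed policy: detected infected agents are exactly the quarantined ones
        return self.status == INFECTED_DETECTED

    def active_cases(self) -> np.ndarray:
        active = (self.status == INFECTED_UNDETECTED) | (self.status == INFECTED_DETECTED)
        return np.bincount(self.city[active], minlength=self.n_cities)

    def status_counts(self) -> dict[str, np.ndarray]:
        out = {}
        for name, code in (
            ("susceptible", SUSCEPTIBLE),
            ("infected_undetected", INFECTED_UNDETECTED),
            ("infected_detected", INFECTED_DETECTED),
            ("recovered", RECOVERED),
            ("dead", DEAD),
        ):
            out[name] = np.bincount(self.city[self.status == code], minlength=self.n_cities)
        return out

    def city_stats(self) -> pd.DataFrame:
        pop = self.population
        return pd.DataFrame(
            {
                "city": [c.name for c in self.config.cities],
                "population": pop,
                "active_cases": self.active_cases(),
                "deaths": self.cum_deaths,
                "recoveries": self.cum_recoveries,
                "cumulative_cases": self.cum_cases,
                "restricted": self.restricted,
            }
        )


def initialize_world(sim_config: SimulationConfig, seed: int | np.random.Generator = 0) -> World:
    """Build the initial population: everyone susceptible and at home.

    Houses, RMUs, offices and schools are placed uniformly at random in each
    city's rectangle; humans are dealt to houses and to jobs according to
    the city's job mix; RM workers are assigned to RMUs round-robin.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cities = sim_config.cities
    if not cities:
        raise ValueError("configuration must contain at least one city")

    house_xy, house_city = [], []
    rmu_xy, rmu_city = [], []
    city_arr, house_arr, job_arr, jobxy, jobsite = [], [], [], [], []

    rmu_base = 0
    any_rm_worker = False
    for ci, spec in enumerate(cities):
        if spec.n_houses <= 0 or spec.humans_per_house <= 0:
            raise ValueError(f"city {spec.name!r} has no inhabitants")
        ox = ci * _CITY_FRAME_OFFSET  # per-city coordinate frame

        def _place(n):
            pts = rng.uniform(0.0, 1.0, (n, 2)) * [spec.width, spec.height]
            pts[:, 0] += ox
            return pts

        h_xy = _place(spec.n_houses)
        r_xy = _place(max(spec.n_rmus, 1))
        o_xy = _place(max(spec.n_offices, 1))
        s_xy = _place(max(spec.n_schools, 1))
        house_xy.append(h_xy)
        house_city.append(np.full(len(h_xy), ci))
        rmu_xy.append(r_xy)
        rmu_city.append(np.full(len(r_xy), ci))

        n_humans = spec.n_houses * spec.humans_per_house
        houses = np.repeat(np.arange(spec.n_houses), spec.humans_per_house)
        mix = np.array([spec.job_mix.get(j, 0.0) for j in JOBS], dtype=float)
        if mix.sum() <= 0:
            raise ValueError(f"city {spec.name!r} has an empty job mix")
        jobs = rng.choice(len(JOBS), size=n_humans, p=mix / mix.sum())
        any_rm_worker |= bool(np.any(jobs == JOB_RM))

        jxy = np.full((n_humans, 2), np.nan)
        jsite = np.full(n_humans, -1, dtype=int)
        jitter = sim_config.workplace_jitter
        for code, sites in ((JOB_RM, r_xy), (JOB_CIVIL, o_xy), (JOB_PRIVATE, o_xy), (JOB_STUDENT, s_xy)):
            idx = np.flatnonzero(jobs == code)
            assign = np.arange(len(idx)) % len(sites)
            # fixed personal workstation scattered around the job site
            jxy[idx] = sites[assign] + rng.normal(0.0, jitter, (len(idx), 2))
            if code == JOB_RM:
                jsite[idx] = rmu_base + assign
        rmu_base += len(r_xy)

        city_arr.append(np.full(n_humans, ci))
        house_arr.append(houses + sum(len(h) for h in house_xy[:-1]))
        job_arr.append(jobs)
        jobxy.append(jxy)
        jobsite.append(jsite)

    if not any_rm_worker:
        raise ValueError("no RM workers anywhere: production is undefined")

    house_xy = np.vstack(house_xy)
    city_v = np.concatenate(city_arr)
    house_v = np.concatenate(house_arr)
    n = len(city_v)
    nc = len(cities)
    world = World(
        config=sim_config,
        rng=rng,
        house_xy=house_xy,
        house_city=np.concatenate(house_city),
        rmu_xy=np.vstack(rmu_xy),
        rmu_city=np.concatenate(rmu_city),
        rmu_quantity=np.zeros(rmu_base),
        city=city_v,
        house=house_v,
        job=np.concatenate(job_arr),
        job_xy=np.vstack(jobxy),
        job_site=np.concatenate(jobsite),
        status=np.full(n, SUSCEPTIBLE, dtype=np.int8),
        recovery_time=np.zeros(n, dtype=int),
        current_xy=house_xy[house_v].copy(),
        restricted=np.zeros(nc, dtype=bool),
        cum_cases=np.zeros(nc, dtype=int),
        cum_deaths=np.zeros(nc, dtype=int),
        cum_recoveries=np.zeros(nc, dtype=int),
        today_new_detected=np.zeros(nc, dtype=int),
    )
    return world


def office_time_share(job: int, restricted: bool) -> float:
    """Expected share of work time spent at the workplace.

    Under restriction, students study from home (share 0) and office workers
    attend 25% of work time; RM workers are essential and always attend.
    """
    if job == JOB_RM:
        return 1.0
    if not restricted:
        return 1.0 if job in (JOB_CIVIL, JOB_PRIVATE, JOB_STUDENT) else 0.0
    if job in (JOB_CIVIL, JOB_PRIVATE):
        return 0.25
    return 0.0


def schedule_activities(world: World, block: str = "work", weekend: bool = False) -> World:
    """Place every agent for the coming activity block.

    Home block: everyone at their house.  Work block: RM workers commute
    every day (essential sector); other workers and students commute on
    weekdays, subject to their city's restriction rules; freelancers roam to
    a random location in their city; quarantined and dead agents never move.
    """
    xy = world.house_xy[world.house].copy()
    if block == "work":
        movable = ~world.quarantined & (world.status != DEAD)
        share = world.config.restricted_office_share
        rest = world.restricted[world.city]

        go_rm = movable & (world.job == JOB_RM)
        xy[go_rm] = world.job_xy[go_rm]
        if not weekend:
            office = movable & np.isin(world.job, (JOB_CIVIL, JOB_PRIVATE))
            attend = np.where(rest, world.rng.random(world.n_humans) < share, True)
            go_office = office & attend
            xy[go_office] = world.job_xy[go_office]
            go_school = movable & (world.job == JOB_STUDENT) & ~rest
            xy[go_school] = world.job_xy[go_school]
            roam = movable & (world.job == JOB_FREELANCER)
            if np.any(roam):
                widths = np.array([c.width for c in world.config.cities])
                heights = np.array([c.height for c in world.config.cities])
                ci = world.city[roam]
                pts = world.rng.uniform(0.0, 1.0, (int(roam.sum()), 2))
                pts[:, 0] = pts[:, 0] * widths[ci] + ci * _CITY_FRAME_OFFSET
                pts[:, 1] *= heights[ci]
                xy[roam] = pts
    world.current_xy = xy
    return world


def attempt_infection(world: World, epi: EpiParams, n_ticks: int = 1) -> World:
    """Contact-driven infection over one activity block of ``n_ticks`` ticks.

    Each tick, a susceptible agent has a transient contact event with each
    of its g circulating (non-quarantined, alive) infected neighbours with
    probability ``contact_rate``; each event transmits with probability
    ``infection_rate``, so the block-level escape probability is
    (1 - contact_rate * infection_rate)^(g * n_ticks).  New cases are
    detected with probability ``detected_ratio`` (detected => quarantined)
    and draw a uniform recovery time.  No-op outside the pandemic phase.
    """
    if world.phase != PHASE_COVID or epi.infection_rate <= 0.0:
        return world
    infectious = world.status == INFECTED_UNDETECTED
    if not np.any(infectious):
        return world
    susceptible = world.status == SUSCEPTIBLE
    if not np.any(susceptible):
        return world

    tree = cKDTree(world.current_xy[infectious])
    sus_idx = np.flatnonzero(susceptible)
    counts = tree.query_ball_point(
        world.current_xy[sus_idx], world.config.contact_radius, return_length=True
    )
    exposed = counts > 0
    if not np.any(exposed):
        return world
    p_tick = world.config.contact_rate * epi.infection_rate
    p_inf = 1.0 - (1.0 - p_tick) ** (counts[exposed] * n_ticks)
    hit = world.rng.random(p_inf.shape) < p_inf
    new = sus_idx[exposed][hit]
    if new.size == 0:
        return world

    detected = world.rng.random(new.size) < epi.detected_ratio
    world.status[new] = np.where(detected, INFECTED_DETECTED, INFECTED_UNDETECTED)
    world.recovery_time[new] = world.rng.integers(
        epi.recovery_min_days, epi.recovery_max_days + 1, size=new.size
    )
    np.add.at(world.cum_cases, world.city[new], 1)
    np.add.at(world.today_new_detected, world.city[new[detected]], 1)
    return world


def progress_health(world: World, epi: EpiParams) -> World:
    """Daily health-state update.

    Infected agents count down their recovery time; at zero they die with
    probability ``ifr``, otherwise they recover and leave quarantine, and
    each fresh recoveree immediately returns to the susceptible pool with
    probability ``resusceptible_prob`` (else permanent immunity).  In
    daily-hazard mode, undetected cases are additionally detected (and
    quarantined) with probability ``detected_ratio`` per day.
    """
    infected = (world.status == INFECTED_UNDETECTED) | (world.status == INFECTED_DETECTED)
    if not np.any(infected):
        return world
    world.recovery_time[infected] -= 1
    finishing = infected & (world.recovery_time <= 0)

    fin_idx = np.flatnonzero(finishing)
    if fin_idx.size:
        dies = world.rng.random(fin_idx.size) < epi.ifr
        dead_idx = fin_idx[dies]
        world.status[dead_idx] = DEAD
        np.add.at(world.cum_deaths, world.city[dead_idx], 1)
        rec_idx = fin_idx[~dies]
        np.add.at(world.cum_recoveries, world.city[rec_idx], 1)
        resus = world.rng.random(rec_idx.size) < epi.resusceptible_prob
        world.status[rec_idx] = np.where(resus, SUSCEPTIBLE, RECOVERED)
        world.recovery_time[fin_idx] = 0

    if epi.detection_mode == "daily_hazard":
        undet = np.flatnonzero((world.status == INFECTED_UNDETECTED))
        if undet.size:
            caught = undet[world.rng.random(undet.size) < epi.detected_ratio]
            world.status[caught] = INFECTED_DETECTED
            np.add.at(world.today_new_detected, world.city[caught], 1)
    return world


def evaluate_restrictions(world: World) -> np.ndarray:
    """Per-city travel-restriction flags.

    A city is restricted iff its per-capita death rate exceeds the cross-
    city mean, its per-capita recovery rate is below the mean, or its
    active-case count exceeds the mean (all strict comparisons).  Cities
    with zero population are excluded from the averages and never
    restricted.
    """
    pop = world.population
    valid = pop > 0
    if not np.any(valid):
        return np.zeros(world.n_cities, dtype=bool)
    death_rate = np.where(valid, world.cum_deaths / np.maximum(pop, 1), 0.0)
    recov_rate = np.where(valid, world.cum_recoveries / np.maximum(pop, 1), 0.0)
    active = world.active_cases().astype(float)

    flags = np.zeros(world.n_cities, dtype=bool)
    flags[valid] = (
        (death_rate[valid] > death_rate[valid].mean())
        | (recov_rate[valid] < recov_rate[valid].mean())
        | (active[valid] > active[valid].mean())
    )
    newly = flags & ~world.restricted
    if np.any(newly):
        names = [world.config.cities[c].name for c in np.flatnonzero(newly)]
        logger.info("day %d: travel restriction imposed in %s", world.day, names)
    world.restricted = flags
    return flags


def accrue_production(world: World, rate_per_worker: float) -> np.ndarray:
    """Add one day of production to every RMU; returns per-city tons.

    Output is rate x (workers neither quarantined nor dead); undetected
    infected workers still work and produce.
    """
    if rate_per_worker < 0:
        raise ValueError("rate_per_worker must be nonnegative")
    working = (
        (world.job == JOB_RM)
        & ~world.quarantined
        & (world.status != DEAD)
    )
    per_rmu = np.bincount(
        world.job_site[working], minlength=len(world.rmu_quantity)
    ) * rate_per_worker
    world.rmu_quantity += per_rmu
    return np.bincount(world.rmu_city, weights=per_rmu, minlength=world.n_cities)


@dataclass
class SimulationResult:
    production: pd.DataFrame  # PROD_COLUMNS layout
    epidemic: pd.DataFrame  # EPI_COLUMNS layout


def _seed_initial_infections(world: World, epi: EpiParams) -> None:
    k = world.config.initial_infections_per_city
    for ci in range(world.n_cities):
        pool = np.flatnonzero((world.city == ci) & (world.status == SUSCEPTIBLE))
        if pool.size == 0 or k == 0:
            continue
        chosen = world.rng.choice(pool, size=min(k, pool.size), replace=False)
        world.status[chosen] = INFECTED_UNDETECTED
        world.recovery_time[chosen] = world.rng.integers(
            epi.recovery_min_days, epi.recovery_max_days + 1, size=chosen.size
        )
        np.add.at(world.cum_cases, world.city[chosen], 1)


def _run_single(config: SimulationConfig, rng: np.random.Generator, rep: int):
    epi = config.epi
    world = initialize_world(config, rng)
    names = [c.name for c in config.cities]
    nc = world.n_cities
    prod_rows, epi_rows = [], []

    # normal year: no disease, production at full staffing
    world.phase = PHASE_NORMAL
    full = np.bincount(
        world.rmu_city,
        weights=np.bincount(world.job_site[world.job == JOB_RM], minlength=len(world.rmu_quantity)),
        minlength=nc,
    ) * config.rate_per_worker
    for day in range(1, config.n_normal_days + 1):
        for ci in range(nc):
            prod_rows.append((rep, names[ci], PHASE_NORMAL, day, full[ci]))
            epi_rows.append((rep, names[ci], PHASE_NORMAL, day, 0, 0, 0, 0))

    # pandemic year
    world.phase = PHASE_COVID
    world.day = 0
    logger.info("repetition %d: pandemic phase begins", rep)
    _seed_initial_infections(world, epi)
    for day in range(1, config.n_covid_days + 1):
        world.day = day
        weekend = (day - 1) % 7 >= 5
        if (day - 1) % config.restriction_cadence_days == 0:
            evaluate_restrictions(world)
        world.today_new_detected[:] = 0
        world.rmu_quantity[:] = 0.0

        schedule_activities(world, block="home", weekend=weekend)
        attempt_infection(world, epi, n_ticks=24 - config.work_ticks)
        schedule_activities(world, block="work", weekend=weekend)
        attempt_infection(world, epi, n_ticks=config.work_ticks)
        progress_health(world, epi)
        tons = accrue_production(world, config.rate_per_worker)

        active = world.active_cases()
        for ci in range(nc):
            prod_rows.append((rep, names[ci], PHASE_COVID, day, tons[ci]))
            epi_rows.append(
                (
                    rep,
                    names[ci],
                    PHASE_COVID,
                    day,
                    int(world.today_new_detected[ci]),
                    int(active[ci]),
                    int(world.cum_deaths[ci]),
                    int(world.cum_recoveries[ci]),
                )
            )
    return prod_rows, epi_rows


def run_simulation(
    sim_config: SimulationConfig, n_repetitions: int = 1, seed: int = 0
) -> SimulationResult:
    """Run ``n_repetitions`` independent two-year simulations.

    Each repetition draws its own generator from the master seed, so runs
    are reproducible and independent of the repetition count ordering.
    """
    ss = np.random.SeedSequence(seed)
    prod_rows, epi_rows = [], []
    for rep, child in enumerate(ss.spawn(n_repetitions)):
        p, e = _run_single(sim_config, np.random.default_rng(child), rep)
        prod_rows.extend(p)
        epi_rows.extend(e)
    production = pd.DataFrame(prod_rows, columns=PROD_COLUMNS)
    epidemic = pd.DataFrame(epi_rows, columns=EPI_COLUMNS)
    return SimulationResult(production=production, epidemic=epidemic)
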