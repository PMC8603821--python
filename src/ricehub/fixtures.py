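"""Built-in West Java case study and synthetic data generators.

The case study covers the five West Java regions with the most COVID-19
cases: Depok City, Bogor City, Bogor Regency, Bekasi City and Bekasi
Regency.  The published case reports only worst-case production capacities,
three demands and qualitative orderings (Depok City has the highest selling
price; the two Bekasi regions share the second-highest; Bekasi City is
closer to Depok City than Bekasi Regency is).  All remaining magnitudes
(exact prices in Rp, the distance matrix, handling and hub development
costs, nominal capacities and the synthetic deviation clouds behind the
uncertainty sets) are constructed here to respect those orderings; they are
fixture choices, not published data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PHASE_COVID, PHASE_NORMAL, PROD_COLUMNS
from .romodel import (
    InstanceData,
    UncertainInstance,
    UncertaintyAttachment,
    attach_capacity_sets,
    interval_set,
)
from .uncertainty import PolyhedralSet, build_polyhedron

__all__ = [
    "REGIONS",
    "SCENARIO1_CAPACITY",
    "SCENARIO2_CAPACITY",
    "DEMAND",
    "load_paper_fixture",
    "fixture_region_sets",
    "SyntheticSpec",
    "generate_synthetic_series",
    "random_instance",
]

REGIONS = ["Depok City", "Bogor City", "Bogor Regency", "Bekasi City", "Bekasi Regency"]

#: worst-case production capacity (ton) per scenario; scenario 1 is built
#: from all simulated production points, scenario 2 from the top 15% only
#: (less conservative, hence higher worst case).
SCENARIO1_CAPACITY = {
    "Depok City": 0.0,
    "Bogor City": 2.734,
    "Bogor Regency": 655.773,
    "Bekasi City": 0.911,
    "Bekasi Regency": 166.905,
}
SCENARIO2_CAPACITY = {
    "Depok City": 64.705,
    "Bogor City": 80.719,
    "Bogor Regency": 1133.704,
    "Bekasi City": 75.250,
    "Bekasi Regency": 307.642,
}

#: daily rice demand (ton); the two Bogor regions never appear as service
#: areas in the case study and are treated as non-demand areas.
DEMAND = {"Depok City": 628.294, "Bekasi City": 790.486, "Bekasi Regency": 978.951}

#: selling price (Rp/ton): Depok City highest, the two Bekasi regions tied
#: second -- the orderings the case study states.
PRICE = {"Depok City": 11.0e6, "Bekasi City": 10.5e6, "Bekasi Regency": 10.5e6}

#: abstract planar coordinates (km); chosen so Bogor Regency's production
#: naturally flows to Depok and Bekasi City is closer to Depok than Bekasi
#: Regency is, mirroring the real relative geography.
COORDS = {
    "Depok City": (0.0, 0.0),
    "Bogor City": (0.0, 22.0),
    "Bogor Regency": (5.0, 28.0),
    "Bekasi City": (22.0, 2.0),
    "Bekasi Regency": (55.0, 15.0),
}

TRANSPORT_RATE = 3000.0  # Rp per ton per km
HANDLING_COST = 150_000.0  # Rp per ton
HUB_COST = 6.0e7  # Rp per hub

#: the nominal capacity is each scenario dataset's daily mean, which sits a
#: little above that scenario's worst case; the margin and upside are
#: synthetic stand-ins for the unpublished simulation data.
NOMINAL_MARGIN = 1.10  # nominal = margin * worst-case capacity

PLANNING_DAY = 180  # covid-phase day the per-period optimizer plans for
_CLOUD_T = (150.0, 210.0)  # day extent of the synthetic deviation clouds
UPSIDE = 0.02  # relative upside deviation of the clouds


def _distance(a: str, b: str) -> float:
    (xa, ya), (xb, yb) = COORDS[a], COORDS[b]
    return math.hypot(xa - xb, ya - yb)


def _nominal_capacity(scenario: int) -> dict[str, float]:
    worst = SCENARIO1_CAPACITY if scenario == 1 else SCENARIO2_CAPACITY
    return {region: NOMINAL_MARGIN * worst[region] for region in REGIONS}


def _base_instance(scenario: int) -> InstanceData:
    # hubs are consolidation points in the consuming regions; the two Bogor
    # regions are producers only (they never appear as hubs or service areas
    # in the case study)
    demand_areas = ["Depok City", "Bekasi City", "Bekasi Regency"]
    hub_sites = list(demand_areas)
    nominal = _nominal_capacity(scenario)
    b_ji = np.array([[TRANSPORT_RATE * _distance(j, i) for i in demand_areas] for j in hub_sites])
    b_kj = np.array([[TRANSPORT_RATE * _distance(k, j) for j in hub_sites] for k in REGIONS])
    return InstanceData(
        commodities=["rice"],
        demand_areas=demand_areas,
        hub_sites=hub_sites,
        producer_areas=list(REGIONS),
        demand=np.array([[DEMAND[i] for i in demand_areas]]),
        price=np.array([[PRICE[i] for i in demand_areas]]),
        capacity=np.array([[nominal[k] for k in REGIONS]]),
        cost_hub_to_demand=b_ji,
        cost_producer_to_hub=b_kj,
        handling_cost=np.array([HANDLING_COST]),
        hub_cost=HUB_COST,
    )


def fixture_region_sets(scenario: int) -> dict[str, PolyhedralSet]:
    """Per-region 2-D (t, u) polyhedral sets for the chosen scenario.

    Each set is the hull of a synthetic rectangular deviation cloud whose
    slice at the planning day spans [worst-case - nominal, +upside].
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    worst = SCENARIO1_CAPACITY if scenario == 1 else SCENARIO2_CAPACITY
    nominal = _nominal_capacity(scenario)
    t0, t1 = _CLOUD_T
    sets = {}
    for region in REGIONS:
        lo = worst[region] - nominal[region]
        hi = UPSIDE * nominal[region]
        cloud = np.array([[t0, lo], [t1, lo], [t1, hi], [t0, hi]])
        sets[region] = build_polyhedron(cloud)
    return sets


def load_paper_fixture(scenario: int) -> UncertainInstance:
    """The West Java case instance with scenario-specific capacity uncertainty."""
    inst = _base_instance(scenario)
    return attach_capacity_sets(inst, fixture_region_sets(scenario), PLANNING_DAY)


# ---------------------------------------------------------------------------
# synthetic production series


@dataclass
class SyntheticSpec:
    """Synthetic per-region daily production series: i.i.d. noise around a
    baseline in the normal year, baseline scaled down by ``dip`` over a
    window of the pandemic year (truncated at zero tons)."""

    n_regions: int = 5
    n_days: int = 365
    n_reps: int = 20
    baseline_mean: float = 1000.0
    baseline_sd: float = 50.0
    dip: float = 0.0328
    dip_start: int = 0
    dip_length: int | None = None  # None = rest of the pandemic year
    region_names: list[str] | None = None
    seed: int = 0


def generate_synthetic_series(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a production series in the standard delimited layout."""
    rng = np.random.default_rng(spec.seed)
    regions = spec.region_names or [f"Region {r + 1}" for r in range(spec.n_regions)]
    if len(regions) != spec.n_regions:
        raise ValueError("region_names length must equal n_regions")
    dip_len = spec.dip_length if spec.dip_length is not None else spec.n_days - spec.dip_start
    scale = np.ones(spec.n_days)
    scale[spec.dip_start : spec.dip_start + dip_len] = 1.0 - spec.dip

    frames = []
    days = np.arange(1, spec.n_days + 1)
    for rep in range(spec.n_reps):
        for region in regions:
            normal = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_days)
            covid = rng.normal(spec.baseline_mean * scale, spec.baseline_sd)
            for phase, values in ((PHASE_NORMAL, normal), (PHASE_COVID, covid)):
                frames.append(
                    pd.DataFrame(
                        {
                            "repetition": rep,
                            "region": region,
                            "phase": phase,
                            "day": days,
                            "production_tons": np.maximum(values, 0.0),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)[PROD_COLUMNS]


# ---------------------------------------------------------------------------
# random optimizer instances (small, for cross-checks)


def random_instance(
    rng: np.random.Generator,
    n_c: int = 1,
    n_i: int = 3,
    n_j: int = 3,
    n_k: int = 3,
    uncertain_frac: float = 0.5,
) -> UncertainInstance:
    """Random small instance with interval capacity uncertainty."""
    inst = InstanceData(
        commodities=[f"c{t}" for t in range(n_c)],
        demand_areas=[f"i{t}" for t in range(n_i)],
        hub_sites=[f"j{t}" for t in range(n_j)],
        producer_areas=[f"k{t}" for t in range(n_k)],
        demand=rng.uniform(50, 200, (n_c, n_i)),
        price=rng.uniform(1e4, 1e5, (n_c, n_i)),
        capacity=rng.uniform(20, 150, (n_c, n_k)),
        cost_hub_to_demand=rng.uniform(100, 2000, (n_j, n_i)),
        cost_producer_to_hub=rng.uniform(100, 2000, (n_k, n_j)),
        handling_cost=rng.uniform(10, 100, n_c),
        hub_cost=float(rng.uniform(1e4, 1e6)),
    )
    atts = []
    for c in range(n_c):
        for k in range(n_k):
            if rng.random() < uncertain_frac:
                span = rng.uniform(0.05, 0.4) * inst.capacity[c, k]
                atts.append(
                    UncertaintyAttachment(
                        "capacity", interval_set(-span, float(rng.uniform(0, span))), [(c, k)]
                    )
                )
    return UncertainInstance(base=inst, attachments=atts)
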