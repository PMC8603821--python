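"""Delimited-text I/O conventions shared across the package.

Production and epidemic series travel as plain pandas DataFrames with fixed
column names so every stage (simulator, validator, uncertainty builder,
optimizer) can read the other stages' CSV output.
"""

from __future__ import annotations

import pandas as pd

#: one row per (repetition, region, phase, day)
PROD_COLUMNS = ["repetition", "region", "phase", "day", "production_tons"]

#: one row per (repetition, city, phase, day)
EPI_COLUMNS = [
    "repetition",
    "city",
    "phase",
    "day",
    "new_cases",
    "active_cases",
    "deaths",
    "recoveries",
]

PHASE_NORMAL = "normal"
PHASE_COVID = "covid"


def read_production_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PROD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"production series file missing columns: {missing}")
    return df[PROD_COLUMNS]


def write_production_series(df: pd.DataFrame, path) -> None:
    df[PROD_COLUMNS].to_csv(path, index=False)


def read_epidemic_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EPI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epidemic series file missing columns: {missing}")
    return df[EPI_COLUMNS]


def write_epidemic_series(df: pd.DataFrame, path) -> None:
    df[EPI_COLUMNS].to_csv(path, index=False)


def read_instance_yaml(path):
    """Read a location-routing instance from a structured-config file."""
    import numpy as np
    import yaml

    from .romodel import InstanceData

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return InstanceData(
        commodities=list(raw["commodities"]),
        demand_areas=list(raw["demand_areas"]),
        hub_sites=list(raw["hub_sites"]),
        producer_areas=list(raw["producer_areas"]),
        demand=np.asarray(raw["demand"], dtype=float),
        price=np.asarray(raw["price"], dtype=float),
        capacity=np.asarray(raw["capacity"], dtype=float),
        cost_hub_to_demand=np.asarray(raw["cost_hub_to_demand"], dtype=float),
        cost_producer_to_hub=np.asarray(raw["cost_producer_to_hub"], dtype=float),
        handling_cost=np.asarray(raw["handling_cost"], dtype=float),
        hub_cost=float(raw["hub_cost"]),
    )


def write_instance_yaml(instance, path) -> None:
    import yaml

    data = {
        "commodities": instance.commodities,
        "demand_areas": instance.demand_areas,
        "hub_sites": instance.hub_sites,
        "producer_areas": instance.producer_areas,
        "demand": instance.demand.tolist(),
        "price": instance.price.tolist(),
        "capacity": instance.capacity.tolist(),
        "cost_hub_to_demand": instance.cost_hub_to_demand.tolist(),
        "cost_producer_to_hub": instance.cost_producer_to_hub.tolist(),
        "handling_cost": instance.handling_cost.tolist(),
        "hub_cost": instance.hub_cost,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
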