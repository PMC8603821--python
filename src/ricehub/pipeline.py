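"""End-to-end pipeline: simulate -> validate -> uncertainty -> optimize -> report.

The pipeline mirrors the integrated framework: a production series (from
the agent-based simulator, the synthetic generator, or a user-supplied CSV)
is validated against the expected pandemic reduction; if the goodness-of-
fit gate passes (or is overridden), per-region polyhedral uncertainty sets
are built for the chosen scenario, attached to a location-routing instance,
and the robust counterpart is solved.  All intermediate artifacts and a
manifest with seeds and versions are written to the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    PHASE_COVID,
    write_epidemic_series,
    write_instance_yaml,
    write_production_series,
)
from .romodel import (
    InstanceData,
    UncertainInstance,
    build_rc,
    report_tables,
    scalarize,
    solve,
    verify_robustness,
)
from .uncertainty import (
    build_polyhedron,
    deviations,
    nominal_series,
    select_scenario,
    write_set_file,
)
from .validation import EXPECTED_REDUCTION, gof_test, production_change

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationRejected", "run_pipeline", "series_to_uncertain_instance"]


class ValidationRejected(RuntimeError):
    """The goodness-of-fit gate rejected the simulated series."""


@dataclass
class PipelineConfig:
    source: str = "synthetic"  # "simulate" | "synthetic" | "fixture" | "series"
    out_dir: str | Path = "ricehub_out"
    seed: int = 0
    scenario: str = "all_data"  # "all_data" | "top15"
    n_repetitions: int = 20
    alpha: float = 0.05
    expected_reduction: float = EXPECTED_REDUCTION
    override_validation: bool = False
    method: str = "lexicographic"
    sim_config: object = None  # SimulationConfig for source="simulate"
    synthetic_spec: object = None  # SyntheticSpec for source="synthetic"
    series_path: str | Path | None = None  # for source="series"
    instance: InstanceData | None = None  # optimizer instance (default: case study)
    planning_day: int | None = None  # None = day of minimal nominal total


def _choose_planning_day(nominals: dict[str, pd.Series]) -> int:
    """Covid-phase day with minimal total nominal production (worst day)."""
    total = None
    for nom in nominals.values():
        total = nom if total is None else total.add(nom, fill_value=0.0)
    return int(total.idxmin())


def series_to_uncertain_instance(
    series: pd.DataFrame,
    instance: InstanceData,
    scenario: str = "all_data",
    planning_day: int | None = None,
    commodity: int = 0,
):
    """Build per-region sets from a series and attach them to an instance.

    The instance's nominal capacity for each region becomes the nominal
    production at the planning day (clamped into the region's hull day
    range for the top-15% scenario, whose day coverage is sparse), and the
    capacity uncertainty interval is the polyhedron slice at that day.
    Returns (UncertainInstance, region sets, planning day).
    """
    from .romodel import UncertaintyAttachment, interval_set

    datasets = select_scenario(series, scenario)
    missing = [k for k in instance.producer_areas if k not in datasets]
    if missing:
        raise ValueError(f"series lacks producer regions: {missing}")

    nominals = {r: nominal_series(ds) for r, ds in datasets.items()}
    sets = {
        r: build_polyhedron(deviations(ds, nominals[r])) for r, ds in datasets.items()
    }
    if planning_day is None:
        planning_day = _choose_planning_day(nominals)

    capacity = instance.capacity.copy()
    attachments = []
    for k, region in enumerate(instance.producer_areas):
        nom, pset = nominals[region], sets[region]
        days = nom.index.to_numpy()
        # clamp into the region's own day coverage: the top-15% scenario
        # keeps only the days of its retained points
        t = float(np.clip(planning_day, days.min(), days.max()))
        nearest = int(days[np.argmin(np.abs(days - t))])
        capacity[commodity, k] = nom.loc[nearest]
        lo, hi = pset.slice_u(t)
        lo = max(lo, -capacity[commodity, k])  # production floor at 0 tons
        attachments.append(
            UncertaintyAttachment("capacity", interval_set(lo, hi), [(commodity, k)])
        )

    inst = InstanceData(
        commodities=instance.commodities,
        demand_areas=instance.demand_areas,
        hub_sites=instance.hub_sites,
        producer_areas=instance.producer_areas,
        demand=instance.demand,
        price=instance.price,
        capacity=capacity,
        cost_hub_to_demand=instance.cost_hub_to_demand,
        cost_producer_to_hub=instance.cost_producer_to_hub,
        handling_cost=instance.handling_cost,
        hub_cost=instance.hub_cost,
    )
    uinst = UncertainInstance(base=inst, attachments=attachments)
    return uinst, sets, planning_day


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of artifacts and file paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "source": config.source,
        "scenario": config.scenario,
        "stages": [],
    }
    artifacts: dict = {"manifest": manifest}

    # stage 1: obtain the production series -------------------------------
    series = None
    if config.source == "fixture":
        from .fixtures import load_paper_fixture

        scenario_id = 1 if config.scenario == "all_data" else 2
        uinst = load_paper_fixture(scenario_id)
        manifest["stages"].append("fixture")
    else:
        if config.source == "simulate":
            from .abm import default_config, run_simulation

            sim_config = config.sim_config or default_config()
            result = run_simulation(sim_config, config.n_repetitions, seed=config.seed)
            series, epidemic = result.production, result.epidemic
            write_epidemic_series(epidemic, out / "epidemic.csv")
        elif config.source == "synthetic":
            from .fixtures import REGIONS, SyntheticSpec, generate_synthetic_series

            spec = config.synthetic_spec or SyntheticSpec(
                n_reps=config.n_repetitions, region_names=list(REGIONS), seed=config.seed
            )
            series = generate_synthetic_series(spec)
        elif config.source == "series":
            from .io import read_production_series

            if config.series_path is None:
                raise ValueError("source='series' requires series_path")
            series = read_production_series(config.series_path)
        else:
            raise ValueError(f"unknown source {config.source!r}")
        write_production_series(series, out / "production.csv")
        manifest["stages"].append(f"series:{config.source}")

        # stage 2: validation gate ----------------------------------------
        obs = production_change(series)
        gof = gof_test(obs, config.expected_reduction, config.alpha)
        (out / "validation.json").write_text(
            json.dumps(
                {
                    "chi2": gof.chi2,
                    "k": gof.k,
                    "df": gof.df,
                    "alpha": gof.alpha,
                    "critical_value": gof.critical_value,
                    "reject_h0": bool(gof.reject_h0),
                },
                indent=2,
            )
        )
        artifacts["gof"] = gof
        manifest["stages"].append("validate")
        logger.info("validation: %s", gof)
        if gof.reject_h0 and not config.override_validation:
            raise ValidationRejected(
                f"goodness-of-fit gate rejected the series ({gof}); "
                "pass override_validation=True to proceed anyway"
            )

        # stage 3: uncertainty sets ---------------------------------------
        from .fixtures import load_paper_fixture

        instance = config.instance
        if instance is None:
            scenario_id = 1 if config.scenario == "all_data" else 2
            instance = load_paper_fixture(scenario_id).base
        uinst, sets, planning_day = series_to_uncertain_instance(
            series, instance, config.scenario, config.planning_day
        )
        for region, pset in sets.items():
            safe = region.replace(" ", "_").lower()
            write_set_file(pset, out / f"set_{safe}.csv")
        manifest["stages"].append("uncertainty")
        manifest["planning_day"] = planning_day
        artifacts["sets"] = sets

    # stage 4: robust optimization ----------------------------------------
    write_instance_yaml(uinst.base, out / "instance.yaml")
    model = build_rc(uinst)
    solution = solve(scalarize(model, config.method))
    artifacts["solution"] = solution
    robustness = verify_robustness(solution, uinst, seed=config.seed)
    artifacts["robustness"] = robustness
    manifest["stages"].append("optimize")
    manifest["objective_fulfillment_rp"] = solution.objective_fulfillment
    manifest["objective_cost_rp"] = solution.objective_cost
    manifest["robust_max_violation"] = robustness["max_violation"]

    # stage 5: reports ------------------------------------------------------
    tables = report_tables(solution)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    artifacts["tables"] = tables
    manifest["stages"].append("report")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts
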