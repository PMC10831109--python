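"""End-to-end pipeline: tables -> scenarios -> adequacy/impact/cost ->
uncertainty exports, with a reproducibility manifest.

Two runs with the same configuration (seed included) produce bit-identical
output files; the manifest lists every output with a SHA-256 checksum and a
configuration hash that excludes output paths, so a run relocated to a
different directory hashes the same.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .adequacy import adequacy_report
from .errors import PipelineUsageError
from .impact import expenditure_report, impact_report
from .scenarios import (
    DietProfile,
    apply_waste,
    build_scenarios,
    builtin_scenarios,
)
from .synthetic import SyntheticSpec, generate_bau_supply, generate_database
from .tables import FoodDatabase, read_food_database, write_results
from .uncertainty import functional_unit_comparison, quantile_sweep

logger = logging.getLogger("dietshift")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``tables_dir`` (a directory in the canonical schema, with a
    ``bau_supply.csv``) or a synthetic setup (``seed`` +
    ``items_per_group``) supplies the inputs.
    """

    outdir: str = "results"
    tables_dir: str | None = None
    seed: int = 0
    items_per_group: int = 3
    scenario_names: tuple[str, ...] = ()  # empty = all seven
    bases: tuple[str, ...] = ("mass", "energy")
    quantiles: tuple[str, ...] = ("q25", "median", "q75")
    expenditure_aggregation: str = "group"
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.bases:
            raise PipelineUsageError("at least one functional-unit basis is required")
        for b in self.bases:
            if b not in ("mass", "energy"):
                raise PipelineUsageError(f"unknown basis {b!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**{k: v for k, v in payload.items() if k in cls.__dataclass_fields__})
        for key in ("scenario_names", "bases", "quantiles"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # relocatable reproducibility
        payload.pop("log_level")
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[FoodDatabase, DietProfile]:
    if config.tables_dir is not None:
        db = read_food_database(config.tables_dir)
        supply_path = Path(config.tables_dir) / "bau_supply.csv"
        if not supply_path.exists():
            raise PipelineUsageError(f"no baseline supply table at {supply_path}")
        from .tables import _read_table

        df = _read_table(supply_path)
        supply = DietProfile(
            amounts=dict(zip(df["group"].astype(str), df["amount_g_day"].astype(float))),
            basis="mass",
            stage="supply",
            name="BAU",
        )
        return db, supply
    spec = SyntheticSpec(seed=config.seed, items_per_group=config.items_per_group)
    db = generate_database(spec)
    return db, generate_bau_supply(spec, db)


def build_scenario_profiles(
    db: FoodDatabase, supply: DietProfile, config: RunConfig
) -> dict[tuple[str, str], DietProfile]:
    """(scenario, basis) -> consumption-stage profile, waste-adjusted first."""
    bau = apply_waste(supply, db)
    profiles: dict[tuple[str, str], DietProfile] = {}
    for basis in config.bases:
        specs = builtin_scenarios(functional_unit=basis)
        if config.scenario_names:
            specs = [s for s in specs if s.name in config.scenario_names]
            if not specs:
                raise PipelineUsageError(f"no known scenario in {config.scenario_names}")
        for name, prof in build_scenarios(bau, specs, db).items():
            prof.basis = basis
            profiles[(name, basis)] = prof
    return profiles


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s [%(message)s]",
        force=False,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage=inputs loading tables")
    db, supply = _load_inputs(config)
    profiles = build_scenario_profiles(db, supply, config)
    logger.info("stage=scenarios built %d profiles", len(profiles))

    files: dict[str, Path] = {}
    prof_frames = [p.to_frame() for p in profiles.values()]
    files["scenario_profiles.csv"] = write_results(
        pd.concat(prof_frames, ignore_index=True), outdir / "scenario_profiles.csv"
    )

    sweeps = {}
    for basis in config.bases:
        by_name = {n: p for (n, b), p in profiles.items() if b == basis}
        logger.info("stage=adequacy basis=%s", basis)
        files[f"adequacy_{basis}.csv"] = write_results(
            adequacy_report(by_name, db), outdir / f"adequacy_{basis}.csv"
        )
        logger.info("stage=impact basis=%s", basis)
        files[f"impact_{basis}.csv"] = write_results(
            impact_report(by_name, db), outdir / f"impact_{basis}.csv"
        )
        logger.info("stage=cost basis=%s", basis)
        files[f"expenditure_{basis}.csv"] = write_results(
            expenditure_report(by_name, db, aggregation=config.expenditure_aggregation),
            outdir / f"expenditure_{basis}.csv",
        )
        logger.info("stage=sweep basis=%s quantiles=%s", basis, ",".join(config.quantiles))
        sweep = quantile_sweep(by_name, db, quantiles=config.quantiles)
        sweeps[basis] = sweep
        files[f"sweep_{basis}.csv"] = write_results(sweep, outdir / f"sweep_{basis}.csv")

    if {"mass", "energy"} <= set(config.bases):
        logger.info("stage=fu-comparison")
        med = {
            b: s[s["quantile"] == "median"][["scenario", "metric", "value"]]
            for b, s in sweeps.items()
        }
        files["fu_comparison.csv"] = write_results(
            functional_unit_comparison(med["mass"], med["energy"]),
            outdir / "fu_comparison.csv",
        )

    manifest = {
        "package": "dietshift",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("stage=done wrote %d files to %s", len(files) + 1, outdir)
    return manifest
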