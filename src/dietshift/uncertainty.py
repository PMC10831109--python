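"""Uncertainty analyses: quantile sweeps, conscious-consumer reallocation,
and functional-unit sensitivity.

Two complementary analyses bound the results:

* **Quantile sweep** — recompute every downstream metric with all per-item
  composition/footprint/price data evaluated at Q25, the median, and Q75.
* **Conscious consumer** — within each food group, move the whole group
  amount onto the single item best for an objective (cheapest, lowest
  footprint, most protein, ...), bounding what deliberate in-store choices
  could achieve without changing group-level diet composition.

A third comparison contrasts results computed under the mass- and
energy-based functional units scenario by scenario.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

from .adequacy import nutrient_supply
from .errors import CoverageError, PipelineUsageError
from .impact import daily_expenditure, total_impact
from .scenarios import DietProfile, energy_of
from .tables import INDICATORS, QUANTILES, FoodDatabase


def quantile_sweep(
    scenarios: Mapping[str, DietProfile],
    db: FoodDatabase,
    quantiles: Iterable[str] = QUANTILES,
    include_nutrients: bool = True,
) -> pd.DataFrame:
    """Recompute impacts, cost and (optionally) nutrient supplies at each
    quantile of the input tables.

    Tidy cube: scenario, basis, quantile, metric, value. Metrics are the
    footprint indicators, ``cost``, ``energy_kcal`` (quantile-invariant) and
    ``nutrient:<name>`` rows.
    """
    quantiles = list(quantiles)
    for q in quantiles:
        if q not in QUANTILES:
            raise KeyError(f"unknown quantile {q!r}")
    if _all_degenerate(db):
        warnings.warn("all quantile triplets are degenerate; sweep adds no spread", stacklevel=2)
    rows = []
    for name, prof in scenarios.items():
        total_kcal, _ = energy_of(prof, db)
        for q in quantiles:
            imp = total_impact(prof, db, quantile=q)
            exp = daily_expenditure(prof, db)
            metrics = dict(imp.totals)
            metrics["cost"] = exp.cost.at(q)
            metrics["energy_kcal"] = total_kcal
            if include_nutrients:
                for n, v in nutrient_supply(prof, db, quantile=q).items():
                    metrics[f"nutrient:{n}"] = v
            for metric, value in metrics.items():
                rows.append(
                    {
                        "scenario": name,
                        "basis": prof.basis,
                        "quantile": q,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def _all_degenerate(db: FoodDatabase) -> bool:
    for it in db.items:
        triplets = [it.price, *it.nutrients.values(), *it.footprints.values()]
        if any(t.q25 != t.q75 for t in triplets):
            return False
    return True


#: objective name -> (optimum, value-of-item function)
def _objective_fn(objective: str, quantile: str):
    if objective.startswith(("min_", "max_")):
        direction, attr = objective.split("_", 1)
    else:
        raise CoverageError(f"objective must look like min_<attr> or max_<attr>: {objective!r}")
    pick = min if direction == "min" else max

    def value(item):
        if attr == "cost":
            return item.price.at(quantile)
        if attr in INDICATORS:
            return item.footprints[attr].at(quantile)
        if attr in item.nutrients:
            return item.nutrients[attr].at(quantile)
        raise CoverageError(f"item {item.id!r} has no attribute for objective {objective!r}")

    return pick, value


def conscious_consumer(
    diet: DietProfile, db: FoodDatabase, objective: str, quantile: str = "median"
) -> DietProfile:
    """Reallocate each group's amount onto its single best item.

    ``objective`` is ``min_cost``, ``min_ghge``, ``min_lu``, ``min_wu``,
    ``max_protein`` or any ``min_/max_<nutrient>``. Group totals are
    unchanged; only the within-group split moves. Ties break by item id for
    reproducibility.
    """
    pick, value = _objective_fn(objective, quantile)
    item_amounts: dict[str, float] = {}
    for group, grams in diet.amounts.items():
        if grams == 0.0:
            continue
        items = db.items_in_group(group)
        if not items:
            raise CoverageError(f"no items in database for consumed group {group!r}")
        best = pick(items, key=lambda it: (value(it), it.id))
        item_amounts[best.id] = item_amounts.get(best.id, 0.0) + grams
    return DietProfile(
        amounts=dict(diet.amounts),
        basis=diet.basis,
        stage=diet.stage,
        name=f"{diet.name}|{objective}" if diet.name else objective,
        item_amounts=item_amounts,
    )


def functional_unit_comparison(
    results_mass: pd.DataFrame, results_energy: pd.DataFrame
) -> pd.DataFrame:
    """Per-scenario ratio of energy-basis to mass-basis totals.

    Inputs are tidy frames with columns (scenario, metric, value) — e.g. a
    median-quantile slice of :func:`quantile_sweep`. Output columns:
    scenario, metric, value_mass, value_energy, ratio,
    energy_below_mass (True where the energy basis gives the lower total).
    """
    need = {"scenario", "metric", "value"}
    for tag, df in (("mass", results_mass), ("energy", results_energy)):
        missing = need - set(df.columns)
        if missing:
            raise PipelineUsageError(f"{tag} results missing column(s): {sorted(missing)}")
    m = results_mass.groupby(["scenario", "metric"], as_index=False)["value"].first()
    e = results_energy.groupby(["scenario", "metric"], as_index=False)["value"].first()
    if set(m["scenario"]) != set(e["scenario"]):
        raise PipelineUsageError(
            "mismatched scenario sets: "
            f"{sorted(set(m['scenario']) ^ set(e['scenario']))}"
        )
    merged = m.merge(e, on=["scenario", "metric"], suffixes=("_mass", "_energy"))
    merged["ratio"] = merged["value_energy"] / merged["value_mass"]
    merged["energy_below_mass"] = merged["ratio"] < 1.0
    return merged.rename(columns={"value_mass": "value_mass", "value_energy": "value_energy"})
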