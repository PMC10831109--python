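"""Per-scenario nutrient supply scored against daily recommendations.

Supplies are additive over items: supply_n = sum_i kg_i x content_n,i at the
chosen quantile of the composition data. Each nutrient is scored on the
normalized scale

    score = supply / threshold - 1

so 0 marks the recommended level exactly. A "minimum"-direction nutrient is
adequate at score >= 0; a "limit" nutrient (sodium, saturated fat) is
adequate at score <= 0. Energy is reported alongside but never scored.

The recommendation table is expected to hold a single threshold per
nutrient — where recommendations differ by sex, the most stringent value
(the maximum, for minimum-type rows) is taken at table construction.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .errors import CoverageError, DataError, PipelineUsageError
from .scenarios import DietProfile, item_masses_kg
from .tables import FoodDatabase, Recommendation, RecommendationTable


def nutrient_supply(
    diet: DietProfile, db: FoodDatabase, quantile: str = "median"
) -> dict[str, float]:
    """Daily supply of every nutrient in the composition table.

    Fortified nutrients are included through the item contents (the
    composition triplets already carry the fortification increments).
    """
    masses = item_masses_kg(diet, db)
    supply: dict[str, float] = {n: 0.0 for n in db.nutrient_names}
    for item_id, kg in masses.items():
        item = db.item(item_id)
        for nutrient, triplet in item.nutrients.items():
            supply[nutrient] = supply.get(nutrient, 0.0) + kg * triplet.at(quantile)
    return supply


def adequacy_score(supply: float, rec: Recommendation) -> tuple[float, bool]:
    """Normalized deviation from the recommendation and the adequacy flag."""
    if rec.threshold <= 0:
        raise DataError(f"nonpositive threshold for {rec.nutrient!r}: {rec.threshold}")
    score = (supply - rec.threshold) / rec.threshold
    meets = supply >= rec.threshold if rec.direction == "minimum" else supply <= rec.threshold
    return score, meets


def adequacy_report(
    scenarios: Mapping[str, DietProfile],
    db: FoodDatabase,
    quantile: str = "median",
    baseline: str = "BAU",
    recommendations: RecommendationTable | None = None,
) -> pd.DataFrame:
    """Score every scenario x nutrient; long format, one row per pair.

    Columns: scenario, nutrient, supply, threshold, unit, direction, score,
    meets, pct_change_vs_bau (100 x (supply - supply_BAU) / supply_BAU;
    NaN where the baseline supply is zero).
    """
    if baseline not in scenarios:
        raise PipelineUsageError(f"baseline scenario {baseline!r} missing from input set")
    recs = recommendations or db.recommendations
    if recs is None or len(recs) == 0:
        raise PipelineUsageError("no recommendation table available")
    available = set(db.nutrient_names)
    missing = [r.nutrient for r in recs if r.nutrient not in available]
    if missing:
        raise CoverageError(f"recommended nutrient(s) absent from composition data: {missing}")

    supplies = {name: nutrient_supply(prof, db, quantile) for name, prof in scenarios.items()}
    bau = supplies[baseline]
    rows = []
    for name in scenarios:
        for rec in recs:
            s = supplies[name].get(rec.nutrient, 0.0)
            score, meets = adequacy_score(s, rec)
            base = bau.get(rec.nutrient, 0.0)
            pct = 100.0 * (s - base) / base if base > 0 else float("nan")
            rows.append(
                {
                    "scenario": name,
                    "nutrient": rec.nutrient,
                    "supply": s,
                    "threshold": rec.threshold,
                    "unit": rec.unit,
                    "direction": rec.direction,
                    "score": score,
                    "meets": meets,
                    "pct_change_vs_bau": pct,
                }
            )
    return pd.DataFrame(rows)
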