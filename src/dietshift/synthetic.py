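"""Seed-reproducible synthetic food databases, baselines and recommendations.

The generator emulates the statistical structure the downstream analysis
assumes rather than any real inventory:

* animal-source groups carry much larger footprints than their plant-based
  alternatives, which in turn exceed whole foods (e.g. group-median GHGe of
  Meats > Plant-based Meat > Legumes);
* PBAs are fortified (B12, vitamin D, calcium, iron) and saltier than the
  conventional group they mimic;
* within-group footprint, nutrient and price dispersion is log-normal, so
  quantile triplets are ordered and right-skewed;
* the baseline supply has zero consumption of PBAs, legumes and soy foods.

All randomness is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import CoverageError, DataError
from .scenarios import DietProfile
from .tables import (
    FoodDatabase,
    FoodItem,
    Recommendation,
    RecommendationTable,
    Triplet,
    write_food_database,
)
from .taxonomy import GROUPS, PBA_COUNTERPART, PBA_GROUPS

# Group-level medians: GHGe kg CO2e/kg, cropland m2/kg, freshwater L/kg,
# price SEK/kg, energy density kcal/100 g, household waste fraction.
# Energy densities follow the magnitudes implied by per-capita supply and
# energy statistics (meat ~1.75 kcal/g, dairy ~1.1, grains ~2.9, ...);
# footprints/prices are order-of-magnitude realistic for Swedish retail,
# with a beef-heavy Meats group and dark-chocolate-heavy PB Snacks.
_G = {
    #                 ghge   lu    wu    price kcal  waste
    "Meats":              (20.0, 30.0, 500.0, 110.0, 175.0, 0.11),
    "Plant-based Meat":   (3.0, 3.5, 300.0, 105.0, 150.0, 0.09),
    "Eggs":               (2.0, 5.0, 200.0, 60.0, 140.0, 0.08),
    "Dairy":              (1.4, 1.5, 100.0, 25.0, 110.0, 0.07),
    "Plant-based Dairy":  (0.5, 0.8, 60.0, 25.0, 98.0, 0.07),
    "Seafood":            (5.0, 1.0, 50.0, 180.0, 167.0, 0.09),
    "Plant-based Seafood":(2.5, 2.0, 100.0, 215.0, 150.0, 0.08),
    "Vegetables":         (0.5, 0.4, 80.0, 30.0, 30.0, 0.20),
    "Fruits":             (0.6, 0.6, 150.0, 30.0, 73.0, 0.20),
    "Potatoes":           (0.2, 0.3, 30.0, 12.0, 85.0, 0.15),
    "Grains":             (0.8, 1.5, 150.0, 20.0, 294.0, 0.12),
    "Plant fats":         (2.5, 4.0, 100.0, 60.0, 722.0, 0.05),
    "Legumes":            (0.9, 2.2, 150.0, 35.0, 120.0, 0.10),
    "Nuts":               (1.5, 5.0, 1500.0, 120.0, 580.0, 0.05),
    "Snacks":             (4.0, 4.0, 300.0, 90.0, 394.0, 0.05),
    "Plant-based Snacks": (4.5, 5.0, 350.0, 95.0, 400.0, 0.05),
    "Other":              (1.0, 0.8, 100.0, 25.0, 42.0, 0.05),
}

# Group-median nutrient content per kg of food. Units per kg: protein,
# fibre, pufa, sfa in g; iron, zinc, calcium, magnesium, phosphorus,
# vitamin_c, vitamin_e, sodium in mg; selenium, folate, vitamin_b12,
# vitamin_d in ug. Plant groups have zero intrinsic B12 and vitamin D.
NUTRIENTS = (
    "protein", "fibre", "iron", "zinc", "calcium", "magnesium", "phosphorus",
    "selenium", "folate", "vitamin_b12", "vitamin_c", "vitamin_d",
    "vitamin_e", "pufa", "sfa", "sodium",
)

_N = {
    "Meats":              dict(protein=190, fibre=0, iron=20, zinc=40, calcium=100, magnesium=230, phosphorus=2000, selenium=150, folate=100, vitamin_b12=20, vitamin_c=10, vitamin_d=8, vitamin_e=5, pufa=15, sfa=60, sodium=7000),
    "Plant-based Meat":   dict(protein=160, fibre=45, iron=25, zinc=25, calcium=300, magnesium=400, phosphorus=2000, selenium=30, folate=600, vitamin_b12=0, vitamin_c=10, vitamin_d=0, vitamin_e=20, pufa=40, sfa=20, sodium=0),
    "Eggs":               dict(protein=125, fibre=0, iron=18, zinc=13, calcium=500, magnesium=120, phosphorus=2000, selenium=300, folate=500, vitamin_b12=20, vitamin_c=0, vitamin_d=30, vitamin_e=20, pufa=20, sfa=30, sodium=1300),
    "Dairy":              dict(protein=50, fibre=0, iron=1, zinc=4, calcium=1800, magnesium=110, phosphorus=950, selenium=20, folate=50, vitamin_b12=4, vitamin_c=10, vitamin_d=10, vitamin_e=1, pufa=1, sfa=22, sodium=500),
    "Plant-based Dairy":  dict(protein=33, fibre=8, iron=2, zinc=3, calcium=300, magnesium=100, phosphorus=600, selenium=10, folate=30, vitamin_b12=0, vitamin_c=0, vitamin_d=0, vitamin_e=5, pufa=5, sfa=5, sodium=0),
    "Seafood":            dict(protein=180, fibre=0, iron=8, zinc=10, calcium=300, magnesium=300, phosphorus=2200, selenium=400, folate=150, vitamin_b12=50, vitamin_c=0, vitamin_d=120, vitamin_e=20, pufa=30, sfa=10, sodium=4000),
    "Plant-based Seafood":dict(protein=120, fibre=30, iron=12, zinc=8, calcium=400, magnesium=200, phosphorus=1200, selenium=60, folate=200, vitamin_b12=0, vitamin_c=0, vitamin_d=0, vitamin_e=40, pufa=50, sfa=15, sodium=0),
    "Vegetables":         dict(protein=20, fibre=25, iron=8, zinc=4, calcium=400, magnesium=150, phosphorus=400, selenium=10, folate=800, vitamin_b12=0, vitamin_c=400, vitamin_d=0, vitamin_e=15, pufa=2, sfa=1, sodium=200),
    "Fruits":             dict(protein=8, fibre=20, iron=3, zinc=1, calcium=150, magnesium=100, phosphorus=150, selenium=5, folate=300, vitamin_b12=0, vitamin_c=450, vitamin_d=0, vitamin_e=10, pufa=1, sfa=2, sodium=30),
    "Potatoes":           dict(protein=20, fibre=20, iron=7, zinc=3, calcium=100, magnesium=220, phosphorus=450, selenium=5, folate=180, vitamin_b12=0, vitamin_c=150, vitamin_d=0, vitamin_e=1, pufa=1, sfa=1, sodium=100),
    "Grains":             dict(protein=110, fibre=80, iron=30, zinc=20, calcium=300, magnesium=800, phosphorus=2500, selenium=100, folate=500, vitamin_b12=0, vitamin_c=0, vitamin_d=0, vitamin_e=15, pufa=10, sfa=4, sodium=3000),
    "Plant fats":         dict(protein=2, fibre=0, iron=1, zinc=1, calcium=50, magnesium=20, phosphorus=50, selenium=2, folate=10, vitamin_b12=0, vitamin_c=0, vitamin_d=0, vitamin_e=300, pufa=250, sfa=120, sodium=1000),
    "Legumes":            dict(protein=80, fibre=65, iron=22, zinc=12, calcium=500, magnesium=400, phosphorus=1300, selenium=40, folate=1700, vitamin_b12=0, vitamin_c=10, vitamin_d=0, vitamin_e=5, pufa=5, sfa=1, sodium=300),
    "Nuts":               dict(protein=200, fibre=80, iron=35, zinc=30, calcium=700, magnesium=2000, phosphorus=4000, selenium=150, folate=600, vitamin_b12=0, vitamin_c=10, vitamin_d=0, vitamin_e=150, pufa=250, sfa=60, sodium=300),
    "Snacks":             dict(protein=60, fibre=25, iron=20, zinc=15, calcium=500, magnesium=500, phosphorus=1500, selenium=30, folate=150, vitamin_b12=1, vitamin_c=0, vitamin_d=1, vitamin_e=30, pufa=40, sfa=120, sodium=1500),
    "Plant-based Snacks": dict(protein=70, fibre=40, iron=40, zinc=15, calcium=600, magnesium=800, phosphorus=2000, selenium=30, folate=200, vitamin_b12=0, vitamin_c=0, vitamin_d=0, vitamin_e=40, pufa=60, sfa=140, sodium=0),
    "Other":              dict(protein=5, fibre=2, iron=2, zinc=1, calcium=100, magnesium=50, phosphorus=100, selenium=5, folate=20, vitamin_b12=0, vitamin_c=300, vitamin_d=0, vitamin_e=2, pufa=1, sfa=2, sodium=2000),
}

#: Fortification increments added to PBA items, per kg of food.
FORTIFICATION_AMOUNTS = {
    "vitamin_b12": 4.0,  # ug/kg
    "vitamin_d": 15.0,  # ug/kg
    "calcium": 1200.0,  # mg/kg
    "iron": 10.0,  # mg/kg
}

#: Baseline per-capita supply, g/person/day per group (PBAs, legumes and
#: soy foods at zero: absent from the baseline consumption statistics).
BAU_SUPPLY_G: dict[str, float] = {
    "Meats": 190.0,
    "Plant-based Meat": 0.0,
    "Eggs": 30.0,
    "Dairy": 400.0,
    "Plant-based Dairy": 0.0,
    "Seafood": 30.0,
    "Plant-based Seafood": 0.0,
    "Vegetables": 165.0,
    "Fruits": 150.0,
    "Potatoes": 100.0,
    "Grains": 170.0,
    "Plant fats": 27.0,
    "Legumes": 0.0,
    "Nuts": 8.0,
    "Snacks": 110.0,
    "Plant-based Snacks": 0.0,
    "Other": 330.0,
}

# Daily thresholds for moderately active healthy adults (18-65 y), most
# stringent sex where recommendations differ. SYNTHETIC PLACEHOLDERS shaped
# after Nordic-style reference values; override from file for real analyses.
_DEFAULT_RECS = (
    # nutrient, threshold/day, unit, direction
    ("protein", 56.0, "g", "minimum"),
    ("fibre", 28.0, "g", "minimum"),
    ("iron", 15.0, "mg", "minimum"),
    ("zinc", 11.0, "mg", "minimum"),
    ("calcium", 950.0, "mg", "minimum"),
    ("magnesium", 350.0, "mg", "minimum"),
    ("phosphorus", 600.0, "mg", "minimum"),
    ("selenium", 90.0, "ug", "minimum"),
    ("folate", 400.0, "ug", "minimum"),
    ("vitamin_b12", 4.0, "ug", "minimum"),
    ("vitamin_c", 110.0, "mg", "minimum"),
    ("vitamin_d", 10.0, "ug", "minimum"),
    ("vitamin_e", 11.0, "mg", "minimum"),
    ("pufa", 11.0, "g", "minimum"),
    ("sfa", 22.0, "g", "limit"),
    ("sodium", 2300.0, "mg", "limit"),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world.

    ``footprint_ordering`` overrides group-median footprints (indicator ->
    group -> median); defaults encode ASF > PBA > WF. ``price_dispersion``
    is the log-scale spread of within-group prices (right-skewed; the
    default Q75/median ratio is ~1.4). ``sodium_uplift`` multiplies each
    PBA group's sodium relative to the conventional group it mimics.
    """

    seed: int = 0
    items_per_group: int = 3
    footprint_ordering: Mapping[str, Mapping[str, float]] | None = None
    fortification_policy: frozenset[str] = frozenset(FORTIFICATION_AMOUNTS)
    sodium_uplift: float = 1.3
    price_dispersion: float = 0.5
    footprint_dispersion: float = 0.35
    nutrient_dispersion: float = 0.3
    item_jitter: float = 0.18  # log-scale between-item spread within a group

    def __post_init__(self):
        if self.items_per_group < 1:
            raise DataError("items_per_group must be >= 1")
        if self.seed < 0:
            raise DataError("seed must be nonnegative")
        unknown = set(self.fortification_policy) - set(FORTIFICATION_AMOUNTS)
        if unknown:
            raise DataError(f"no fortification amounts defined for: {sorted(unknown)}")


def _lognormal_triplet(median: float, sigma: float) -> Triplet:
    """Quantiles of a log-normal with the given median and log-sd.

    0.6745 is the standard normal 75th-percentile z-score, so
    q75/median = exp(0.6745 sigma) > median/q25's inverse mirror, giving
    the right-skew (q75 - median > median - q25) seen in retail prices.
    """
    if median == 0.0:
        return Triplet.point(0.0)
    z = 0.6744897501960817
    return Triplet(
        float(median * np.exp(-z * sigma)), float(median), float(median * np.exp(z * sigma))
    )


def _slug(group: str, k: int) -> str:
    base = group.lower().replace(" ", "_").replace("-", "_")
    return f"{base}_{k + 1:02d}"


def generate_database(spec: SyntheticSpec) -> FoodDatabase:
    """Generate a fully validated synthetic food database."""
    rng = np.random.default_rng(spec.seed)
    overrides = {k: dict(v) for k, v in (spec.footprint_ordering or {}).items()}
    items: list[FoodItem] = []
    for group in GROUPS:
        ghge, lu, wu, price, kcal100, waste = _G[group]
        ghge = overrides.get("ghge", {}).get(group, ghge)
        lu = overrides.get("lu", {}).get(group, lu)
        wu = overrides.get("wu", {}).get(group, wu)
        base_nut = dict(_N[group])
        if group in PBA_GROUPS:
            base_nut["sodium"] = _N[PBA_COUNTERPART[group]]["sodium"] * spec.sodium_uplift
        k = spec.items_per_group
        shares = rng.dirichlet(np.full(k, 2.0))
        for i in range(k):
            jit = lambda m, s: float(m * np.exp(rng.normal(0.0, s))) if m else 0.0
            density = float(np.clip(jit(kcal100, 0.08), 10.0, 900.0))
            nutrients = {
                n: _lognormal_triplet(jit(base_nut[n], spec.item_jitter), spec.nutrient_dispersion)
                for n in NUTRIENTS
            }
            if group in PBA_GROUPS:
                for n in sorted(spec.fortification_policy):
                    nutrients[n] = nutrients[n].shifted(FORTIFICATION_AMOUNTS[n])
            footprints = {
                ind: _lognormal_triplet(jit(val, spec.item_jitter), spec.footprint_dispersion)
                for ind, val in (("ghge", ghge), ("lu", lu), ("wu", wu))
            }
            items.append(
                FoodItem(
                    id=_slug(group, i),
                    group=group,
                    energy_density=density,
                    nutrients=nutrients,
                    footprints=footprints,
                    price=_lognormal_triplet(jit(price, spec.item_jitter), spec.price_dispersion),
                    waste_fraction=waste,
                    share_within_group=float(shares[i]),
                    fortified_with=frozenset(spec.fortification_policy)
                    if group in PBA_GROUPS
                    else frozenset(),
                )
            )
    return FoodDatabase(items=items, recommendations=generate_recommendations(spec))


def group_median(db: FoodDatabase, group: str, indicator: str) -> float:
    """Median over a group's item-median footprint intensities."""
    vals = [it.footprints[indicator].median for it in db.items_in_group(group)]
    if not vals:
        raise CoverageError(f"no items in group {group!r}")
    return float(np.median(vals))


def generate_bau_supply(spec: SyntheticSpec, db: FoodDatabase) -> DietProfile:
    """The baseline supply profile (g/person/day per group).

    Group totals follow the canonical per-capita supply defaults; the
    item-level split within each group is the database's seed-fixed shares.
    """
    missing = [g for g, v in BAU_SUPPLY_G.items() if v > 0 and not db.items_in_group(g)]
    if missing:
        raise CoverageError(f"baseline groups absent from database: {missing}")
    return DietProfile(amounts=dict(BAU_SUPPLY_G), basis="mass", stage="supply", name="BAU")


def generate_recommendations(
    spec: SyntheticSpec, override: str | Path | RecommendationTable | None = None
) -> RecommendationTable:
    """The default recommendation table, optionally merged with overrides.

    Overrides replace only the nutrients they list; all other rows are kept.
    """
    base = RecommendationTable(
        [
            Recommendation(n, t, unit=u, direction=d, source_note="synthetic placeholder")
            for n, t, u, d in _DEFAULT_RECS
        ]
    )
    if override is None:
        return base
    if isinstance(override, (str, Path)):
        from .tables import _read_table

        override = RecommendationTable.from_frame(_read_table(Path(override)))
    return base.merged_with(override)


def generate_tables(spec: SyntheticSpec, directory: str | Path) -> dict[str, Path]:
    """Emit the full synthetic table set in the canonical schema, plus the
    baseline supply profile as ``bau_supply.csv``."""
    import pandas as pd

    db = generate_database(spec)
    paths = write_food_database(db, directory)
    supply = generate_bau_supply(spec, db)
    bau_path = Path(directory) / "bau_supply.csv"
    pd.DataFrame(
        [{"group": g, "amount_g_day": supply.amounts[g]} for g in GROUPS]
    ).to_csv(bau_path, index=False)
    paths["bau_supply"] = bau_path
    return paths
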