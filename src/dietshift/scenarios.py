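"""Construction of plant-based replacement scenarios from a baseline diet.

The baseline ("BAU", business-as-usual) is a per-capita supply profile in
g/person/day per food group. Household loss and waste fractions convert it to
a consumption-stage profile, on which six replacement scenarios are built:

* vegan (VGN): all animal-source food (ASF) groups removed entirely,
* vegetarian (VGT): meats and seafood removed, eggs and dairy retained,
* flexitarian (FLX): every ASF group halved,

each in a PBA variant (removed amounts routed to the matching plant-based
alternative group) and a WHOLE variant (removed amounts redistributed over
whole-food groups under per-group caps, e.g. the EAT-Lancet upper reference
value for legumes).

Replacement is equated to the removed food under one of two functional
units: mass (replacement grams = removed grams) or energy (replacement
grams chosen so the added kcal equal the removed kcal).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CoverageError, DataError, InfeasibleSubstitution, SchemaError
from .tables import FoodDatabase
from .taxonomy import ASF_GROUPS, GROUP_ORDER, GROUPS

SCENARIO_NAMES = ("BAU", "VGNPBA", "VGNWHOLE", "VGTPBA", "VGTWHOLE", "FLXPBA", "FLXWHOLE")

_ALLOC_TOL = 1e-9


@dataclass
class DietProfile:
    """Per-capita diet: g/person/day per food group.

    ``basis`` records the functional unit the profile was constructed under
    (the amounts are grams in either case); ``stage`` is "supply" before and
    "consumption" after the waste adjustment. ``item_amounts`` optionally
    pins an explicit item-level split (g/day per item id); when absent,
    group amounts are split over items by their database shares.
    """

    amounts: dict[str, float]
    basis: str = "mass"
    stage: str = "consumption"
    name: str = ""
    item_amounts: dict[str, float] | None = None

    def __post_init__(self):
        for g, v in self.amounts.items():
            if v < 0:
                raise DataError(f"negative amount for group {g!r}: {v}")
        if self.basis not in ("mass", "energy"):
            raise DataError(f"basis must be 'mass' or 'energy', got {self.basis!r}")
        if self.stage not in ("supply", "consumption"):
            raise DataError(f"stage must be 'supply' or 'consumption', got {self.stage!r}")

    def amount(self, group: str) -> float:
        return self.amounts.get(group, 0.0)

    @property
    def total_g(self) -> float:
        return sum(self.amounts.values())

    def scaled(self, factor: float) -> "DietProfile":
        return DietProfile(
            amounts={g: v * factor for g, v in self.amounts.items()},
            basis=self.basis,
            stage=self.stage,
            name=self.name,
            item_amounts=None
            if self.item_amounts is None
            else {i: v * factor for i, v in self.item_amounts.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "amount_g_day": self.amounts[g]}
            for g in sorted(self.amounts, key=lambda g: GROUP_ORDER.get(g, 99))
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "scenario", self.name)
        df.insert(1, "basis", self.basis)
        df.insert(2, "stage", self.stage)
        return df


def item_masses_kg(diet: DietProfile, db: FoodDatabase) -> dict[str, float]:
    """Resolve a profile to kg/day per item.

    Honours an explicit ``item_amounts`` split when present; otherwise each
    group's grams are split pro rata by the items' within-group shares.
    """
    if diet.item_amounts is not None:
        return {i: g / 1000.0 for i, g in diet.item_amounts.items()}
    out: dict[str, float] = {}
    for group, grams in diet.amounts.items():
        if grams == 0.0:
            continue
        items = db.items_in_group(group)
        if not items:
            raise CoverageError(f"no items in database for consumed group {group!r}")
        wsum = sum(it.share_within_group for it in items)
        for it in items:
            out[it.id] = grams * (it.share_within_group / wsum) / 1000.0
    return out


# ---------------------------------------------------------------------------
# waste adjustment and energy content
# ---------------------------------------------------------------------------


def apply_waste(supply: DietProfile, db: FoodDatabase) -> DietProfile:
    """Supply -> consumption: amount x (1 - group waste fraction)."""
    if supply.stage != "supply":
        raise DataError("apply_waste expects a supply-stage profile")
    amounts = {}
    for group, grams in supply.amounts.items():
        w = db.group_waste_fraction(group) if grams > 0 else 0.0
        if not (0.0 <= w < 1.0):
            raise DataError(f"waste fraction for {group!r} out of [0,1): {w}")
        amounts[group] = grams * (1.0 - w)
    return DietProfile(amounts=amounts, basis=supply.basis, stage="consumption", name=supply.name)


def energy_of(diet: DietProfile, db: FoodDatabase) -> tuple[float, dict[str, float]]:
    """Total and per-group energy content, kcal/person/day."""
    per_group: dict[str, float] = {}
    for group, grams in diet.amounts.items():
        if grams == 0.0:
            per_group[group] = 0.0
            continue
        try:
            density = db.group_energy_density(group)  # kcal/g
        except KeyError as exc:
            raise CoverageError(str(exc)) from None
        per_group[group] = grams * density
    return sum(per_group.values()), per_group


# ---------------------------------------------------------------------------
# scenario specification and substitution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative substitution rule set.

    ``replacement_map`` maps each removed group to weighted replacement
    targets. ``caps`` are per-group maxima in g/day (overflow reallocates to
    the remaining targets in descending-weight order, ties broken by group
    name). ``functional_unit`` selects mass- or energy-equivalent
    replacement.
    """

    name: str
    removed_groups: tuple[str, ...] = ()
    reduction_fraction: float = 1.0
    mode: str = "none"  # {"PBA", "WF", "none"}
    replacement_map: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    caps: tuple[tuple[str, float], ...] = ()
    functional_unit: str = "mass"

    def __post_init__(self):
        if self.mode not in ("PBA", "WF", "none"):
            raise DataError(f"mode must be PBA/WF/none, got {self.mode!r}")
        if self.mode != "none" and not (0.0 < self.reduction_fraction <= 1.0):
            raise DataError(f"reduction fraction must be in (0,1], got {self.reduction_fraction}")
        if self.functional_unit not in ("mass", "energy"):
            raise DataError(f"functional unit must be mass/energy, got {self.functional_unit!r}")

    @property
    def replacements(self) -> dict[str, tuple[tuple[str, float], ...]]:
        return dict(self.replacement_map)

    @property
    def cap_map(self) -> dict[str, float]:
        return dict(self.caps)

    @staticmethod
    def _freeze_map(mapping: Mapping[str, Mapping[str, float] | Iterable]) -> tuple:
        frozen = []
        for g in sorted(mapping):
            targets = mapping[g]
            if isinstance(targets, Mapping):
                targets = targets.items()
            frozen.append((g, tuple((t, float(w)) for t, w in targets)))
        return tuple(frozen)

    @classmethod
    def build(
        cls,
        name: str,
        removed_groups: Iterable[str],
        reduction_fraction: float,
        mode: str,
        replacement_map: Mapping[str, Mapping[str, float]],
        caps: Mapping[str, float] | None = None,
        functional_unit: str = "mass",
    ) -> "ScenarioSpec":
        return cls(
            name=name,
            removed_groups=tuple(sorted(removed_groups)),
            reduction_fraction=reduction_fraction,
            mode=mode,
            replacement_map=cls._freeze_map(replacement_map),
            caps=tuple(sorted((caps or {}).items())),
            functional_unit=functional_unit,
        )


#: EAT-Lancet-style upper reference values for whole-food groups, g/day.
#: Config defaults; override per ScenarioSpec.
DEFAULT_WF_CAPS: dict[str, float] = {
    "Vegetables": 600.0,
    "Fruits": 300.0,
    "Grains": 350.0,
    "Legumes": 150.0,
    "Nuts": 75.0,
    "Plant fats": 80.0,
}

#: Whole-food replacement weights per scenario family, seeded from the
#: canonical scenario table's group increments over BAU (config, not
#: hard-coded heuristics: pass your own replacement_map to override).
WF_WEIGHTS: dict[str, dict[str, float]] = {
    "VGNWHOLE": {
        "Vegetables": 165.0,
        "Fruits": 150.0,
        "Grains": 100.0,
        "Plant fats": 6.0,
        "Legumes": 150.0,
        "Nuts": 42.0,
    },
    "VGTWHOLE": {"Grains": 50.0, "Legumes": 150.0, "Nuts": 17.0},
    "FLXWHOLE": {
        "Vegetables": 85.0,
        "Fruits": 80.0,
        "Grains": 50.0,
        "Legumes": 100.0,
        "Nuts": 17.0,
    },
}

_PBA_MAP_FULL = {
    "Meats": {"Plant-based Meat": 1.0},
    "Eggs": {"Plant-based Meat": 1.0},  # no egg alternative; routed with meat
    "Dairy": {"Plant-based Dairy": 1.0},
    "Seafood": {"Plant-based Seafood": 1.0},
    "Snacks": {"Plant-based Snacks": 1.0},
}
_PBA_MAP_VGT = {
    "Meats": {"Plant-based Meat": 1.0},
    "Seafood": {"Plant-based Seafood": 1.0},
}


def builtin_scenarios(functional_unit: str = "mass") -> list[ScenarioSpec]:
    """The seven canonical scenario specs (BAU + six replacements)."""

    def wf_map(removed: Iterable[str], family: str) -> dict[str, dict[str, float]]:
        m = {g: dict(WF_WEIGHTS[family]) for g in removed if g != "Snacks"}
        m["Snacks"] = {"Plant-based Snacks": 1.0}
        return {g: m[g] for g in m if g in set(removed)} if "Snacks" in removed else {
            g: m[g] for g in m if g != "Snacks"
        }

    vgn_removed = sorted(ASF_GROUPS | {"Snacks"})
    vgt_removed = ["Meats", "Seafood"]
    specs = [
        ScenarioSpec(name="BAU", mode="none", functional_unit=functional_unit),
        ScenarioSpec.build(
            "VGNPBA", vgn_removed, 1.0, "PBA", _PBA_MAP_FULL, functional_unit=functional_unit
        ),
        ScenarioSpec.build(
            "VGNWHOLE",
            vgn_removed,
            1.0,
            "WF",
            wf_map(vgn_removed, "VGNWHOLE"),
            caps=DEFAULT_WF_CAPS,
            functional_unit=functional_unit,
        ),
        ScenarioSpec.build(
            "VGTPBA", vgt_removed, 1.0, "PBA", _PBA_MAP_VGT, functional_unit=functional_unit
        ),
        ScenarioSpec.build(
            "VGTWHOLE",
            vgt_removed,
            1.0,
            "WF",
            wf_map(vgt_removed, "VGTWHOLE"),
            caps=DEFAULT_WF_CAPS,
            functional_unit=functional_unit,
        ),
        ScenarioSpec.build(
            "FLXPBA", vgn_removed, 0.5, "PBA", _PBA_MAP_FULL, functional_unit=functional_unit
        ),
        ScenarioSpec.build(
            "FLXWHOLE",
            vgn_removed,
            0.5,
            "WF",
            wf_map(vgn_removed, "FLXWHOLE"),
            caps=DEFAULT_WF_CAPS,
            functional_unit=functional_unit,
        ),
    ]
    return specs


def _grams_per_unit(target: str, spec: ScenarioSpec, db: FoodDatabase | None) -> float:
    """Grams of *target* equivalent to one functional unit (1 g or 1 kcal)."""
    if spec.functional_unit == "mass":
        return 1.0
    if db is None:
        raise DataError("energy-basis substitution requires a food database")
    density = db.group_energy_density(target)  # kcal/g
    if density <= 0:
        raise DataError(f"zero energy density for replacement target {target!r}")
    return 1.0 / density


def substitute(bau: DietProfile, spec: ScenarioSpec, db: FoodDatabase | None = None) -> DietProfile:
    """Apply a replacement rule set to a consumption-stage baseline.

    Per removed group g, r_g = reduction_fraction x bau_g grams are removed.
    On the mass basis the same grams are added to the replacement targets,
    allocated by weight; on the energy basis the removed kcal are added
    (grams = kcal / target energy density). Targets at their cap overflow to
    the next-weighted target (descending weight, ties by name); if every
    target is capped the residual raises :class:`InfeasibleSubstitution`.
    Groups that are neither removed nor targets are untouched.
    """
    if bau.stage != "consumption":
        raise DataError("substitute expects a consumption-stage baseline")
    if spec.mode == "none":
        return DietProfile(
            amounts=dict(bau.amounts), basis=spec.functional_unit, stage="consumption", name=spec.name
        )

    out = dict(bau.amounts)
    caps = spec.cap_map
    replacements = spec.replacements
    unit = "g" if spec.functional_unit == "mass" else "kcal"

    for group in spec.removed_groups:
        removed_g = spec.reduction_fraction * bau.amount(group)
        if removed_g == 0.0:
            continue
        out[group] = bau.amount(group) - removed_g
        targets = replacements.get(group)
        if not targets:
            raise SchemaError(f"removed group {group!r} has no replacement targets")
        if spec.functional_unit == "mass":
            units = removed_g
        else:
            if db is None:
                raise DataError("energy-basis substitution requires a food database")
            units = removed_g * db.group_energy_density(group)  # kcal removed
        # deterministic overflow order: descending weight, ties by name
        ordered = sorted(targets, key=lambda tw: (-tw[1], tw[0]))
        _allocate(units, ordered, out, caps, spec, db, unit)

    for t in {t for targets in replacements.values() for t, _ in targets}:
        out.setdefault(t, 0.0)
    return DietProfile(amounts=out, basis=spec.functional_unit, stage="consumption", name=spec.name)


def _allocate(
    units: float,
    targets: list[tuple[str, float]],
    out: dict[str, float],
    caps: dict[str, float],
    spec: ScenarioSpec,
    db: FoodDatabase | None,
    unit: str,
) -> None:
    """Waterfill *units* over *targets* respecting caps (recursive)."""
    if units <= _ALLOC_TOL:
        return
    if not targets:
        raise InfeasibleSubstitution(units, unit)
    wsum = sum(w for _, w in targets)
    leftover = 0.0
    for target, w in targets:
        share_units = units * w / wsum
        gpu = _grams_per_unit(target, spec, db)
        grams = share_units * gpu
        headroom = caps.get(target, math.inf) - out.get(target, 0.0)
        if grams <= headroom + _ALLOC_TOL:
            out[target] = out.get(target, 0.0) + grams
        else:
            out[target] = out.get(target, 0.0) + max(headroom, 0.0)
            leftover += (grams - max(headroom, 0.0)) / gpu
    still = [
        (t, w)
        for t, w in targets
        if caps.get(t, math.inf) - out.get(t, 0.0) > _ALLOC_TOL
    ]
    _allocate(leftover, still, out, caps, spec, db, unit)


def build_scenarios(
    bau: DietProfile,
    specs: Iterable[ScenarioSpec],
    db: FoodDatabase | None = None,
) -> dict[str, DietProfile]:
    """Apply each spec to the baseline; returns {scenario name: profile}."""
    return {spec.name: substitute(bau, spec, db) for spec in specs}


# ---------------------------------------------------------------------------
# canonical scenario table
# ---------------------------------------------------------------------------


def _packaged_canonical_table() -> Path:
    return Path(importlib.resources.files("dietshift").joinpath("data/canonical_scenarios.csv"))


def load_canonical_scenarios(path: str | Path | None = None) -> list[tuple[str, DietProfile]]:
    """Load the packaged canonical scenario table (or a same-shaped file).

    Returns (scenario name, profile) pairs, one per scenario x basis, in
    table order. Mass-basis rows are g/person/day. The energy-basis rows
    reproduce the source table's lower numbers unmodified; for the baseline
    they are energy contents rather than gram amounts, so treat them as
    descriptive, not as construction ground truth.
    """
    from .tables import _read_table

    src = Path(path) if path is not None else _packaged_canonical_table()
    df = _read_table(src)
    for col in ("group", "basis"):
        if col not in df.columns:
            raise SchemaError(f"canonical scenario table is missing column {col!r}")
    scen_cols = [c for c in df.columns if c not in ("group", "basis")]
    if df[scen_cols].isna().any().any():
        bad = df[scen_cols].isna().stack()
        r, c = bad[bad].index[0]
        raise SchemaError(f"missing cell in canonical table: row {r}, column {c!r}")
    out: list[tuple[str, DietProfile]] = []
    for basis in ("mass", "energy"):
        sub = df[df["basis"] == basis]
        if sub.empty:
            continue
        for scen in scen_cols:
            amounts = dict(zip(sub["group"].astype(str), sub[scen].astype(float)))
            out.append(
                (scen, DietProfile(amounts=amounts, basis=basis, stage="consumption", name=scen))
            )
    return out


def canonical_bau(basis: str = "mass") -> DietProfile:
    """The baseline profile from the packaged canonical table."""
    for name, prof in load_canonical_scenarios():
        if name == "BAU" and prof.basis == basis:
            return prof
    raise CoverageError("canonical table lacks a BAU column")
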