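"""Domain types, readers/writers and validation for all input tables.

Internal unit conventions (readers convert on ingestion):

* quantities: grams per person per day,
* composition: nutrient amount per kg of food,
* footprint intensities: kg CO2e / m2 / L per kg of food,
* prices: currency (SEK in the shipped fixtures) per kg,
* energy density: kcal per 100 g (so kcal = grams x density / 100),
* one litre of beverage is accounted as one kg.

Every uncertain quantity is carried as a Q25/median/Q75 triplet; tables with
median-only columns load as degenerate triplets (Q25 = median = Q75).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationFailed
from .taxonomy import (
    ASF_GROUPS,
    GROUP_ORDER,
    PBA_GROUPS,
    is_known_group,
)

QUANTILES = ("q25", "median", "q75")

#: Footprint indicators and the units of their per-day totals.
INDICATORS = {"ghge": "kg CO2e", "lu": "m2", "wu": "L"}


class Triplet(NamedTuple):
    """A Q25/median/Q75 triplet for one uncertain per-kg quantity."""

    q25: float
    median: float
    q75: float

    def at(self, quantile: str) -> float:
        if quantile not in QUANTILES:
            raise KeyError(f"quantile must be one of {QUANTILES}, got {quantile!r}")
        return getattr(self, quantile)

    @classmethod
    def point(cls, value: float) -> "Triplet":
        """Degenerate triplet (used when only a median is known)."""
        return cls(value, value, value)

    @property
    def is_ordered(self) -> bool:
        return self.q25 <= self.median <= self.q75

    @property
    def is_nonnegative(self) -> bool:
        return self.q25 >= 0.0

    def scaled(self, factor: float) -> "Triplet":
        return Triplet(self.q25 * factor, self.median * factor, self.q75 * factor)

    def shifted(self, offset: float) -> "Triplet":
        return Triplet(self.q25 + offset, self.median + offset, self.q75 + offset)


@dataclass
class FoodItem:
    """One food product with its composition, footprint and price data."""

    id: str
    group: str
    energy_density: float  # kcal per 100 g
    nutrients: dict[str, Triplet] = field(default_factory=dict)  # per kg
    footprints: dict[str, Triplet] = field(default_factory=dict)  # per kg
    price: Triplet = Triplet.point(0.0)  # currency per kg
    waste_fraction: float = 0.0  # household loss/waste, in [0, 1)
    share_within_group: float = 1.0  # mass share of its group's total
    fortified_with: frozenset[str] = frozenset()

    @property
    def is_asf(self) -> bool:
        return self.group in ASF_GROUPS

    @property
    def is_pba(self) -> bool:
        return self.group in PBA_GROUPS

    @property
    def energy_density_per_g(self) -> float:
        """kcal per gram."""
        return self.energy_density / 100.0


@dataclass(frozen=True)
class Recommendation:
    """One daily intake threshold.

    direction="minimum" rows are adequate when supply >= threshold;
    direction="limit" rows (nutrients to restrict, e.g. sodium, saturated
    fat) are adequate when supply <= threshold.
    """

    nutrient: str
    threshold: float  # amount per day, same unit as the composition table
    unit: str = ""
    direction: str = "minimum"  # {"minimum", "limit"}
    source_note: str = ""


@dataclass
class RecommendationTable:
    rows: list[Recommendation] = field(default_factory=list)

    def __post_init__(self):
        names = [r.nutrient for r in self.rows]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate recommendation rows for: {dupes}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def get(self, nutrient: str) -> Recommendation | None:
        for r in self.rows:
            if r.nutrient == nutrient:
                return r
        return None

    @property
    def nutrients(self) -> list[str]:
        return [r.nutrient for r in self.rows]

    def merged_with(self, overrides: "RecommendationTable") -> "RecommendationTable":
        """Replace rows whose nutrient appears in *overrides*; keep the rest."""
        by_name = {r.nutrient: r for r in overrides.rows}
        rows = [by_name.pop(r.nutrient, r) for r in self.rows]
        rows.extend(by_name.values())  # genuinely new nutrients appended
        return RecommendationTable(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nutrient": r.nutrient,
                    "threshold": r.threshold,
                    "unit": r.unit,
                    "direction": r.direction,
                    "source_note": r.source_note,
                }
                for r in self.rows
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RecommendationTable":
        _require_columns(df, ["nutrient", "threshold"], "recommendations")
        rows = []
        for rec in df.to_dict("records"):
            rows.append(
                Recommendation(
                    nutrient=str(rec["nutrient"]),
                    threshold=float(rec["threshold"]),
                    unit=str(rec.get("unit", "") or ""),
                    direction=str(rec.get("direction", "minimum") or "minimum"),
                    source_note=str(rec.get("source_note", "") or ""),
                )
            )
        return cls(rows)


@dataclass
class FoodDatabase:
    """All per-item data plus the recommendation table.

    ``meta`` carries free-form provenance such as the LCA system boundary
    (default cradle-to-consumer, including consumer-stage cooking).
    """

    items: list[FoodItem]
    recommendations: RecommendationTable | None = None
    meta: dict = field(default_factory=lambda: {"boundary_note": "cradle-to-consumer"})

    def __post_init__(self):
        self._by_id = {it.id: it for it in self.items}
        if len(self._by_id) != len(self.items):
            raise SchemaError("duplicate item ids in database")

    # -- lookups ---------------------------------------------------------

    def item(self, item_id: str) -> FoodItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"no such item: {item_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def groups_present(self) -> list[str]:
        seen = {it.group for it in self.items}
        return sorted(seen, key=lambda g: GROUP_ORDER.get(g, len(GROUP_ORDER)))

    def items_in_group(self, group: str) -> list[FoodItem]:
        return [it for it in self.items if it.group == group]

    @property
    def nutrient_names(self) -> list[str]:
        names: set[str] = set()
        for it in self.items:
            names.update(it.nutrients)
        return sorted(names)

    # -- group-level aggregates ------------------------------------------

    def group_energy_density(self, group: str) -> float:
        """Share-weighted mean kcal/g over the group's items."""
        items = self.items_in_group(group)
        if not items:
            raise KeyError(f"no items in group {group!r}")
        wsum = sum(it.share_within_group for it in items)
        return sum(it.share_within_group * it.energy_density_per_g for it in items) / wsum

    def group_waste_fraction(self, group: str) -> float:
        items = self.items_in_group(group)
        if not items:
            raise KeyError(f"no items in group {group!r}")
        wsum = sum(it.share_within_group for it in items)
        return sum(it.share_within_group * it.waste_fraction for it in items) / wsum


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    item_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, item_id: str, rule: str, message: str) -> None:
        self.issues.append(Issue(item_id, rule, message))

    def rules(self) -> set[str]:
        return {i.rule for i in self.issues}


def validate_database(db: FoodDatabase) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    Rules emitted: unknown-group, class-consistency, energy-density-positive,
    waste-range, nonnegative-price, quantile-order, nonnegative-quantity,
    share-sum, threshold-positive, direction-valid.
    """
    rep = ValidationReport()
    for it in db.items:
        if not is_known_group(it.group):
            rep.add(it.id, "unknown-group", f"group {it.group!r} not in taxonomy")
            continue
        expect_asf, expect_pba = it.group in ASF_GROUPS, it.group in PBA_GROUPS
        if (it.is_asf, it.is_pba) != (expect_asf, expect_pba):
            # unreachable with derived flags, but guards subclasses overriding them
            rep.add(it.id, "class-consistency", "ASF/PBA flags contradict group class")
        if it.is_asf and it.is_pba:
            rep.add(it.id, "class-consistency", "item flagged both ASF and PBA")
        if not (it.energy_density > 0):
            rep.add(it.id, "energy-density-positive", f"energy density {it.energy_density}")
        if not (0.0 <= it.waste_fraction < 1.0):
            rep.add(it.id, "waste-range", f"waste fraction {it.waste_fraction}")
        if it.price.q25 < 0:
            rep.add(it.id, "nonnegative-price", f"price {it.price}")
        triplets: list[tuple[str, Triplet]] = [("price", it.price)]
        triplets += [(f"nutrient:{n}", t) for n, t in sorted(it.nutrients.items())]
        triplets += [(f"footprint:{n}", t) for n, t in sorted(it.footprints.items())]
        for name, t in triplets:
            if not t.is_ordered:
                rep.add(it.id, "quantile-order", f"{name} triplet not ordered: {t}")
            if name != "price" and not t.is_nonnegative:
                rep.add(it.id, "nonnegative-quantity", f"{name} negative: {t}")
    for group in db.groups_present:
        share = sum(it.share_within_group for it in db.items_in_group(group))
        if not math.isclose(share, 1.0, rel_tol=0, abs_tol=1e-6):
            rep.add(group, "share-sum", f"within-group shares sum to {share:.6g}")
    if db.recommendations is not None:
        for r in db.recommendations:
            if not (r.threshold > 0):
                rep.add(r.nutrient, "threshold-positive", f"threshold {r.threshold}")
            if r.direction not in ("minimum", "limit"):
                rep.add(r.nutrient, "direction-valid", f"direction {r.direction!r}")
    return rep


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

TABLE_FILES = {
    "composition": "composition.csv",
    "footprints": "footprints.csv",
    "prices": "prices.csv",
    "waste": "waste.csv",
    "recommendations": "recommendations.csv",
}


def _sniff_sep(path: Path) -> str:
    """Comma or tab, decided from the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_table(path: Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"input table not found: {path}")
    # round_trip parsing: pandas' default float reader can be off by one ulp
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip", encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing required column(s): {missing}")


def _triplet_from_row(row: Mapping, base: str, table: str, per_100g: bool = False) -> Triplet | None:
    """Assemble a triplet from ``base_q25/_median/_q75`` columns.

    Falls back to a degenerate triplet when only ``base`` or ``base_median``
    is present; returns None when the quantity is absent entirely.
    """
    factor = 10.0 if per_100g else 1.0  # per-100g inputs -> per-kg
    cols = [f"{base}_{q}" for q in QUANTILES]
    if all(c in row for c in cols):
        vals = [row[c] for c in cols]
        if any(pd.isna(v) for v in vals):
            return None
        return Triplet(*(float(v) * factor for v in vals))
    for c in (f"{base}_median", base):
        if c in row and not pd.isna(row[c]):
            return Triplet.point(float(row[c]) * factor)
    return None


def read_food_database(
    source: str | Path | Mapping[str, str | Path],
    config: str | Path | Mapping | None = None,
) -> FoodDatabase:
    """Read a food database from a directory of tables (or a path mapping).

    *source* is either a directory containing ``composition.csv``,
    ``footprints.csv``, ``prices.csv``, ``waste.csv`` and (optionally)
    ``recommendations.csv``, or a mapping from those table names to paths.
    *config* optionally remaps external column names to the internal schema,
    as ``{table_name: {external_column: internal_column}}`` (dict or YAML
    file); ``{table_name: {"per_100g": true}}`` declares composition inputs
    on a per-100 g basis.

    The returned database is fully validated; violations raise
    :class:`~dietshift.errors.ValidationFailed`.
    """
    if isinstance(source, (str, Path)):
        root = Path(source)
        paths = {k: root / v for k, v in TABLE_FILES.items()}
    else:
        paths = {k: Path(v) for k, v in source.items()}

    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
    config = dict(config or {})

    def colmap(table: str) -> dict[str, str]:
        sub = dict(config.get(table, {}) or {})
        sub.pop("per_100g", None)
        return sub

    comp = _read_table(paths["composition"], colmap("composition"))
    _require_columns(comp, ["item_id", "group", "energy_density_kcal_100g"], "composition")
    foot = _read_table(paths["footprints"], colmap("footprints"))
    _require_columns(foot, ["item_id"], "footprints")
    prices = _read_table(paths["prices"], colmap("prices"))
    _require_columns(prices, ["item_id"], "prices")
    waste = _read_table(paths["waste"], colmap("waste"))
    _require_columns(waste, ["group", "waste_fraction"], "waste")

    per_100g = bool(config.get("composition", {}).get("per_100g", False))
    waste_by_group = dict(zip(waste["group"].astype(str), waste["waste_fraction"].astype(float)))
    foot_by_id = {str(r["item_id"]): r for r in foot.to_dict("records")}
    price_by_id = {str(r["item_id"]): r for r in prices.to_dict("records")}

    nutrient_bases = sorted(
        {
            c.rsplit("_", 1)[0] if c.rsplit("_", 1)[-1] in QUANTILES else c
            for c in comp.columns
            if c
            not in (
                "item_id",
                "group",
                "energy_density_kcal_100g",
                "share_within_group",
                "fortified_with",
            )
        }
    )

    items: list[FoodItem] = []
    for row in comp.to_dict("records"):
        item_id = str(row["item_id"])
        group = str(row["group"])
        nutrients: dict[str, Triplet] = {}
        for base in nutrient_bases:
            t = _triplet_from_row(row, base, "composition", per_100g=per_100g)
            if t is not None:
                nutrients[base] = t
        frow = foot_by_id.get(item_id, {})
        footprints: dict[str, Triplet] = {}
        for ind in INDICATORS:
            t = _triplet_from_row(frow, ind, "footprints")
            if t is not None:
                footprints[ind] = t
        prow = price_by_id.get(item_id, {})
        price = _triplet_from_row(prow, "price", "prices") or Triplet.point(0.0)
        fortified = row.get("fortified_with", "")
        fortified = "" if pd.isna(fortified) else str(fortified)
        share = row.get("share_within_group", float("nan"))
        items.append(
            FoodItem(
                id=item_id,
                group=group,
                energy_density=float(row["energy_density_kcal_100g"]),
                nutrients=nutrients,
                footprints=footprints,
                price=price,
                waste_fraction=float(waste_by_group.get(group, 0.0)),
                share_within_group=float(share) if not pd.isna(share) else float("nan"),
                fortified_with=frozenset(x for x in fortified.split(";") if x),
            )
        )

    # items without an explicit share get an equal split of the remainder
    for group in sorted({it.group for it in items}):
        grp = [it for it in items if it.group == group]
        missing = [it for it in grp if math.isnan(it.share_within_group)]
        if missing:
            assigned = sum(it.share_within_group for it in grp if not math.isnan(it.share_within_group))
            rest = max(0.0, 1.0 - assigned)
            for it in missing:
                it.share_within_group = rest / len(missing)

    recs = None
    rec_path = paths.get("recommendations")
    if rec_path is not None and Path(rec_path).exists():
        recs = RecommendationTable.from_frame(_read_table(Path(rec_path), colmap("recommendations")))

    db = FoodDatabase(items=items, recommendations=recs)
    report = validate_database(db)
    if not report.ok:
        raise ValidationFailed(report.issues)
    return db


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _sorted_items(db: FoodDatabase) -> list[FoodItem]:
    return sorted(db.items, key=lambda it: (GROUP_ORDER.get(it.group, 99), it.id))


def write_food_database(db: FoodDatabase, directory: str | Path) -> dict[str, Path]:
    """Write the database back out in the canonical table schema.

    Deterministic row and column order, so write -> read -> write round-trips
    bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    items = _sorted_items(db)
    nutrient_names = db.nutrient_names

    comp_rows = []
    for it in items:
        row: dict = {
            "item_id": it.id,
            "group": it.group,
            "share_within_group": it.share_within_group,
            "energy_density_kcal_100g": it.energy_density,
            "fortified_with": ";".join(sorted(it.fortified_with)),
        }
        for n in nutrient_names:
            t = it.nutrients.get(n, Triplet.point(0.0))
            for q in QUANTILES:
                row[f"{n}_{q}"] = t.at(q)
        comp_rows.append(row)
    paths = {"composition": directory / TABLE_FILES["composition"]}
    pd.DataFrame(comp_rows).to_csv(paths["composition"], index=False)

    foot_rows = []
    for it in items:
        row = {"item_id": it.id}
        for ind in INDICATORS:
            t = it.footprints.get(ind, Triplet.point(0.0))
            for q in QUANTILES:
                row[f"{ind}_{q}"] = t.at(q)
        foot_rows.append(row)
    paths["footprints"] = directory / TABLE_FILES["footprints"]
    pd.DataFrame(foot_rows).to_csv(paths["footprints"], index=False)

    price_rows = [
        {"item_id": it.id, **{f"price_{q}": it.price.at(q) for q in QUANTILES}} for it in items
    ]
    paths["prices"] = directory / TABLE_FILES["prices"]
    pd.DataFrame(price_rows).to_csv(paths["prices"], index=False)

    # waste is a group-level input; items carry it uniformly, so the first
    # item's value is the group's (exact, no re-averaging on round-trip)
    waste_rows = [
        {"group": g, "waste_fraction": db.items_in_group(g)[0].waste_fraction}
        for g in db.groups_present
    ]
    paths["waste"] = directory / TABLE_FILES["waste"]
    pd.DataFrame(waste_rows).to_csv(paths["waste"], index=False)

    if db.recommendations is not None:
        paths["recommendations"] = directory / TABLE_FILES["recommendations"]
        db.recommendations.to_frame().to_csv(paths["recommendations"], index=False)
    return paths


def _round_sig(value, digits: int = 6):
    if isinstance(value, float):
        if math.isnan(value) or math.isinf(value):
            return value
        return float(f"{value:.{digits}g}")
    return value


def write_results(results, path: str | Path, format: str = "csv") -> Path:
    """Serialize a result object (DataFrame or anything with ``to_frame`` /
    ``to_payload``) to CSV or JSON at 6 significant digits, with a
    deterministic column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")

    if format == "json" and hasattr(results, "to_payload"):
        payload = _round_payload(results.to_payload())
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return path

    if hasattr(results, "to_frame"):
        frame = results.to_frame()
    elif isinstance(results, pd.DataFrame):
        frame = results
    else:
        raise TypeError(f"cannot serialize results of type {type(results).__name__}")
    frame = frame.copy()
    for col in frame.columns:
        if pd.api.types.is_float_dtype(frame[col]):
            frame[col] = frame[col].map(_round_sig)
    if format == "csv":
        frame.to_csv(path, index=False)
    else:
        payload = _round_payload(frame.to_dict("records"))
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _round_payload(obj):
    if isinstance(obj, dict):
        return {k: _round_payload(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_payload(v) for v in obj]
    return _round_sig(obj)
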