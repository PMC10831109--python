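"""Environmental footprint and daily expenditure accounting.

Footprint totals per indicator (GHGe kg CO2e, cropland m2, blue freshwater
L per person-day) and daily cost are linear in the diet:

    total = sum_items kg_i x intensity_i(quantile)

with per-group contributions and shares. The intensities are
cradle-to-consumer life-cycle values carried in the database; freshwater is
consumptive blue water only. Quantile triplets propagate by evaluating the
same sums at the Q25 / median / Q75 intensity tables (a bound on the
spread, not a sampled confidence interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import CoverageError, DataError
from .scenarios import DietProfile, energy_of, item_masses_kg
from .tables import INDICATORS, QUANTILES, FoodDatabase, Triplet
from .taxonomy import ASF_GROUPS, GROUP_ORDER


@dataclass
class ImpactResult:
    """Totals, per-group contributions and shares for one diet.

    ``shares_defined`` is False for an empty diet (zero totals), in which
    case the share columns are NaN.
    """

    scenario: str
    quantile: str
    totals: dict[str, float]
    contributions: pd.DataFrame  # columns: group, <indicator>...
    shares_defined: bool = True

    def group_share(self, group: str, indicator: str) -> float:
        total = self.totals[indicator]
        if total <= 0:
            return float("nan")
        sub = self.contributions.loc[self.contributions["group"] == group, indicator]
        return float(sub.iloc[0]) / total if len(sub) else 0.0

    def shares(self) -> pd.DataFrame:
        out = self.contributions.copy()
        for ind in INDICATORS:
            total = self.totals.get(ind, 0.0)
            out[ind] = out[ind] / total if total > 0 else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        out = self.contributions.copy()
        shares = self.shares()
        for ind in INDICATORS:
            out = out.rename(columns={ind: f"{ind}_total"})
            out[f"{ind}_share"] = shares[ind]
        out.insert(0, "scenario", self.scenario)
        out.insert(1, "quantile", self.quantile)
        return out

    def to_payload(self) -> dict:
        return {
            "scenario": self.scenario,
            "quantile": self.quantile,
            "totals": dict(self.totals),
            "contributions": self.contributions.to_dict("records"),
            "shares": self.shares().to_dict("records"),
            "shares_defined": self.shares_defined,
        }


def total_impact(diet: DietProfile, db: FoodDatabase, quantile: str = "median") -> ImpactResult:
    """Footprint totals with per-group contribution breakdown."""
    masses = item_masses_kg(diet, db)
    contrib: dict[str, dict[str, float]] = {}
    for item_id, kg in masses.items():
        item = db.item(item_id)
        for ind in INDICATORS:
            if ind not in item.footprints:
                raise CoverageError(f"item {item_id!r} lacks intensity for indicator {ind!r}")
            contrib.setdefault(item.group, dict.fromkeys(INDICATORS, 0.0))
            contrib[item.group][ind] += kg * item.footprints[ind].at(quantile)
    groups = sorted(contrib, key=lambda g: GROUP_ORDER.get(g, 99))
    rows = [{"group": g, **contrib[g]} for g in groups]
    frame = pd.DataFrame(rows, columns=["group", *INDICATORS])
    totals = {ind: float(frame[ind].sum()) if len(frame) else 0.0 for ind in INDICATORS}
    return ImpactResult(
        scenario=diet.name,
        quantile=quantile,
        totals=totals,
        contributions=frame,
        shares_defined=any(v > 0 for v in totals.values()),
    )


def percent_change(value: float, baseline: float) -> float:
    """Signed percent change vs baseline (-50.0 means a 50% reduction)."""
    if baseline <= 0:
        raise DataError(f"baseline must be positive, got {baseline}")
    return 100.0 * (value - baseline) / baseline


def asf_energy_share(diet: DietProfile, db: FoodDatabase) -> float:
    """Fraction of total dietary energy supplied by animal-source groups."""
    total, per_group = energy_of(diet, db)
    if total <= 0:
        raise DataError("zero total energy; ASF energy share undefined")
    return sum(v for g, v in per_group.items() if g in ASF_GROUPS) / total


@dataclass
class ExpenditureResult:
    """Daily food cost with its Q25/median/Q75 spread.

    ``group_costs``/``group_shares`` break the median-quantile cost down by
    food group; the triplet ``cost`` evaluates the whole basket at each
    price quantile.
    """

    scenario: str
    cost: Triplet  # currency/day at q25, median, q75
    group_costs: dict[str, float]
    aggregation: str = "group"

    @property
    def group_shares(self) -> dict[str, float]:
        total = sum(self.group_costs.values())
        if total <= 0:
            return {g: float("nan") for g in self.group_costs}
        return {g: c / total for g, c in self.group_costs.items()}

    def to_frame(self) -> pd.DataFrame:
        shares = self.group_shares
        rows = [
            {
                "scenario": self.scenario,
                "group": g,
                "cost_median": self.group_costs[g],
                "cost_share": shares[g],
            }
            for g in sorted(self.group_costs, key=lambda g: GROUP_ORDER.get(g, 99))
        ]
        return pd.DataFrame(rows)

    def to_payload(self) -> dict:
        return {
            "scenario": self.scenario,
            "cost": {q: self.cost.at(q) for q in QUANTILES},
            "group_costs": dict(self.group_costs),
            "group_shares": self.group_shares,
            "aggregation": self.aggregation,
        }


def _group_unit_price(db: FoodDatabase, group: str, quantile: str) -> float:
    """Share-weighted group price per kg at the given quantile."""
    items = db.items_in_group(group)
    if not items:
        raise CoverageError(f"no priced items in group {group!r}")
    wsum = sum(it.share_within_group for it in items)
    return sum(it.share_within_group * it.price.at(quantile) for it in items) / wsum


def daily_expenditure(
    diet: DietProfile, db: FoodDatabase, aggregation: str = "group"
) -> ExpenditureResult:
    """Daily cost of a diet, currency per person-day.

    ``aggregation="group"`` (default) prices each group at its pooled
    share-weighted percentile unit price and multiplies by the group mass;
    ``"item"`` sums item-by-item. The two coincide when the item split
    follows the database shares and differ only for explicit item-level
    profiles (e.g. conscious-consumer reallocations).
    """
    if aggregation not in ("group", "item"):
        raise DataError(f"aggregation must be 'group' or 'item', got {aggregation!r}")
    costs: dict[str, float] = {}
    group_costs: dict[str, float] = {}
    if aggregation == "group" and diet.item_amounts is None:
        for q in QUANTILES:
            costs[q] = sum(
                (grams / 1000.0) * _group_unit_price(db, g, q)
                for g, grams in diet.amounts.items()
                if grams > 0
            )
        group_costs = {
            g: (grams / 1000.0) * _group_unit_price(db, g, "median")
            for g, grams in diet.amounts.items()
            if grams > 0
        }
    else:
        masses = item_masses_kg(diet, db)
        for q in QUANTILES:
            costs[q] = sum(kg * db.item(i).price.at(q) for i, kg in masses.items())
        for i, kg in masses.items():
            item = db.item(i)
            group_costs[item.group] = group_costs.get(item.group, 0.0) + kg * item.price.median
    return ExpenditureResult(
        scenario=diet.name,
        cost=Triplet(costs["q25"], costs["median"], costs["q75"]),
        group_costs=group_costs,
        aggregation=aggregation,
    )


# ---------------------------------------------------------------------------
# multi-scenario reports
# ---------------------------------------------------------------------------


def impact_report(
    scenarios: Mapping[str, DietProfile],
    db: FoodDatabase,
    quantile: str = "median",
    baseline: str = "BAU",
) -> pd.DataFrame:
    """Totals per scenario x indicator with percent change vs baseline."""
    results = {name: total_impact(prof, db, quantile) for name, prof in scenarios.items()}
    base = results.get(baseline)
    rows = []
    for name, res in results.items():
        for ind, unit in INDICATORS.items():
            pct = (
                percent_change(res.totals[ind], base.totals[ind])
                if base is not None and base.totals[ind] > 0 and name != baseline
                else (0.0 if name == baseline else float("nan"))
            )
            rows.append(
                {
                    "scenario": name,
                    "quantile": quantile,
                    "indicator": ind,
                    "unit": f"{unit}/day",
                    "total": res.totals[ind],
                    "pct_change_vs_bau": pct,
                }
            )
    return pd.DataFrame(rows)


def expenditure_report(
    scenarios: Mapping[str, DietProfile],
    db: FoodDatabase,
    baseline: str = "BAU",
    aggregation: str = "group",
) -> pd.DataFrame:
    """Daily cost per scenario at each quantile, with change vs baseline."""
    results = {n: daily_expenditure(p, db, aggregation) for n, p in scenarios.items()}
    base = results.get(baseline)
    rows = []
    for name, res in results.items():
        pct = (
            percent_change(res.cost.median, base.cost.median)
            if base is not None and base.cost.median > 0 and name != baseline
            else (0.0 if name == baseline else float("nan"))
        )
        rows.append(
            {
                "scenario": name,
                "cost_q25": res.cost.q25,
                "cost_median": res.cost.median,
                "cost_q75": res.cost.q75,
                "pct_change_vs_bau": pct,
            }
        )
    return pd.DataFrame(rows)
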