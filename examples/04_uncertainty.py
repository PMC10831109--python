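"""Uncertainty analyses: quantile sweep, functional-unit comparison and the
conscious-consumer bound.

The sweep recomputes each total at the Q25 / median / Q75 of every input
table; the functional-unit comparison contrasts mass- vs energy-equivalent
replacement; the conscious consumer moves each group's amount onto its
single cheapest (or lowest-emission) item, bounding what deliberate
in-store choices could achieve without changing the diet's composition.
"""

import dietshift as ds

spec = ds.SyntheticSpec(seed=42)
db = ds.generate_database(spec)
bau = ds.apply_waste(ds.generate_bau_supply(spec, db), db)
mass = ds.build_scenarios(bau, ds.builtin_scenarios("mass"), db)
energy = ds.build_scenarios(bau, ds.builtin_scenarios("energy"), db)

sweep = ds.quantile_sweep(mass, db, include_nutrients=False)
ghge = sweep[sweep["metric"] == "ghge"].pivot_table(
    index="scenario", columns="quantile", values="value"
)
print("GHGe kg CO2e/day by data quantile:")
for scen, row in ghge.iterrows():
    print(f"  {scen:<10} {row['q25']:.2f} <= {row['median']:.2f} <= {row['q75']:.2f}")

med = lambda s: s[s["quantile"] == "median"][["scenario", "metric", "value"]]
fu = ds.functional_unit_comparison(
    med(sweep), med(ds.quantile_sweep(energy, db, include_nutrients=False))
)
fu_ghge = fu[fu["metric"] == "ghge"].set_index("scenario")
print("\nenergy-basis GHGe relative to mass basis (ratio > 1 = higher):")
for scen, row in fu_ghge.iterrows():
    print(f"  {scen:<10} x{row['ratio']:.3f}")

cheap = ds.conscious_consumer(mass["BAU"], db, "min_cost")
green = ds.conscious_consumer(mass["BAU"], db, "min_ghge")
base = ds.daily_expenditure(mass["BAU"], db, aggregation="item")
print(
    f"\nconscious consumer on the baseline: cost "
    f"{base.cost.median:.0f} -> {ds.daily_expenditure(cheap, db, aggregation='item').cost.median:.0f} SEK/day (cheapest items), "
    f"GHGe {ds.total_impact(mass['BAU'], db).totals['ghge']:.2f} -> "
    f"{ds.total_impact(green, db).totals['ghge']:.2f} kg/day (lowest-emission items)."
)
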