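# dietshift

Diet-scenario sustainability modelling: what happens to nutrient adequacy,
environmental footprints and daily food expenditure when animal-source
foods (ASFs) in a national average diet are replaced by plant-based
alternatives (PBAs) or whole foods (WFs)?

`dietshift` is a library for food-systems and nutrition researchers who
want to build such replacement scenarios reproducibly. Starting from a
per-capita baseline supply (g/person/day per food group), it:

1. converts supply to consumption with household loss/waste fractions,
2. constructs vegan (VGN), vegetarian (VGT) and flexitarian (FLX)
   scenarios, each with a PBA or WHOLE replacement variant, under two
   functional units — **mass** (replacement grams = removed grams) and
   **energy** (replacement grams chosen so added kcal = removed kcal),
3. scores every scenario against daily nutrient recommendations,
4. computes footprint totals (GHGe in kg CO₂e, cropland in m², blue
   freshwater in L, per person-day) and daily cost with food-group
   contribution breakdowns, and
5. bounds the results with quantile sweeps, a functional-unit comparison
   and a "conscious consumer" within-group reallocation.

## Model

All accounting is linear in the diet. For a consumption-stage diet with
item masses $m_i$ (kg/day):

- **nutrients:** $S_n = \sum_i m_i \, c_{n,i}(q)$, where $c_{n,i}$ is the
  content of nutrient $n$ per kg of item $i$ at data quantile
  $q \in \{Q25, \text{median}, Q75\}$;
- **adequacy score:** $z_n = S_n / T_n - 1$ against threshold $T_n$;
  0 marks the recommended daily level, "minimum" nutrients pass at
  $z \ge 0$, nutrients to limit (sodium, saturated fat) at $z \le 0$;
- **footprints / cost:** $X = \sum_i m_i \, x_i(q)$ for cradle-to-consumer
  intensity or retail price $x_i$ per kg, with per-group contributions and
  shares;
- **substitution:** per removed group $g$, $r_g = f \cdot \text{BAU}_g$
  grams leave the diet ($f = 1$ vegan/vegetarian, $0.5$ flexitarian) and
  the equivalent amount (grams, or kcal via group energy densities) is
  allocated over replacement targets by configurable weights, respecting
  per-group caps (EAT-Lancet-style upper reference values) with
  deterministic overflow.

A seeded synthetic data module generates food databases with the
structure this analysis assumes (ASF ≫ PBA ≫ WF footprints, fortified and
salty PBAs, right-skewed prices, zero baseline PBA/legume consumption), so
the whole pipeline runs and is tested without any external data. A
canonical scenario table ships with the package and anchors the
substitution rules exactly.

## Worked example

```python
import dietshift as ds

spec = ds.SyntheticSpec(seed=42)
db = ds.generate_database(spec)
bau = ds.apply_waste(ds.generate_bau_supply(spec, db), db)
scenarios = ds.build_scenarios(bau, ds.builtin_scenarios("mass"), db)

ghge_bau = ds.total_impact(scenarios["BAU"], db).totals["ghge"]
for name, prof in scenarios.items():
    tot = ds.total_impact(prof, db).totals["ghge"]
    exp = ds.daily_expenditure(prof, db)
    print(f"{name:<10}{tot:>6.2f} kg CO2e/d {ds.percent_change(tot, ghge_bau):>+7.1f}%"
          f"  {exp.cost.median:>5.1f} SEK/d")
```

prints (seed 42):

```
BAU         5.23 kg CO2e/d    +0.0%   63.9 SEK/d
VGNPBA      2.04 kg CO2e/d   -61.0%   63.7 SEK/d
VGNWHOLE    1.64 kg CO2e/d   -68.6%   50.7 SEK/d
VGTPBA      2.23 kg CO2e/d   -57.4%   61.9 SEK/d
VGTWHOLE    1.81 kg CO2e/d   -65.3%   46.4 SEK/d
FLXPBA      3.63 kg CO2e/d   -30.5%   63.8 SEK/d
FLXWHOLE    3.43 kg CO2e/d   -34.4%   56.8 SEK/d
```

Every replacement scenario cuts emissions relative to the baseline
because ASF intensities dominate those of their replacements in the
synthetic world; PBA diets cost about the same as the baseline while
whole-food diets come out cheaper. The `examples/` directory has one
short narrative script per capability (scenario construction, nutrient
adequacy, footprints and cost, uncertainty analyses); each prints its
numbers with a line on what they mean. A thin CLI mirrors the stages:

```sh
dietshift synth --seed 1 --out tables/       # emit a synthetic table set
dietshift run-all --seed 1 --out results/    # full pipeline + manifest
```

Real analyses replace the synthetic tables with CSV/TSV inputs in the
same schema (`composition.csv`, `footprints.csv`, `prices.csv`,
`waste.csv`, `recommendations.csv`, `bau_supply.csv`); a YAML config can
remap column names. See `docs/methods.md` for the model's assumptions,
parameters and limitations.

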