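# Methods

## Scope and model

`dietshift` models population-average diet change as bookkeeping over
food groups: a baseline per-capita supply (g/person/day for 17 food
groups: four animal-source groups, four plant-based-alternative groups,
and whole-food/other groups) is waste-adjusted to consumption, transformed
by declarative substitution rules into replacement scenarios, and paired
with per-kg composition, footprint-intensity and price tables to yield
per-day nutrient supplies, environmental totals and costs. Everything
downstream of substitution is linear in the diet, which is what makes the
brute-force oracles in the test suite exact.

Assumptions inherited from this design:

- **Group-level resolution.** Scenarios move grams between food groups;
  items matter only through their within-group mass shares (and through
  the conscious-consumer reallocation, which pins an explicit item split).
- **Population averages.** No stratification by sex, age or income; the
  recommendation table carries one threshold per nutrient, the most
  stringent across sexes for minimum-type rows (asserted at load).
- **Static data.** Footprint intensities are cradle-to-consumer
  life-cycle values (consumer cooking included) taken as given; freshwater
  is consumptive blue water only. Prices are point-in-time retail values;
  no inflation adjustment or currency conversion.
- **1 litre ≡ 1 kg** for beverages, so dairy/plant-drink rows mix with
  solid foods in one mass accounting.

## Scenario construction

Six scenarios derive from the baseline (BAU): vegan (VGN, all four ASF
groups removed), vegetarian (VGT, meats and seafood removed, eggs and
dairy retained) and flexitarian (FLX, every ASF group halved), each with
a PBA variant and a WHOLE variant. Reduction fractions are exactly 1
(VGN/VGT) and 0.5 (FLX), so halving and zeroing are bit-exact.

**Replacement maps.** The PBA variant routes each removed group to the
alternative that mimics it (meats → PB meat, dairy → PB dairy, seafood →
PB seafood); removed eggs route to PB meat, the only alternative
available, which reproduces the canonical scenario table's PB-meat cells
(220 g vegan = 190 meats + 30 eggs). Snacks swap to plant-based snacks in
the vegan and flexitarian scenarios but not the vegetarian ones, again
following the canonical table. The WHOLE variant redistributes removed
grams over {vegetables, fruits, grains, plant fats, legumes, nuts} with
per-scenario weights seeded from the canonical table's group increments
over BAU; the weights are configuration, not algorithm, and can be
replaced wholesale through `ScenarioSpec`.

**Functional units.** On the mass basis, added grams equal removed grams
(conservation is exact when no cap binds). On the energy basis, the
removed kcal (grams × share-weighted group energy density) are added
instead, with target grams = kcal / target density; kcal conservation
holds to 1e-6 relative. Because PBA energy densities sit below their ASF
counterparts, energy-basis scenarios add more replacement grams and
generally carry slightly higher footprints — the pattern the
functional-unit comparison quantifies.

**Caps and overflow.** Whole-food targets respect per-group caps
(defaults: vegetables 600, fruits 300, grains 350, legumes 150, nuts 75,
plant fats 80 g/day — upper-reference-value magnitudes for a healthy
reference diet). A capped target's residual reallocates to the remaining
targets in descending-weight order with lexicographic tie-break; the
procedure is a deterministic waterfill, and if every target caps out the
residual raises an `InfeasibleSubstitution` error carrying the
unallocated grams/kcal. Allocation tolerance is 1e-9 in the functional
unit.

**Canonical table.** The package ships a 17-group × 7-scenario × 2-basis
scenario table as a CSV fixture. Its mass rows are gram amounts; its
"energy-unit" rows are reproduced as printed but are ambiguous for the
baseline (they equal kcal contents, e.g. meats 333 kcal = 190 g ×
1.75 kcal/g), so the loader tags them `basis="energy"` without
reinterpretation and nothing rule-based is anchored on them. Only the
unambiguous ASF cells (halving, zeroing, retention) are treated as exact
anchors, and the rule engine reproduces them bit-exactly.

**Order of operations.** Waste adjustment precedes substitution:
scenarios are consumption-stage diets, and the baseline supply defaults
(meats 190 g, eggs 30, dairy 400, seafood 30, …) enter as supply-stage
amounts.

## Adequacy scoring

Score = supply/threshold − 1; 0 is the recommended level. The relative
deviation is the simplest transform consistent with centring the
recommendation at zero, and it makes "meets" equivalent to a sign test
(≥ 0 for minimum-type nutrients, ≤ 0 for sodium and saturated fat).
Energy is reported in the sweep but never scored. Thresholds must be
positive; a nutrient recommended but absent from the composition table is
a coverage error, not a silent zero.

## Footprints and cost

Totals, per-group contributions and shares are plain weighted sums;
shares are undefined (NaN, flagged) for an empty diet. Quantile triplets
propagate by evaluating the same sums at the Q25/median/Q75 input tables
— a bound on the spread under perfectly correlated item-level deviations,
not a sampled confidence interval.

Group cost aggregation is an open choice: pooling items into a group
percentile price before multiplying by group mass ("group", default) or
summing item-by-item ("item"). Both are implemented; they coincide
exactly when the item split follows the database shares (the group unit
price is the share-weighted mean of item prices, so the sums are equal
term by term) and differ only for explicit item-level profiles such as
conscious-consumer reallocations.

## Uncertainty analyses

- **Quantile sweep:** every metric recomputed at each quantile; the
  output cube records the quantile used. Degenerate databases (Q25 =
  median = Q75 everywhere) produce a warning, not an error.
- **Functional-unit comparison:** per-scenario ratio of energy-basis to
  mass-basis totals, flagging scenarios where the energy basis comes out
  lower.
- **Conscious consumer:** within each group, the whole group amount moves
  to the single item optimal for the objective (`min_cost`, `min_ghge`,
  `min_lu`, `min_wu`, `max_<nutrient>`, …) at the stated quantile, ties
  broken by item id. Group totals never change, so the result isolates
  within-group choice. Single-best-item reallocation was chosen over
  weighted reallocation as the cleaner bound; a weighted variant can be
  expressed by setting `item_amounts` directly.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any real
inventory:

- group-median footprints with ASF ≫ PBA ≫ WF ordering (meats 20 kg
  CO₂e/kg vs PB meat 3 vs legumes 0.9; overridable per indicator/group);
- PBAs fortified with B12 (+4 µg/kg), vitamin D (+15 µg/kg), calcium
  (+1200 mg/kg) and iron (+10 mg/kg), and saltier than the conventional
  group they mimic (sodium uplift ×1.3 by default); plant items have zero
  intrinsic B12 and vitamin D;
- log-normal within-group dispersion: item medians jitter around group
  medians (log-sd 0.18), and each item's Q25/Q75 derive from a log-normal
  with log-sd 0.35 (footprints), 0.3 (nutrients) and 0.5 (prices), giving
  ordered, right-skewed triplets (Q75 − median > median − Q25);
- energy densities jittered around group defaults implied by per-capita
  supply and energy statistics (meats 1.75, dairy 1.1, grains 2.94
  kcal/g, …), clipped to the physiologic 0.1–9 kcal/g range, with PBA
  densities below their ASF counterparts;
- baseline supply fixed at the canonical group totals with zero PBAs,
  legumes and soy foods; within-group item shares are Dirichlet-drawn,
  seed-fixed;
- group waste fractions at household loss/waste magnitudes (5–20%,
  highest for fresh produce);
- recommendation thresholds are synthetic placeholders at
  Nordic-recommendation magnitudes, flagged as such in `source_note` and
  overridable from file (overrides replace only the nutrients they list).

All outputs are pure functions of `(spec, seed)`; equal seeds produce
byte-identical table sets.

What the generator does **not** emulate: real item-level correlations
between price, nutrition and footprint; seasonal/regional price
structure; the actual national composition database; bioavailability of
fortified nutrients. Passing tests therefore demonstrate that the
machinery is correct and that the qualitative structure (every scenario
below baseline GHGe, fortification-driven adequacy differences,
PBA sodium increases) emerges from the assumed orderings — not that the
synthetic magnitudes match any real country's.

## Numerical choices

- Substitution allocation tolerance 1e-9; mass conservation exact to
  floating arithmetic, energy conservation to 1e-6 relative.
- Share sums asserted to 1e-6 (validation) and 1e-9 (in-memory results);
  result files serialize at 6 significant digits.
- CSV reading uses round-trip float parsing (pandas' default fast parser
  can be off by one ulp, which would break write→read→write identity).
- Deterministic orderings throughout: groups in canonical table order,
  items by id, overflow by descending weight then name — no dependence on
  dict iteration or RNG state outside the seeded generator.
- Degenerate inputs: empty diets give zero totals with flagged undefined
  shares; zero baseline supply makes percent-change undefined (error for
  scalar calls, NaN in reports); waste ≥ 1, nonpositive thresholds and
  zero-density energy targets are hard errors.

## Problem sizes

The shipped tests and the acceptance script run the default synthetic
world — 3 items per group (51 items), 16 nutrients, 7 scenarios × 2
functional units — and 20 seeds for the dominance property; the whole
suite completes in a few seconds. Larger databases are generated by
raising `items_per_group`; all accounting is vectorised over items and
scales linearly.

## Known limitations

- No diet optimisation (least-cost/least-impact), no bioavailability or
  protein-quality modelling, no health-outcome or acceptance modelling.
- Footprint indicators limited to GHGe, cropland and blue freshwater.
- The quantile sweep assumes perfectly correlated deviations across
  items; true uncertainty propagation would need item-level
  distributions and correlations the input tables do not carry.
- Whole-food replacement weights are configuration seeded from one
  published scenario set; they are not derived from nutritional
  optimisation and other choices are equally defensible.
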