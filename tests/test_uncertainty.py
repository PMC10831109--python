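"""Quantile sweeps, conscious-consumer reallocation, functional-unit
comparison and full-pipeline determinism."""

import itertools
import json

import pandas as pd
import pytest

import dietshift as ds
from dietshift.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="module")
def sweep(db, mass_profiles):
    return ds.quantile_sweep(mass_profiles, db)


def test_sweep_cardinality(sweep, db, mass_profiles):
    n_metrics = len(ds.INDICATORS) + 2 + len(db.nutrient_names)  # + cost, energy
    assert len(sweep) == len(mass_profiles) * 3 * n_metrics
    assert set(sweep["quantile"]) == set(ds.QUANTILES)


def test_sweep_values_monotone_across_quantiles(sweep):
    monotone_metrics = [m for m in sweep["metric"].unique() if m != "energy_kcal"]
    wide = sweep.pivot_table(
        index=["scenario", "metric"], columns="quantile", values="value"
    ).reset_index()
    wide = wide[wide["metric"].isin(monotone_metrics)]
    assert (wide["q25"] <= wide["median"] + 1e-12).all()
    assert (wide["median"] <= wide["q75"] + 1e-12).all()


def test_degenerate_quantiles_warn_and_collapse(toy_db):
    for it in toy_db.items:
        it.price = ds.Triplet.point(it.price.median)
        it.nutrients = {k: ds.Triplet.point(t.median) for k, t in it.nutrients.items()}
        it.footprints = {k: ds.Triplet.point(t.median) for k, t in it.footprints.items()}
    diet = {"BAU": ds.DietProfile(amounts={"Meats": 100.0}, name="BAU")}
    with pytest.warns(UserWarning, match="degenerate"):
        cube = ds.quantile_sweep(diet, toy_db)
    wide = cube.pivot_table(index="metric", columns="quantile", values="value")
    assert (wide["q25"] == wide["q75"]).all()


def test_conscious_consumer_picks_cheapest_item(toy_db):
    diet = ds.DietProfile(amounts={"Meats": 100.0}, name="d")
    out = ds.conscious_consumer(diet, toy_db, "min_cost")
    assert out.item_amounts == {"m1": 100.0}  # 40/kg beats 100/kg
    assert out.amounts == diet.amounts  # group totals unchanged


def test_conscious_consumer_single_item_groups_unchanged(toy_db):
    diet = ds.DietProfile(amounts={"Legumes": 120.0}, name="d")
    out = ds.conscious_consumer(diet, toy_db, "min_ghge")
    assert out.item_amounts == {"l1": 120.0}


def test_conscious_consumer_objective_without_attribute_errors(toy_db):
    diet = ds.DietProfile(amounts={"Meats": 100.0})
    with pytest.raises(ds.CoverageError):
        ds.conscious_consumer(diet, toy_db, "min_caffeine")


def test_min_ghge_beats_every_exhaustive_single_item_allocation(db, bau_consumption):
    """Optimal within-group choice <= any alternative, by enumeration."""
    best = ds.conscious_consumer(bau_consumption, db, "min_ghge")
    best_total = ds.total_impact(best, db).totals["ghge"]
    for group, grams in bau_consumption.amounts.items():
        if grams == 0:
            continue
        for candidate in db.items_in_group(group):
            alt_items = dict(best.item_amounts)
            # redirect this group's grams onto the candidate item
            for it in db.items_in_group(group):
                alt_items.pop(it.id, None)
            alt_items[candidate.id] = grams
            alt = ds.DietProfile(
                amounts=dict(bau_consumption.amounts), item_amounts=alt_items
            )
            assert best_total <= ds.total_impact(alt, db).totals["ghge"] + 1e-12


def test_max_protein_maximises_supply(db, bau_consumption):
    out = ds.conscious_consumer(bau_consumption, db, "max_protein")
    base = ds.nutrient_supply(bau_consumption, db)["protein"]
    assert ds.nutrient_supply(out, db)["protein"] >= base


def test_functional_unit_comparison_identity():
    frame = pd.DataFrame(
        {"scenario": ["A", "B"], "metric": ["ghge", "ghge"], "value": [2.0, 3.0]}
    )
    out = ds.functional_unit_comparison(frame, frame.copy())
    assert (out["ratio"] == 1.0).all()
    assert not out["energy_below_mass"].any()
    assert len(out) == 2  # one row per scenario x metric


def test_functional_unit_comparison_closed_form():
    """25% more replacement grams on the energy basis -> ratio 1.25."""
    mass = pd.DataFrame({"scenario": ["S"], "metric": ["ghge"], "value": [2.0]})
    energy = pd.DataFrame({"scenario": ["S"], "metric": ["ghge"], "value": [2.5]})
    out = ds.functional_unit_comparison(mass, energy)
    assert out["ratio"].iloc[0] == pytest.approx(1.25)


def test_functional_unit_comparison_rejects_mismatched_scenarios():
    mass = pd.DataFrame({"scenario": ["A"], "metric": ["ghge"], "value": [1.0]})
    energy = pd.DataFrame({"scenario": ["B"], "metric": ["ghge"], "value": [1.0]})
    with pytest.raises(ds.PipelineUsageError):
        ds.functional_unit_comparison(mass, energy)


def test_pipeline_end_to_end_outputs_and_determinism(tmp_path):
    cfg1 = RunConfig(outdir=str(tmp_path / "r1"), seed=13)
    cfg2 = RunConfig(outdir=str(tmp_path / "r2"), seed=13)
    m1 = run_pipeline(cfg1)
    m2 = run_pipeline(cfg2)
    assert m1["config_hash"] == m2["config_hash"]  # outdir excluded from hash
    assert m1["files"] == m2["files"]  # byte-identical outputs
    profiles = pd.read_csv(tmp_path / "r1" / "scenario_profiles.csv")
    assert profiles.groupby(["scenario", "basis"]).ngroups == 14
    for name in ("adequacy_mass.csv", "impact_energy.csv", "expenditure_mass.csv",
                 "sweep_energy.csv", "fu_comparison.csv", "manifest.json"):
        assert (tmp_path / "r1" / name).exists()
    manifest = json.loads((tmp_path / "r1" / "manifest.json").read_text())
    assert set(manifest["files"]) == set(m1["files"])


def test_pipeline_mass_only_skips_energy_outputs(tmp_path):
    cfg = RunConfig(outdir=str(tmp_path), seed=1, bases=("mass",))
    run_pipeline(cfg)
    assert (tmp_path / "impact_mass.csv").exists()
    assert not (tmp_path / "impact_energy.csv").exists()
    assert not (tmp_path / "fu_comparison.csv").exists()
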