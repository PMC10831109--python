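"""Table readers/writers, validation completeness and result exports."""

import dataclasses
import json

import pandas as pd
import pytest

import dietshift as ds
from dietshift.tables import write_food_database


def test_median_only_columns_load_as_degenerate_triplets(tmp_path):
    (tmp_path / "composition.csv").write_text(
        "item_id,group,energy_density_kcal_100g,protein\n"
        "a,Meats,200,80\n"
        "b,Legumes,100,60\n"
    )
    (tmp_path / "footprints.csv").write_text("item_id,ghge\na,10\nb,1\n")
    (tmp_path / "prices.csv").write_text("item_id,price\na,40\nb,30\n")
    (tmp_path / "waste.csv").write_text("group,waste_fraction\nMeats,0.1\nLegumes,0.0\n")
    db = ds.read_food_database(tmp_path)
    assert db.item("a").nutrients["protein"] == ds.Triplet(80, 80, 80)
    assert db.item("a").price.q25 == db.item("a").price.q75 == 40
    assert db.item("a").waste_fraction == pytest.approx(0.1)
    # items without explicit shares split the group equally
    assert db.item("a").share_within_group == 1.0


def test_quantile_ordering_violation_rejected_at_read(tmp_path):
    (tmp_path / "composition.csv").write_text(
        "item_id,group,energy_density_kcal_100g,protein_q25,protein_median,protein_q75\n"
        "a,Meats,200,80,70,90\n"
    )
    (tmp_path / "footprints.csv").write_text("item_id,ghge\na,10\n")
    (tmp_path / "prices.csv").write_text("item_id,price\na,40\n")
    (tmp_path / "waste.csv").write_text("group,waste_fraction\nMeats,0.1\n")
    with pytest.raises(ds.ValidationFailed) as exc:
        ds.read_food_database(tmp_path)
    assert any(i.rule == "quantile-order" and i.item_id == "a" for i in exc.value.issues)


def test_missing_required_column_names_the_column(tmp_path):
    (tmp_path / "composition.csv").write_text("item_id,protein\na,80\n")
    (tmp_path / "footprints.csv").write_text("item_id,ghge\na,10\n")
    (tmp_path / "prices.csv").write_text("item_id,price\na,40\n")
    (tmp_path / "waste.csv").write_text("group,waste_fraction\nMeats,0.1\n")
    with pytest.raises(ds.SchemaError, match="group"):
        ds.read_food_database(tmp_path)


def test_column_remap_config_applies(tmp_path):
    (tmp_path / "composition.csv").write_text(
        "code,category,kcal100,protein\na,Meats,200,80\n"
    )
    (tmp_path / "footprints.csv").write_text("item_id,ghge\na,10\n")
    (tmp_path / "prices.csv").write_text("item_id,price\na,40\n")
    (tmp_path / "waste.csv").write_text("group,waste_fraction\nMeats,0.1\n")
    cfg = {
        "composition": {
            "code": "item_id",
            "category": "group",
            "kcal100": "energy_density_kcal_100g",
        }
    }
    db = ds.read_food_database(tmp_path, config=cfg)
    assert db.item("a").group == "Meats"


def test_synthetic_database_roundtrips_bit_identically(db, tmp_path):
    d1, d2 = tmp_path / "w1", tmp_path / "w2"
    write_food_database(db, d1)
    db2 = ds.read_food_database(d1)
    write_food_database(db2, d2)
    for f in sorted(d1.iterdir()):
        assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name


def test_validation_passes_on_conforming_database(db):
    assert ds.validate_database(db).ok


@pytest.mark.parametrize(
    "mutate, rule",
    [
        (lambda it: setattr(it, "price", ds.Triplet(-5.0, 10.0, 20.0)), "nonnegative-price"),
        (lambda it: setattr(it, "price", ds.Triplet(50.0, 40.0, 60.0)), "quantile-order"),
        (lambda it: setattr(it, "waste_fraction", 1.2), "waste-range"),
        (lambda it: setattr(it, "energy_density", 0.0), "energy-density-positive"),
        (lambda it: setattr(it, "group", "Cheese"), "unknown-group"),
        (
            lambda it: it.nutrients.__setitem__("protein", ds.Triplet(90.0, 80.0, 70.0)),
            "quantile-order",
        ),
        (
            lambda it: it.footprints.__setitem__("ghge", ds.Triplet(-1.0, 1.0, 2.0)),
            "nonnegative-quantity",
        ),
        (lambda it: setattr(it, "share_within_group", it.share_within_group + 0.5), "share-sum"),
    ],
)
def test_each_single_field_violation_is_caught(spec, mutate, rule):
    """Validation is complete: every invariant-breaking mutation is reported."""
    db = ds.generate_database(spec)  # fresh copy, fixtures stay pristine
    victim = db.item("meats_01")
    mutate(victim)
    report = ds.validate_database(db)
    assert rule in report.rules()


def test_pba_item_moved_into_meats_fails_class_consistency(spec):
    """An item flagged PBA cannot sit in an ASF group."""

    class MislabeledItem(ds.FoodItem):
        @property
        def is_pba(self):
            return True

    db = ds.generate_database(spec)
    orig = db.item("meats_01")
    db.items[db.items.index(orig)] = MislabeledItem(**dataclasses.asdict(orig))
    report = ds.validate_database(db)
    assert "class-consistency" in report.rules()


def test_recommendation_threshold_must_be_positive(toy_db):
    toy_db.recommendations = ds.RecommendationTable(
        [ds.Recommendation("protein", -1.0, direction="minimum")]
    )
    assert "threshold-positive" in ds.validate_database(toy_db).rules()


def test_write_results_csv_roundtrip_lossless_at_declared_precision(tmp_path):
    df = pd.DataFrame({"scenario": ["BAU"], "value": [1.23456789]})
    p = ds.write_results(df, tmp_path / "r.csv")
    back = pd.read_csv(p)
    assert back["value"].iloc[0] == pytest.approx(1.23457, rel=1e-6)
    p2 = ds.write_results(back, tmp_path / "r2.csv")
    assert p2.read_bytes() == p.read_bytes()


def test_impact_result_json_shares_sum_to_one(toy_db, tmp_path):
    diet = ds.DietProfile(amounts={"Meats": 300.0, "Legumes": 200.0}, name="toy")
    res = ds.total_impact(diet, toy_db)
    path = ds.write_results(res, tmp_path / "impact.json", format="json")
    payload = json.loads(path.read_text())
    for ind in ds.INDICATORS:
        # exported at 6 significant digits; the in-memory shares sum to 1
        # within 1e-9 (see test_impact.py::test_contributions_sum_to_totals)
        assert sum(r[ind] for r in payload["shares"]) == pytest.approx(1.0, abs=1e-5)


def test_empty_results_export_header_only(tmp_path):
    df = pd.DataFrame(columns=["scenario", "value"])
    p = ds.write_results(df, tmp_path / "empty.csv")
    assert p.read_text().strip() == "scenario,value"
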