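"""Scenario construction: waste, energy accounting, substitution rules."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import dietshift as ds
from dietshift.scenarios import canonical_bau, load_canonical_scenarios
from dietshift.taxonomy import ASF_GROUPS, GROUPS


def _single_item_db(densities: dict, waste: dict | None = None) -> ds.FoodDatabase:
    """One item per group with exact energy densities (kcal/g)."""
    items = [
        ds.FoodItem(
            id=g.lower().replace(" ", "_"),
            group=g,
            energy_density=d * 100.0,
            footprints={"ghge": ds.Triplet.point(1.0)},
            waste_fraction=(waste or {}).get(g, 0.0),
        )
        for g, d in densities.items()
    ]
    return ds.FoodDatabase(items=items)


# -- waste adjustment -------------------------------------------------------


def test_waste_adjustment_arithmetic():
    db = _single_item_db({"Meats": 2.0}, waste={"Meats": 0.2})
    supply = ds.DietProfile(amounts={"Meats": 100.0}, stage="supply")
    cons = ds.apply_waste(supply, db)
    assert cons.stage == "consumption"
    assert cons.amount("Meats") == pytest.approx(80.0)


def test_zero_waste_is_identity(spec):
    db = _single_item_db({"Meats": 2.0, "Legumes": 0.8})
    supply = ds.DietProfile(amounts={"Meats": 50.0, "Legumes": 30.0}, stage="supply")
    cons = ds.apply_waste(supply, db)
    assert cons.amounts == supply.amounts


_DB_CACHE: dict = {}


def _default_db() -> ds.FoodDatabase:
    if "db" not in _DB_CACHE:
        _DB_CACHE["db"] = ds.generate_database(ds.SyntheticSpec(seed=7))
    return _DB_CACHE["db"]


@given(
    st.dictionaries(
        st.sampled_from(sorted(GROUPS)),
        st.floats(0, 1000, allow_nan=False),
        min_size=1,
    )
)
def test_consumption_never_exceeds_supply(amounts):
    db = _default_db()
    supply = ds.DietProfile(amounts=amounts, stage="supply")
    cons = ds.apply_waste(supply, db)
    for g, v in amounts.items():
        assert cons.amount(g) <= v + 1e-12


def test_waste_fraction_at_or_above_one_rejected():
    db = _single_item_db({"Meats": 2.0})
    db.item("meats").waste_fraction = 1.0
    supply = ds.DietProfile(amounts={"Meats": 100.0}, stage="supply")
    with pytest.raises(ds.DataError):
        ds.apply_waste(supply, db)


# -- energy content ---------------------------------------------------------


def test_energy_of_matches_hand_computation():
    db = _single_item_db({"Meats": 1.75})
    diet = ds.DietProfile(amounts={"Meats": 190.0})
    total, per_group = ds.energy_of(diet, db)
    assert total == pytest.approx(332.5)
    assert per_group["Meats"] == pytest.approx(332.5)


def test_energy_of_empty_diet_is_zero(db):
    total, _ = ds.energy_of(ds.DietProfile(amounts={}), db)
    assert total == 0.0


def test_energy_is_linear_in_amounts(db, bau_consumption):
    total, _ = ds.energy_of(bau_consumption, db)
    doubled, _ = ds.energy_of(bau_consumption.scaled(2.0), db)
    assert doubled == pytest.approx(2.0 * total, rel=1e-12)


# -- substitution -----------------------------------------------------------


@pytest.fixture(scope="module")
def specs_by_name():
    return {s.name: s for s in ds.builtin_scenarios("mass")}


def test_flexitarian_rule_halves_every_asf_group(specs_by_name):
    bau = canonical_bau()
    flx = ds.substitute(bau, specs_by_name["FLXPBA"])
    assert flx.amount("Meats") == 95.0
    assert flx.amount("Eggs") == 15.0
    assert flx.amount("Seafood") == 15.0
    assert flx.amount("Dairy") == 200.0
    for g in ASF_GROUPS:
        assert flx.amount(g) == 0.5 * bau.amount(g)


def test_vegan_rule_zeroes_all_asf_and_fills_pba(specs_by_name):
    bau = canonical_bau()
    vgn = ds.substitute(bau, specs_by_name["VGNPBA"])
    for g in ASF_GROUPS:
        assert vgn.amount(g) == 0.0
    # eggs route to the meat alternative: 190 + 30
    assert vgn.amount("Plant-based Meat") == pytest.approx(220.0)
    assert vgn.amount("Plant-based Dairy") == pytest.approx(400.0)
    assert vgn.amount("Plant-based Snacks") == pytest.approx(110.0)


def test_vegetarian_rule_retains_eggs_and_dairy(specs_by_name):
    bau = canonical_bau()
    vgt = ds.substitute(bau, specs_by_name["VGTPBA"])
    assert vgt.amount("Eggs") == 30.0
    assert vgt.amount("Dairy") == 400.0
    assert vgt.amount("Meats") == 0.0
    assert vgt.amount("Seafood") == 0.0
    assert vgt.amount("Snacks") == 110.0  # snack swap is not vegetarian


def test_mode_none_returns_input_unchanged(specs_by_name):
    bau = canonical_bau()
    out = ds.substitute(bau, specs_by_name["BAU"])
    assert out.amounts == bau.amounts


def test_mass_conservation_when_caps_do_not_bind(specs_by_name):
    bau = canonical_bau()
    flx = ds.substitute(bau, specs_by_name["FLXWHOLE"])
    assert flx.total_g == pytest.approx(bau.total_g, rel=1e-12)


def test_energy_basis_kcal_conservation_oracle():
    db = _single_item_db({"Meats": 2.0, "Legumes": 0.8})
    spec = ds.ScenarioSpec.build(
        "toy", ["Meats"], 1.0, "WF", {"Meats": {"Legumes": 1.0}}, functional_unit="energy"
    )
    bau = ds.DietProfile(amounts={"Meats": 100.0, "Legumes": 0.0})
    out = ds.substitute(bau, spec, db)
    # 100 g x 2.0 kcal/g = 200 kcal; at 0.8 kcal/g that is 250 g
    assert out.amount("Legumes") == pytest.approx(250.0)
    assert out.amount("Meats") == 0.0


def test_energy_basis_conserves_kcal_end_to_end(db, bau_consumption):
    for spec in ds.builtin_scenarios("energy"):
        if spec.mode == "none":
            continue
        out = ds.substitute(bau_consumption, spec, db)
        e_in, _ = ds.energy_of(bau_consumption, db)
        e_out, _ = ds.energy_of(out, db)
        assert e_out == pytest.approx(e_in, rel=1e-6), spec.name


def test_cap_overflow_goes_to_next_weighted_target():
    db = _single_item_db({"Meats": 2.0, "Legumes": 1.0, "Grains": 1.0})
    spec = ds.ScenarioSpec.build(
        "toy",
        ["Meats"],
        1.0,
        "WF",
        {"Meats": {"Legumes": 0.9, "Grains": 0.1}},
        caps={"Legumes": 50.0},
    )
    bau = ds.DietProfile(amounts={"Meats": 100.0, "Legumes": 0.0, "Grains": 0.0})
    out = ds.substitute(bau, spec, db)
    assert out.amount("Legumes") == pytest.approx(50.0)  # capped
    assert out.amount("Grains") == pytest.approx(50.0)  # 10 by weight + 40 overflow
    assert out.total_g == pytest.approx(bau.total_g)


def test_all_targets_capped_raises_infeasibility():
    spec = ds.ScenarioSpec.build(
        "toy", ["Meats"], 1.0, "WF", {"Meats": {"Legumes": 1.0}}, caps={"Legumes": 10.0}
    )
    bau = ds.DietProfile(amounts={"Meats": 100.0, "Legumes": 0.0})
    with pytest.raises(ds.InfeasibleSubstitution) as exc:
        ds.substitute(bau, spec)
    assert exc.value.residual == pytest.approx(90.0)


def test_energy_basis_with_zero_density_target_errors():
    db = _single_item_db({"Meats": 2.0, "Legumes": 0.8})
    db.item("legumes").energy_density = 0.0
    spec = ds.ScenarioSpec.build(
        "toy", ["Meats"], 1.0, "WF", {"Meats": {"Legumes": 1.0}}, functional_unit="energy"
    )
    bau = ds.DietProfile(amounts={"Meats": 100.0})
    with pytest.raises(ds.DataError):
        ds.substitute(bau, spec, db)


@given(st.floats(0.05, 1.0))
def test_flexitarian_scaling_halves_exactly_for_any_baseline_scale(factor):
    spec = [s for s in ds.builtin_scenarios("mass") if s.name == "FLXPBA"][0]
    bau = canonical_bau().scaled(factor)
    out = ds.substitute(bau, spec)
    for g in ASF_GROUPS:
        assert out.amount(g) == 0.5 * bau.amount(g)


# -- canonical table --------------------------------------------------------


def test_canonical_table_loads_fourteen_profiles():
    pairs = load_canonical_scenarios()
    assert len(pairs) == 14
    names = [n for n, _ in pairs]
    assert names.count("BAU") == 2  # mass + energy


def test_canonical_vegan_mass_columns_zero_all_asf():
    for name, prof in load_canonical_scenarios():
        if prof.basis == "mass" and name in ("VGNPBA", "VGNWHOLE"):
            for g in ASF_GROUPS:
                assert prof.amount(g) == 0.0


def test_canonical_flxwhole_legumes_quantity():
    prof = {
        (n, p.basis): p for n, p in load_canonical_scenarios()
    }[("FLXWHOLE", "mass")]
    assert prof.amount("Legumes") == 100.0


def test_canonical_vgnwhole_has_pb_snacks():
    prof = {(n, p.basis): p for n, p in load_canonical_scenarios()}[("VGNWHOLE", "mass")]
    assert prof.amount("Plant-based Snacks") == 110.0


def test_single_scenario_file_yields_two_profiles(tmp_path):
    p = tmp_path / "mini.csv"
    p.write_text(
        "group,basis,BAU\nMeats,mass,190\nLegumes,mass,0\nMeats,energy,333\nLegumes,energy,0\n"
    )
    pairs = load_canonical_scenarios(p)
    assert len(pairs) == 2
    assert {prof.basis for _, prof in pairs} == {"mass", "energy"}


def test_canonical_missing_cell_raises_parse_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("group,basis,BAU\nMeats,mass,\n")
    with pytest.raises(ds.SchemaError, match="BAU"):
        load_canonical_scenarios(p)


def test_rule_builder_reproduces_unambiguous_canonical_asf_cells(specs_by_name):
    """FLX/VGT/VGN ASF columns of the canonical table, bit-exact."""
    bau = canonical_bau()
    table = {(n, p.basis): p for n, p in load_canonical_scenarios()}
    for name in ("FLXPBA", "FLXWHOLE", "VGTPBA", "VGTWHOLE", "VGNPBA", "VGNWHOLE"):
        built = ds.substitute(bau, specs_by_name[name], db=None)
        expected = table[(name, "mass")]
        for g in ASF_GROUPS:
            assert built.amount(g) == expected.amount(g), (name, g)
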