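import pytest
from hypothesis import HealthCheck, settings

import dietshift as ds

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec() -> ds.SyntheticSpec:
    return ds.SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def db(spec) -> ds.FoodDatabase:
    """Default synthetic database: 3 items per group, 51 items."""
    return ds.generate_database(spec)


@pytest.fixture(scope="session")
def bau_consumption(spec, db) -> ds.DietProfile:
    return ds.apply_waste(ds.generate_bau_supply(spec, db), db)


@pytest.fixture(scope="session")
def mass_profiles(bau_consumption, db) -> dict:
    return ds.build_scenarios(bau_consumption, ds.builtin_scenarios("mass"), db)


@pytest.fixture(scope="session")
def energy_profiles(bau_consumption, db) -> dict:
    return ds.build_scenarios(bau_consumption, ds.builtin_scenarios("energy"), db)


def _toy_items():
    T = ds.Triplet
    return [
        ds.FoodItem(
            id="m1",
            group="Meats",
            energy_density=200.0,
            nutrients={"protein": T(70, 80, 90), "sodium": T(5000, 6000, 7000)},
            footprints={"ghge": T(8, 10, 12), "lu": T(20, 25, 30), "wu": T(300, 400, 500)},
            price=T(30, 40, 60),
            waste_fraction=0.2,
            share_within_group=0.5,
        ),
        ds.FoodItem(
            id="m2",
            group="Meats",
            energy_density=100.0,
            nutrients={"protein": T(100, 120, 140), "sodium": T(1000, 1500, 2000)},
            footprints={"ghge": T(0.5, 1, 2), "lu": T(4, 5, 6), "wu": T(100, 150, 200)},
            price=T(80, 100, 120),
            waste_fraction=0.2,
            share_within_group=0.5,
        ),
        ds.FoodItem(
            id="l1",
            group="Legumes",
            energy_density=80.0,
            nutrients={"protein": T(50, 60, 70), "sodium": T(200, 300, 400)},
            footprints={"ghge": T(0.5, 1.0, 1.5), "lu": T(1, 2, 3), "wu": T(50, 100, 150)},
            price=T(20, 30, 40),
            waste_fraction=0.0,
            share_within_group=1.0,
        ),
    ]


@pytest.fixture
def toy_db() -> ds.FoodDatabase:
    """Hand-computed two-group database for arithmetic oracles."""
    recs = ds.RecommendationTable(
        [
            ds.Recommendation("protein", 50.0, unit="g", direction="minimum"),
            ds.Recommendation("sodium", 2000.0, unit="mg", direction="limit"),
        ]
    )
    return ds.FoodDatabase(items=_toy_items(), recommendations=recs)
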