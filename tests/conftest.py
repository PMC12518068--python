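import pytest

from dietopt.food_system_io import (
    Classification,
    Diet,
    FoodItem,
    FoodSystem,
    NutrientDef,
)
from dietopt.guidelines import GuidelineSet, MicroRef
from dietopt.synthetic_data import Bottleneck, GeneratorParams, generate_food_system


@pytest.fixture
def tiny_system() -> FoodSystem:
    """Two-group, four-item handmade system used across modules."""
    defs = {
        "protein": NutrientDef("protein", "Protein", "g", "macro_energy", 4.0),
        "fat": NutrientDef("fat", "Fat", "g", "macro_energy", 9.0),
        "sodium": NutrientDef("sodium", "Sodium", "mg", "macro_mass"),
        "iron": NutrientDef("iron", "Iron", "mg", "micro"),
    }

    def item(iid, energy, protein, fat, sodium, iron, ghge, fixed=False,
             occurrences=10):
        return FoodItem(
            item_id=iid, name=iid.upper(), energy=energy,
            nutrients={"protein": protein, "fat": fat, "sodium": sodium,
                       "iron": iron},
            ghge=ghge, fixed=fixed, occurrences=occurrences,
        )

    items = {
        "a1": item("a1", 200.0, 10.0, 8.0, 300.0, 2.0, 0.5),
        "a2": item("a2", 250.0, 15.0, 5.0, 100.0, 6.0, 1.5),
        "b1": item("b1", 350.0, 5.0, 20.0, 600.0, 1.0, 0.2),
        "b2": item("b2", 300.0, 8.0, 12.0, 200.0, 3.0, 0.8),
    }
    cls = Classification(
        "groups", {"ga": "Group A", "gb": "Group B"},
        {"a1": "ga", "a2": "ga", "b1": "gb", "b2": "gb"},
    )
    guidelines = GuidelineSet(
        macro_energy_bounds={"protein": (10.0, 35.0), "fat": (None, 40.0)},
        macro_mass_bounds={"sodium": (None, 2300.0)},
        micro_refs={"iron": MicroRef(rda=18.0, ear=8.1, unit="mg")},
    )
    system = FoodSystem(
        items=items, nutrient_defs=defs, classifications={"groups": cls},
        diets={"obs": Diet("obs", {"a1": 100.0, "a2": 50.0, "b1": 150.0,
                                   "b2": 80.0})},
        guidelines={"obs": guidelines},
    )
    system.validate()
    return system


@pytest.fixture(scope="session")
def generated_system() -> FoodSystem:
    """One seeded full-size synthetic system, shared by read-only tests."""
    return generate_food_system(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def compliant_system() -> FoodSystem:
    """Synthetic system whose observed diets meet all guidelines."""
    return generate_food_system(GeneratorParams(seed=11, bottlenecks=()))
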