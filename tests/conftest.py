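import pytest
from hypothesis import HealthCheck, settings

from nutrikit import (
    FoodRecord,
    NutrientDef,
    NutrientRegistry,
    SourceTable,
    default_registry,
)

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def registry() -> NutrientRegistry:
    return default_registry()


@pytest.fixture
def tiny_registry() -> NutrientRegistry:
    return NutrientRegistry(
        [
            NutrientDef("energy", "Energy", "kcal", "macronutrient"),
            NutrientDef("carbohydrate", "Carbohydrate", "g", "macronutrient"),
            NutrientDef("protein", "Protein", "g", "macronutrient"),
            NutrientDef("fat", "Fat", "g", "macronutrient"),
            NutrientDef("water", "Water", "g", "macronutrient"),
            NutrientDef("sodium", "Sodium", "mg", "mineral"),
            NutrientDef("fiber", "Fiber", "g", "fiber"),
        ]
    )


def make_food(food_id, name_en="food", state="cooked", values=None, **kw) -> FoodRecord:
    merged = dict(values or {})
    merged.update(kw)
    return FoodRecord(
        food_id=food_id,
        name_ko=name_en,
        name_en=name_en,
        state=state,
        values=merged,
    )


def make_table(source_id, foods, rank=1) -> SourceTable:
    return SourceTable(source_id, source_id, rank, foods)


@pytest.fixture
def make_food_factory():
    return make_food


@pytest.fixture
def make_table_factory():
    return make_table
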