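import numpy as np
import pandas as pd
import pytest

from dietopt.food_composition import (
    MICRONUTRIENTS,
    FoodTable,
    load_taxonomy,
)
from dietopt.pipeline import optimize_population
from dietopt.survey_records import records_from_frames
from dietopt.synthetic_data import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


def make_table(rows, taxonomy):
    """Build a FoodTable from partial row dicts (missing nutrients zeroed)."""
    full = []
    for r in rows:
        base = {c: 0.0 for c in MICRONUTRIENTS}
        base.update(
            {
                "name": r.get("food_id", "food"),
                "energy": 0.0,
                "protein": 0.0,
                "fat": 0.0,
                "saturated_fat": 0.0,
                "carbohydrate": 0.0,
                "starch": 0.0,
                "total_sugars": 0.0,
                "free_sugars": 0.0,
                "fiber": 0.0,
                "sodium": 0.0,
                "cholesterol": 0.0,
                "is_beverage": False,
                "is_energy_free_drink": False,
                "is_alcoholic": False,
                "unit_cost": 0.0,
            }
        )
        base.update(r)
        base["category"] = taxonomy.category_of(base["subcategory"])
        full.append(base)
    df = pd.DataFrame(full).set_index("food_id")
    return FoodTable(df, taxonomy)


@pytest.fixture(scope="session")
def tiny_table(taxonomy):
    """Five hand-checkable foods spanning solids, beverages and sugar."""
    return make_table(
        [
            dict(food_id="apple", subcategory="fresh_fruits", energy=52.0,
                 carbohydrate=11.5, total_sugars=10.0, starch=1.5, fiber=2.4),
            dict(food_id="bread", subcategory="refined_starches", energy=240.0,
                 protein=8.0, carbohydrate=50.0, starch=48.0, total_sugars=2.0,
                 fat=2.0, sodium=500.0, fiber=3.0),
            dict(food_id="cola", subcategory="sugar_sweetened_beverages",
                 energy=42.0, carbohydrate=10.5, total_sugars=10.5,
                 free_sugars=10.5, is_beverage=True),
            dict(food_id="sugar", subcategory="table_sugar", energy=398.0,
                 carbohydrate=99.6, total_sugars=99.6, free_sugars=99.6),
            dict(food_id="water", subcategory="water", is_beverage=True,
                 is_energy_free_drink=True),
        ],
        taxonomy,
    )


@pytest.fixture(scope="session")
def small_population():
    return generate_population(GeneratorConfig(seed=42, n_individuals=60))


@pytest.fixture(scope="session")
def small_records(small_population):
    return records_from_frames(
        small_population.individuals, small_population.diaries
    )


@pytest.fixture(scope="session")
def small_run(small_population, small_records):
    return optimize_population(small_records, small_population.table)
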