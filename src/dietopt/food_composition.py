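"""Food composition table with free-sugar accounting.

Free sugars (WHO definition) are the mono- and disaccharides added to foods by
the manufacturer, cook or consumer, plus the sugars naturally present in honey,
syrups, fruit juices and fruit-juice concentrates.  A composition table rarely
carries them directly, so each food declares how its free-sugar content is
obtained:

``sugars_equal_free``
    free sugars := total sugars (beverages, honey, syrups).
``recipe``
    free sugars estimated from the food's average recipe: the summed weight of
    assimilated-sugar ingredients times their equivalent-sugar converting
    factor (1.0 for white sugar, 0.8 for honey).
``expert_zero`` / ``expert_value``
    an explicit nutritional-expertise estimate (0, or a supplied override).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

__all__ = [
    "MACRO_COLUMNS",
    "MICRONUTRIENTS",
    "NUTRIENT_COLUMNS",
    "FLAG_COLUMNS",
    "FREE_SUGAR_RULES",
    "Taxonomy",
    "FoodItem",
    "Recipe",
    "SugarConversionTable",
    "FoodTable",
    "FoodCompositionError",
    "load_taxonomy",
    "load_conversion_table",
    "load_recipes",
    "estimate_free_sugars",
    "apply_whole_food_rule",
    "load_food_table",
    "write_food_table",
]

#: per-100 g macronutrient-level columns (energy kcal, masses g except sodium
#: and cholesterol in mg)
MACRO_COLUMNS = (
    "energy",
    "protein",
    "fat",
    "saturated_fat",
    "carbohydrate",
    "starch",
    "total_sugars",
    "free_sugars",
    "fiber",
    "sodium",
    "cholesterol",
)

#: micronutrients tracked per 100 g (units per the nutrient-reference config)
MICRONUTRIENTS = (
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "vitamin_b3",
    "vitamin_b5",
    "vitamin_b6",
    "vitamin_b9",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
    "calcium",
    "iron",
    "magnesium",
    "zinc",
    "potassium",
    "copper",
    "iodine",
    "selenium",
    "phosphorus",
    "manganese",
)

NUTRIENT_COLUMNS = MACRO_COLUMNS + MICRONUTRIENTS

FLAG_COLUMNS = ("is_beverage", "is_energy_free_drink", "is_alcoholic")

FREE_SUGAR_RULES = ("sugars_equal_free", "recipe", "expert_zero", "expert_value")

#: carbohydrate closure tolerance: starch + total_sugars <= carbohydrate*(1+eps)
CARB_EPSILON = 0.02

#: energy threshold (kcal/100 mL, density 1 assumed) below which a beverage is
#: an "energy-free" drink
ENERGY_FREE_DRINK_KCAL = 4.0


class FoodCompositionError(ValueError):
    """Raised when a food table, recipe or rule application is invalid."""


def _config_path(name: str):
    return importlib.resources.files("dietopt.config").joinpath(name)


@dataclass(frozen=True)
class Taxonomy:
    """The 9-category / 30-sub-category food classification."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cat, subs in self.categories.items():
            for sub in subs:
                if sub in seen:
                    raise FoodCompositionError(
                        f"sub-category {sub!r} appears under both "
                        f"{seen[sub]!r} and {cat!r}"
                    )
                seen[sub] = cat
        object.__setattr__(self, "_sub_to_cat", seen)

    @property
    def subcategories(self) -> tuple[str, ...]:
        return tuple(self._sub_to_cat)

    def category_of(self, subcategory: str) -> str:
        try:
            return self._sub_to_cat[subcategory]
        except KeyError:
            raise FoodCompositionError(f"unknown sub-category: {subcategory!r}")


def load_taxonomy(path=None) -> Taxonomy:
    """Load a taxonomy from YAML; the packaged default has 9 categories and
    30 sub-categories."""
    src = path if path is not None else _config_path("taxonomy.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        raw = yaml.safe_load(fh)
    cats = {c: tuple(subs) for c, subs in raw["categories"].items()}
    return Taxonomy(cats)


@dataclass
class FoodItem:
    """One food, nutrient contents per 100 g."""

    food_id: str
    name: str
    category: str
    subcategory: str
    energy: float  # kcal/100 g
    protein: float = 0.0
    fat: float = 0.0
    saturated_fat: float = 0.0
    carbohydrate: float = 0.0
    starch: float = 0.0
    total_sugars: float = 0.0
    free_sugars: float = 0.0
    fiber: float = 0.0
    sodium: float = 0.0  # mg/100 g
    cholesterol: float = 0.0  # mg/100 g
    micronutrients: dict[str, float] = field(default_factory=dict)
    is_beverage: bool = False
    is_energy_free_drink: bool = False
    is_alcoholic: bool = False
    unit_cost: float = 0.0  # currency per 100 g

    def validate(self) -> "FoodItem":
        if not 0.0 <= self.free_sugars <= self.total_sugars + 1e-9:
            raise FoodCompositionError(
                f"{self.food_id}: free_sugars ({self.free_sugars}) outside "
                f"[0, total_sugars={self.total_sugars}]"
            )
        if self.starch + self.total_sugars > self.carbohydrate * (1 + CARB_EPSILON) + 1e-9:
            raise FoodCompositionError(
                f"{self.food_id}: starch + sugars exceed carbohydrate "
                f"({self.starch} + {self.total_sugars} > {self.carbohydrate})"
            )
        if self.is_energy_free_drink and not (
            self.is_beverage and self.energy < ENERGY_FREE_DRINK_KCAL
        ):
            raise FoodCompositionError(
                f"{self.food_id}: energy-free drink must be a beverage with "
                f"energy < {ENERGY_FREE_DRINK_KCAL} kcal/100 g"
            )
        return self


@dataclass(frozen=True)
class Recipe:
    """Average recipe of a composite food, as ingredient weight fractions.

    Fractions need not sum to one (water loss or gain during preparation)."""

    food_id: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self):
        for ing, frac in self.components:
            if frac < 0:
                raise FoodCompositionError(
                    f"recipe {self.food_id}: negative weight fraction for {ing!r}"
                )


class SugarConversionTable:
    """ingredient -> equivalent-sugar converting factor in [0, 1].

    Ingredients absent from the table convert at 0.  If present, the white
    sugar entry must be 1.0 and the honey entry 0.8 (fixed anchors)."""

    def __init__(self, factors: dict[str, float]):
        for ing, f in factors.items():
            if not 0.0 <= f <= 1.0:
                raise FoodCompositionError(
                    f"conversion factor for {ing!r} outside [0, 1]: {f}"
                )
        if "white_sugar" in factors and factors["white_sugar"] != 1.0:
            raise FoodCompositionError("white_sugar converting factor must be 1.0")
        if "honey" in factors and factors["honey"] != 0.8:
            raise FoodCompositionError("honey converting factor must be 0.8")
        self._factors = dict(factors)

    def fraction(self, ingredient_id: str) -> float:
        return self._factors.get(ingredient_id, 0.0)

    def __contains__(self, ingredient_id: str) -> bool:
        return ingredient_id in self._factors


def load_conversion_table(path=None) -> SugarConversionTable:
    src = path if path is not None else _config_path("conversion_factors.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        return SugarConversionTable(yaml.safe_load(fh))


def load_recipes(path) -> dict[str, Recipe]:
    """Read recipes from CSV (food_id, ingredient_id, weight_fraction)."""
    df = pd.read_csv(path)
    out: dict[str, Recipe] = {}
    for food_id, grp in df.groupby("food_id", sort=False):
        out[str(food_id)] = Recipe(
            str(food_id),
            tuple(
                (str(r.ingredient_id), float(r.weight_fraction))
                for r in grp.itertuples()
            ),
        )
    return out


def estimate_free_sugars(recipe: Recipe, conv: SugarConversionTable) -> float:
    """Free sugars (g per 100 g of food) from the recipe's assimilated-sugar
    ingredients: 100 * sum of weight_fraction * converting factor."""
    grams = 100.0 * sum(frac * conv.fraction(ing) for ing, frac in recipe.components)
    if grams > 100.0 + 1e-9:
        raise FoodCompositionError(
            f"recipe {recipe.food_id}: estimated free sugars exceed 100 g/100 g"
        )
    return grams


def apply_whole_food_rule(
    food: FoodItem,
    rule_class: str,
    recipe: Recipe | None = None,
    conv: SugarConversionTable | None = None,
    override: float | None = None,
) -> FoodItem:
    """Return a copy of *food* with ``free_sugars`` set according to its rule.

    The free <= total invariant is enforced by clipping (with a warning):
    recipe estimates can overshoot the analyzed total-sugar content."""
    if rule_class not in FREE_SUGAR_RULES:
        raise FoodCompositionError(f"unknown free-sugar rule: {rule_class!r}")
    if rule_class == "sugars_equal_free":
        fs = food.total_sugars
    elif rule_class == "expert_zero":
        fs = 0.0
    elif rule_class == "expert_value":
        if override is None:
            raise FoodCompositionError(
                f"{food.food_id}: expert_value rule requires an override"
            )
        fs = float(override)
    else:  # recipe
        if recipe is None:
            raise FoodCompositionError(f"{food.food_id}: no recipe on file")
        fs = estimate_free_sugars(recipe, conv or load_conversion_table())
    if fs > food.total_sugars:
        warnings.warn(
            f"{food.food_id}: free sugars ({fs:.2f}) clipped to total sugars "
            f"({food.total_sugars:.2f})",
            stacklevel=2,
        )
        fs = food.total_sugars
    if fs < 0:
        raise FoodCompositionError(f"{food.food_id}: negative free sugars")
    return replace(food, free_sugars=fs).validate()


class FoodTable:
    """A validated food composition table.

    Backed by a DataFrame indexed by ``food_id``; nutrient columns are per
    100 g.  Construct via :func:`load_food_table` or from a DataFrame."""

    def __init__(self, df: pd.DataFrame, taxonomy: Taxonomy):
        missing = [c for c in NUTRIENT_COLUMNS if c not in df.columns]
        if missing:
            raise FoodCompositionError(f"missing nutrient columns: {missing}")
        self.df = df
        self.taxonomy = taxonomy
        self._validate()

    def _validate(self):
        df = self.df
        bad_sub = df.index[~df["subcategory"].isin(self.taxonomy.subcategories)]
        if len(bad_sub):
            raise FoodCompositionError(
                f"unknown sub-category for foods: {list(bad_sub)}"
            )
        expected_cat = df["subcategory"].map(self.taxonomy.category_of)
        bad_cat = df.index[df["category"] != expected_cat]
        if len(bad_cat):
            raise FoodCompositionError(
                f"category inconsistent with sub-category for foods: {list(bad_cat)}"
            )
        bad_fs = df.index[
            (df["free_sugars"] < -1e-9)
            | (df["free_sugars"] > df["total_sugars"] + 1e-9)
        ]
        if len(bad_fs):
            raise FoodCompositionError(
                f"free_sugars outside [0, total_sugars] for foods: {list(bad_fs)}"
            )
        bad_carb = df.index[
            df["starch"] + df["total_sugars"]
            > df["carbohydrate"] * (1 + CARB_EPSILON) + 1e-9
        ]
        if len(bad_carb):
            raise FoodCompositionError(
                f"starch + sugars exceed carbohydrate for foods: {list(bad_carb)}"
            )
        bad_efd = df.index[
            df["is_energy_free_drink"]
            & (~df["is_beverage"] | (df["energy"] >= ENERGY_FREE_DRINK_KCAL))
        ]
        if len(bad_efd):
            raise FoodCompositionError(
                f"energy-free-drink flag inconsistent for foods: {list(bad_efd)}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def food_ids(self) -> pd.Index:
        return self.df.index

    def nutrient(self, nutrient_id: str) -> pd.Series:
        """Per-100 g content vector for one nutrient."""
        if nutrient_id not in NUTRIENT_COLUMNS:
            raise FoodCompositionError(f"unknown nutrient: {nutrient_id!r}")
        return self.df[nutrient_id]

    def nutrient_matrix(self, nutrients=NUTRIENT_COLUMNS) -> pd.DataFrame:
        return self.df[list(nutrients)]

    def item(self, food_id: str) -> FoodItem:
        row = self.df.loc[food_id]
        return FoodItem(
            food_id=food_id,
            name=row["name"],
            category=row["category"],
            subcategory=row["subcategory"],
            micronutrients={n: float(row[n]) for n in MICRONUTRIENTS},
            unit_cost=float(row["unit_cost"]),
            **{n: float(row[n]) for n in MACRO_COLUMNS},
            **{f: bool(row[f]) for f in FLAG_COLUMNS},
        )

    def __len__(self):
        return len(self.df)


def load_food_table(
    path,
    taxonomy: Taxonomy | None = None,
    recipes: dict[str, Recipe] | None = None,
    conv: SugarConversionTable | None = None,
    required_nutrients=None,
) -> FoodTable:
    """Read a food table from CSV and validate it.

    If a ``free_sugar_rule`` column is present, free-sugar contents are
    (re)computed per food from its rule class (``expert_value`` rows read the
    ``free_sugars_override`` column; ``recipe`` rows need *recipes*).
    *required_nutrients* lets a caller demand the columns its constraint set
    needs, with a clear error naming any that are absent.
    """
    df = pd.read_csv(path, dtype={"food_id": str})
    if "food_id" not in df.columns:
        raise FoodCompositionError("food table must have a food_id column")
    df = df.set_index("food_id")
    if required_nutrients:
        missing = [n for n in required_nutrients if n not in df.columns]
        if missing:
            raise FoodCompositionError(
                f"food table lacks nutrient columns required by the active "
                f"constraint set: {missing}"
            )
    for flag in FLAG_COLUMNS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
        else:
            df[flag] = False
    if "unit_cost" not in df.columns:
        df["unit_cost"] = 0.0
    taxonomy = taxonomy or load_taxonomy()

    if "free_sugar_rule" in df.columns:
        conv = conv or load_conversion_table()
        recipes = recipes or {}
        fs = []
        for food_id, row in df.iterrows():
            rule = row["free_sugar_rule"]
            if rule == "sugars_equal_free":
                val = row["total_sugars"]
            elif rule == "expert_zero":
                val = 0.0
            elif rule == "expert_value":
                val = float(row.get("free_sugars_override", float("nan")))
            elif rule == "recipe":
                if food_id not in recipes:
                    raise FoodCompositionError(
                        f"{food_id}: recipe rule but no recipe on file"
                    )
                val = estimate_free_sugars(recipes[food_id], conv)
            else:
                raise FoodCompositionError(
                    f"{food_id}: unknown free_sugar_rule {rule!r}"
                )
            fs.append(min(val, row["total_sugars"]))
        df["free_sugars"] = fs
    return FoodTable(df, taxonomy)


def write_food_table(table: FoodTable, path) -> None:
    """Write the table back to CSV (flags as 0/1, full float precision)."""
    out = table.df.copy()
    for flag in FLAG_COLUMNS:
        out[flag] = out[flag].astype(int)
    out.to_csv(path, index_label="food_id")
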