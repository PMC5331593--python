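"""Seed-reproducible synthetic food tables and 7-day survey populations.

The generator emulates the statistical structure of a national 7-day diet
diary of adults (20-75 y) as it bears on free-sugar analysis:

* a two-group population: 59% with a free-sugar energy share at or below 10%
  (group mean 6.3%, SD 2.5%) and 41% above 10% (mean 14.2%, SD 4.2%),
  drawn from truncated normals whose parent parameters are moment-matched so
  the *realized* (truncated) mean and SD equal the configured ones;
* group-specific total energy (2123 +/- 539 vs 2192 +/- 529 kcal/day) and
  snacking energy (means 131 vs 258 kcal/day, gamma-distributed since the
  reported SDs exceed the means);
* sub-category food amounts centred on the reported observed group means,
  with multiplicative gamma noise and realistic non-consumption;
* per-individual survey weights (lognormal, normalized to mean 1).

Each diary is constructed so that its computed 7-day mean energy and
free-sugar energy share equal the drawn targets exactly (a two-lever
rescaling of free-sugar-bearing vs other energy-bearing foods per day), so
the group classifier reproduces the generator's label for every individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.stats import truncnorm

from .food_composition import (
    MICRONUTRIENTS,
    FoodTable,
    Recipe,
    Taxonomy,
    load_conversion_table,
    load_taxonomy,
)
from .survey_records import (
    FS_KCAL_PER_G,
    MEAL_MOMENTS,
    N_DAYS,
    SNACK_MOMENTS,
)

__all__ = [
    "GeneratorConfig",
    "GroupParams",
    "SyntheticPopulation",
    "GenerationError",
    "generate_food_table",
    "generate_population",
    "moment_report",
]

FS_ACCEPTABLE = "FS_ACCEPTABLE"
FS_EXCESS = "FS_EXCESS"


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-group simulation targets (all per day)."""

    fs_share_mean: float  # % of energy
    fs_share_sd: float
    fs_share_lower: float  # truncation bounds on the share
    fs_share_upper: float
    energy_mean: float  # kcal
    energy_sd: float
    snack_energy_mean: float  # kcal
    snack_energy_sd: float
    age_mean: float
    age_sd: float
    p_female: float


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_individuals: int = 1693
    p_excess: float = 0.41
    n_foods: int = 100
    force_group: str | None = None  # FS_ACCEPTABLE | FS_EXCESS | None
    groups: dict = field(
        default_factory=lambda: {
            FS_ACCEPTABLE: GroupParams(
                fs_share_mean=6.3,
                fs_share_sd=2.5,
                fs_share_lower=0.5,
                fs_share_upper=10.0,
                energy_mean=2123.0,
                energy_sd=539.0,
                snack_energy_mean=131.0,
                snack_energy_sd=154.0,
                age_mean=51.1,
                age_sd=14.0,
                p_female=0.506,
            ),
            FS_EXCESS: GroupParams(
                fs_share_mean=14.2,
                fs_share_sd=4.2,
                fs_share_lower=10.0,
                fs_share_upper=35.0,
                energy_mean=2192.0,
                energy_sd=529.0,
                snack_energy_mean=258.0,
                snack_energy_sd=220.0,
                age_mean=41.1,
                age_sd=14.5,
                p_female=0.55,
            ),
        }
    )

    def __post_init__(self):
        if not 0.0 <= self.p_excess <= 1.0:
            raise GenerationError("p_excess must be in [0, 1]")
        for g in self.groups.values():
            if min(g.fs_share_sd, g.energy_sd, g.snack_energy_sd) <= 0:
                raise GenerationError("all SDs must be positive")


# ---------------------------------------------------------------------------
# sub-category archetypes
# ---------------------------------------------------------------------------

# per-100 g archetype composition: energy is recomputed from Atwater factors
# (4/9/4) so percent-energy constraints are exactly consistent.
# fs_rule: how free sugars are derived; fs_frac: white-sugar weight fraction
# of the average recipe for recipe-class foods.
_A = {
    # subcat: protein, fat, sfa_frac, sugars, starch, fiber, sodium, chol,
    #         fs_rule, fs_frac, beverage, cost
    "fresh_fruits": (0.8, 0.3, 0.2, 11.0, 0.5, 2.4, 2, 0, "expert_zero", 0.0, False, 0.35),
    "processed_fruits": (0.5, 0.2, 0.2, 17.0, 0.5, 1.6, 5, 0, "recipe", 0.08, False, 0.40),
    "vegetables": (1.5, 0.3, 0.2, 2.8, 1.8, 3.1, 60, 0, "expert_zero", 0.0, False, 0.45),
    "nuts": (18.0, 54.0, 0.12, 4.5, 7.5, 8.0, 5, 0, "expert_zero", 0.0, False, 1.50),
    "refined_starches": (8.0, 2.0, 0.3, 2.0, 46.0, 3.0, 550, 0, "expert_zero", 0.0, False, 0.30),
    "unrefined_starches": (6.0, 1.5, 0.25, 1.5, 26.0, 6.0, 160, 0, "expert_zero", 0.0, False, 0.25),
    "ready_to_eat_cereals": (8.0, 4.0, 0.4, 22.0, 53.0, 6.0, 400, 0, "recipe", 0.20, False, 0.60),
    "meats_eggs_fish": (22.0, 13.0, 0.30, 0.3, 0.2, 0.0, 350, 90, "expert_zero", 0.0, False, 1.20),
    "mixed_dishes": (7.5, 9.0, 0.32, 2.0, 13.0, 1.5, 780, 30, "recipe", 0.01, False, 0.80),
    "sandwiches": (10.0, 10.0, 0.35, 3.0, 25.0, 2.0, 880, 35, "recipe", 0.01, False, 0.90),
    "plain_milk": (3.3, 1.6, 0.65, 4.8, 0.0, 0.0, 45, 6, "expert_zero", 0.0, True, 0.12),
    "sweet_milk": (3.2, 1.6, 0.65, 10.0, 0.3, 0.0, 50, 6, "recipe", 0.055, True, 0.20),
    "plain_yogurts": (4.0, 2.8, 0.65, 5.0, 0.0, 0.0, 55, 10, "expert_zero", 0.0, False, 0.25),
    "sweet_yogurts": (3.8, 2.6, 0.65, 12.5, 0.3, 0.0, 55, 10, "recipe", 0.09, False, 0.30),
    "cheese": (22.0, 26.0, 0.62, 1.0, 0.3, 0.0, 820, 80, "expert_zero", 0.0, False, 1.10),
    "milk_egg_desserts": (3.5, 4.0, 0.6, 16.0, 4.0, 0.3, 80, 40, "recipe", 0.13, False, 0.45),
    "cakes_pastries": (5.5, 18.0, 0.42, 26.0, 22.0, 1.8, 300, 60, "recipe", 0.24, False, 0.70),
    "biscuits": (6.0, 20.0, 0.45, 30.0, 35.0, 2.5, 350, 30, "recipe", 0.28, False, 0.55),
    "croissants": (7.5, 22.0, 0.55, 12.0, 33.0, 2.0, 380, 55, "recipe", 0.10, False, 0.75),
    "confectionery": (4.5, 22.0, 0.6, 55.0, 7.0, 3.0, 60, 10, "recipe", 0.48, False, 1.00),
    "honey_marmalade_spread": (0.8, 3.0, 0.5, 66.0, 2.0, 0.8, 30, 0, "recipe", 0.55, False, 0.60),
    "table_sugar": (0.0, 0.0, 0.0, 99.6, 0.0, 0.0, 0, 0, "recipe", 0.996, False, 0.15),
    "water": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 3, 0, "sugars_equal_free", 0.0, True, 0.03),
    "hot_beverages": (0.1, 0.0, 0.0, 0.15, 0.0, 0.0, 2, 0, "sugars_equal_free", 0.0, True, 0.08),
    "diet_beverages": (0.0, 0.0, 0.0, 0.2, 0.0, 0.0, 10, 0, "sugars_equal_free", 0.0, True, 0.15),
    "sugar_sweetened_beverages": (0.0, 0.0, 0.0, 10.5, 0.0, 0.0, 10, 0, "sugars_equal_free", 0.0, True, 0.15),
    "fruit_juices": (0.5, 0.1, 0.2, 10.0, 0.2, 0.3, 5, 0, "sugars_equal_free", 0.0, True, 0.25),
    "added_fats": (0.3, 80.0, 0.40, 0.3, 0.2, 0.0, 90, 60, "expert_zero", 0.0, False, 0.80),
    "sauces": (1.5, 12.0, 0.3, 4.0, 4.0, 0.5, 1350, 15, "recipe", 0.03, False, 0.60),
    "soya_foods": (8.0, 4.5, 0.15, 2.0, 1.5, 1.2, 40, 0, "expert_zero", 0.0, False, 0.45),
}

# within-sub-category variants, applied cyclically to successive foods of a
# sub-category: real tables pair salty bread with unsalted pasta, butter with
# oil, processed with lean meat — heterogeneity the optimizer needs for
# substitutions (field order: protein, fat, sfa_frac, sugars, starch, fiber,
# sodium, cholesterol; None keeps the archetype value)
_VARIANTS: dict[str, list[dict]] = {
    "refined_starches": [
        {"sodium": 700, "fiber": 3.2},          # bread
        {"sodium": 25, "fiber": 2.2},           # pasta / rice
        {"sodium": 450, "fiber": 3.0},
    ],
    "unrefined_starches": [
        {"sodium": 320, "fiber": 7.0},          # wholegrain bread
        {"sodium": 12, "fiber": 8.5},           # legumes / brown rice
    ],
    "meats_eggs_fish": [
        {"fat": 17.0, "sfa_frac": 0.38, "sodium": 1050},  # processed meat
        {"fat": 8.0, "sfa_frac": 0.30, "sodium": 90},    # lean meat / eggs
        {"fat": 11.0, "sfa_frac": 0.22, "sodium": 110},  # fish
        {"fat": 14.0, "sfa_frac": 0.36, "sodium": 120},
    ],
    "added_fats": [
        {"fat": 82.0, "sfa_frac": 0.66, "cholesterol": 220},  # butter
        {"fat": 92.0, "sfa_frac": 0.12, "cholesterol": 0},    # vegetable oil
        {"fat": 70.0, "sfa_frac": 0.30, "cholesterol": 10},   # margarine
    ],
    "cheese": [
        {},
        {"fat": 19.0, "sodium": 520},           # fresh / soft cheese
    ],
    "vegetables": [
        {"sodium": 15},                          # plain vegetables
        {"sodium": 160},                         # soups / canned
    ],
    "plain_yogurts": [{}, {"fat": 1.0, "sfa_frac": 0.6}],
}

# minimum foods per sub-category: sub-categories with compositional variants
# must field all of them (a table whose only added fat is butter makes the
# fat window unsatisfiable population-wide)
_MIN_FOODS = {sub: len(v) for sub, v in _VARIANTS.items()}

# extra foods beyond one per sub-category are allocated with these weights
_EXTRA_FOOD_WEIGHTS = {
    "fresh_fruits": 6, "processed_fruits": 2, "vegetables": 8, "nuts": 1,
    "refined_starches": 6, "unrefined_starches": 4, "ready_to_eat_cereals": 1,
    "meats_eggs_fish": 8, "mixed_dishes": 5, "sandwiches": 2,
    "plain_milk": 1, "sweet_milk": 1, "plain_yogurts": 2, "sweet_yogurts": 2,
    "cheese": 4, "milk_egg_desserts": 2, "cakes_pastries": 3, "biscuits": 2,
    "croissants": 2, "confectionery": 2, "honey_marmalade_spread": 2,
    "table_sugar": 0, "water": 2, "hot_beverages": 2, "diet_beverages": 1,
    "sugar_sweetened_beverages": 2, "fruit_juices": 2, "added_fats": 3,
    "sauces": 2, "soya_foods": 1,
}

# relative per-nutrient density patterns across sub-categories (unitless);
# absolute contents are calibrated so a reference diet at ~2150 kcal covers
# each recommendation at the coverage factor below.
_MICRO_RELATIVE = {
    "vitamin_a": {"vegetables": 10, "added_fats": 10, "cheese": 8, "meats_eggs_fish": 3,
                  "plain_milk": 2, "fresh_fruits": 1.5, "_default": 0.3},
    "vitamin_b1": {"unrefined_starches": 5, "refined_starches": 2.5, "meats_eggs_fish": 3,
                   "nuts": 5, "ready_to_eat_cereals": 8, "mixed_dishes": 2, "_default": 0.5},
    "vitamin_b2": {"plain_milk": 5, "plain_yogurts": 5, "sweet_yogurts": 4, "cheese": 5,
                   "meats_eggs_fish": 3, "ready_to_eat_cereals": 6, "_default": 0.5},
    "vitamin_b3": {"meats_eggs_fish": 8, "unrefined_starches": 3, "refined_starches": 2,
                   "hot_beverages": 8, "_default": 0.5},
    "vitamin_b5": {"meats_eggs_fish": 4, "plain_milk": 3, "plain_yogurts": 3,
                   "mixed_dishes": 2, "unrefined_starches": 2, "_default": 0.8},
    "vitamin_b6": {"meats_eggs_fish": 6, "unrefined_starches": 3, "vegetables": 2,
                   "fresh_fruits": 2, "_default": 0.5},
    "vitamin_b9": {"vegetables": 8, "fresh_fruits": 3, "unrefined_starches": 3,
                   "nuts": 4, "cheese": 2, "fruit_juices": 8, "_default": 0.6},
    "vitamin_b12": {"meats_eggs_fish": 12, "cheese": 4, "plain_milk": 3,
                    "plain_yogurts": 3, "sweet_yogurts": 2, "_default": 0.0},
    "vitamin_c": {"fresh_fruits": 10, "vegetables": 8, "fruit_juices": 25,
                  "processed_fruits": 3, "_default": 0.1},
    "vitamin_d": {"meats_eggs_fish": 7, "added_fats": 8, "plain_milk": 2,
                  "sweet_milk": 2, "plain_yogurts": 1.5, "ready_to_eat_cereals": 4,
                  "_default": 0.1},
    "vitamin_e": {"added_fats": 12, "nuts": 10, "vegetables": 3, "sauces": 6,
                  "fresh_fruits": 1.5, "_default": 0.5},
    "calcium": {"cheese": 12, "plain_milk": 5, "sweet_milk": 5, "plain_yogurts": 6,
                "sweet_yogurts": 5, "water": 0.05, "vegetables": 1.5, "soya_foods": 4,
                "_default": 0.5},
    "iron": {"meats_eggs_fish": 6, "unrefined_starches": 3, "vegetables": 2,
             "nuts": 4, "mixed_dishes": 2, "ready_to_eat_cereals": 10, "_default": 0.6},
    "magnesium": {"nuts": 12, "unrefined_starches": 5, "vegetables": 2.5,
                  "hot_beverages": 0.4, "water": 0.04, "fresh_fruits": 1.5,
                  "cheese": 1, "_default": 0.6},
    "zinc": {"meats_eggs_fish": 8, "cheese": 5, "unrefined_starches": 3,
             "nuts": 4, "_default": 0.6},
    "potassium": {"vegetables": 5, "fresh_fruits": 4, "unrefined_starches": 3.5,
                  "plain_milk": 2, "meats_eggs_fish": 2.5, "fruit_juices": 4,
                  "hot_beverages": 0.4, "_default": 0.6},
    "copper": {"nuts": 12, "unrefined_starches": 4, "meats_eggs_fish": 3,
               "vegetables": 2, "confectionery": 3, "_default": 0.6},
    "iodine": {"plain_milk": 6, "plain_yogurts": 6, "sweet_yogurts": 5, "cheese": 5,
               "meats_eggs_fish": 6, "sweet_milk": 5, "_default": 0.4},
    "selenium": {"meats_eggs_fish": 10, "refined_starches": 2, "cheese": 3,
                 "unrefined_starches": 2, "_default": 0.4},
    "phosphorus": {"cheese": 6, "meats_eggs_fish": 4, "plain_milk": 3,
                   "plain_yogurts": 3, "unrefined_starches": 2, "_default": 0.8},
    "manganese": {"unrefined_starches": 8, "nuts": 8, "hot_beverages": 1.5,
                  "vegetables": 2, "fresh_fruits": 1.5, "_default": 0.5},
}

# sub-categories that carry no micronutrients beyond their explicit entries
# (water, unsweetened hot drinks, soft drinks, sugar)
_MICRO_POOR = {
    "water", "hot_beverages", "diet_beverages",
    "sugar_sweetened_beverages", "table_sugar",
}

# fraction of the daily recommendation the calibration reference diet provides
_MICRO_COVERAGE = {
    "vitamin_a": 1.20, "vitamin_b1": 1.10, "vitamin_b2": 1.15, "vitamin_b3": 1.30,
    "vitamin_b5": 1.20, "vitamin_b6": 1.15, "vitamin_b9": 1.10, "vitamin_b12": 1.60,
    "vitamin_c": 1.25, "vitamin_d": 1.20, "vitamin_e": 1.15, "calcium": 1.25,
    "iron": 1.15, "magnesium": 1.10, "zinc": 1.15, "potassium": 1.15,
    "copper": 1.20, "iodine": 1.30, "selenium": 1.20, "phosphorus": 1.60,
    "manganese": 1.20,
}

_MICRO_RI = {
    "vitamin_a": 750, "vitamin_b1": 1.2, "vitamin_b2": 1.6, "vitamin_b3": 14,
    "vitamin_b5": 5, "vitamin_b6": 1.8, "vitamin_b9": 330, "vitamin_b12": 2.4,
    "vitamin_c": 110, "vitamin_d": 5, "vitamin_e": 12, "calcium": 900,
    "iron": 12.5, "magnesium": 400, "zinc": 11, "potassium": 3500,
    "copper": 1.5, "iodine": 150, "selenium": 60, "phosphorus": 750,
    "manganese": 2.5,
}

# reference observed sub-category amounts (g/day) per group, used both to
# calibrate micronutrient densities (population-average diet) and as the
# centres of the per-individual Dirichlet-style allocation
_REFERENCE_AMOUNTS = {
    FS_ACCEPTABLE: {
        "fresh_fruits": 178.5, "processed_fruits": 12.3, "vegetables": 245.2,
        "nuts": 2.0, "refined_starches": 181.2, "unrefined_starches": 85.1,
        "ready_to_eat_cereals": 3.6, "meats_eggs_fish": 179.9,
        "mixed_dishes": 70.4, "sandwiches": 47.0, "plain_milk": 80.9,
        "sweet_milk": 4.6, "plain_yogurts": 44.8, "sweet_yogurts": 34.1,
        "cheese": 37.1, "milk_egg_desserts": 12.3, "cakes_pastries": 41.1,
        "biscuits": 4.6, "croissants": 14.2, "confectionery": 3.1,
        "honey_marmalade_spread": 10.4, "table_sugar": 5.5, "water": 821.1,
        "hot_beverages": 403.7, "diet_beverages": 10.2,
        "sugar_sweetened_beverages": 17.0, "fruit_juices": 36.4,
        "added_fats": 28.0, "sauces": 20.1, "soya_foods": 4.0,
    },
    FS_EXCESS: {
        "fresh_fruits": 107.4, "processed_fruits": 15.5, "vegetables": 169.8,
        "nuts": 2.1, "refined_starches": 150.7, "unrefined_starches": 73.9,
        "ready_to_eat_cereals": 6.7, "meats_eggs_fish": 147.9,
        "mixed_dishes": 75.5, "sandwiches": 50.4, "plain_milk": 95.5,
        "sweet_milk": 12.0, "plain_yogurts": 31.7, "sweet_yogurts": 52.0,
        "cheese": 29.8, "milk_egg_desserts": 27.3, "cakes_pastries": 58.9,
        "biscuits": 13.6, "croissants": 22.1, "confectionery": 9.9,
        "honey_marmalade_spread": 18.6, "table_sugar": 11.3, "water": 765.7,
        "hot_beverages": 368.4, "diet_beverages": 16.9,
        "sugar_sweetened_beverages": 128.3, "fruit_juices": 92.8,
        "added_fats": 24.0, "sauces": 17.8, "soya_foods": 2.9,
    },
}

# probability that an individual never consumes the sub-category
_P_SKIP = {
    FS_ACCEPTABLE: {
        "nuts": 0.7, "ready_to_eat_cereals": 0.8, "diet_beverages": 0.85,
        "sugar_sweetened_beverages": 0.6, "soya_foods": 0.9, "sweet_milk": 0.85,
        "processed_fruits": 0.6, "confectionery": 0.6, "biscuits": 0.55,
        "croissants": 0.4, "milk_egg_desserts": 0.5, "honey_marmalade_spread": 0.4,
        "sweet_yogurts": 0.35, "plain_milk": 0.3, "fruit_juices": 0.5,
        "fresh_fruits": 0.1, "cakes_pastries": 0.2, "plain_yogurts": 0.3,
        "mixed_dishes": 0.1, "sandwiches": 0.3, "soups": 0.0,
    },
    FS_EXCESS: {
        "nuts": 0.7, "ready_to_eat_cereals": 0.7, "diet_beverages": 0.8,
        "sugar_sweetened_beverages": 0.25, "soya_foods": 0.9, "sweet_milk": 0.7,
        "processed_fruits": 0.55, "confectionery": 0.4, "biscuits": 0.35,
        "croissants": 0.3, "milk_egg_desserts": 0.35, "honey_marmalade_spread": 0.3,
        "sweet_yogurts": 0.25, "plain_milk": 0.25, "fruit_juices": 0.3,
        "fresh_fruits": 0.2, "cakes_pastries": 0.15, "plain_yogurts": 0.4,
        "mixed_dishes": 0.1, "sandwiches": 0.3,
    },
}

# sub-categories eligible for snacking occasions, in decreasing affinity
_SNACK_AFFINITY = (
    "sugar_sweetened_beverages", "biscuits", "confectionery", "cakes_pastries",
    "croissants", "milk_egg_desserts", "sweet_yogurts", "fruit_juices",
    "sweet_milk", "fresh_fruits", "honey_marmalade_spread", "plain_yogurts",
    "nuts", "ready_to_eat_cereals", "processed_fruits", "sandwiches",
    "plain_milk", "cheese", "hot_beverages",
)

# meal assignment for non-snack foods
_BREAKFAST_SUBCATS = {
    "ready_to_eat_cereals", "croissants", "honey_marmalade_spread",
    "plain_milk", "sweet_milk", "hot_beverages", "table_sugar", "biscuits",
}


def _moment_matched_truncnorm(mean, sd, lower, upper):
    """Parent (mu, sigma) of a truncated normal whose realized mean on
    [lower, upper] equals the target exactly and whose realized SD is as
    close to the target as the family allows.

    A one-sided truncated normal cannot realize SD >= mean - lower (that is
    the exponential limit), so for targets at or beyond that boundary the
    parent scale is capped at 3x the target SD and only the mean is matched
    exactly; the realized SD then falls somewhat short of the target."""

    def realized(mu, log_sigma):
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def eqs(x):
        m, s = realized(*x)
        return [m - mean, s - sd]

    sol = root(eqs, x0=[mean, np.log(sd)], method="hybr")
    if sol.success and np.exp(sol.x[1]) <= 3.0 * sd:
        return float(sol.x[0]), float(np.exp(sol.x[1]))

    # fall back: cap the parent scale, solve the mean exactly
    log_sigma = float(np.log(3.0 * sd))

    def mean_eq(mu):
        return realized(mu, log_sigma)[0] - mean

    lo, hi = lower - 50.0 * sd, upper - 1e-9
    if mean_eq(lo) * mean_eq(hi) > 0:
        raise GenerationError(
            f"cannot match truncated-normal mean {mean} on ({lower}, {upper})"
        )
    mu = brentq(mean_eq, lo, hi, xtol=1e-10)
    return float(mu), float(np.exp(log_sigma))


def _draw_truncnorm(rng, mean, sd, lower, upper, size):
    mu, sigma = _moment_matched_truncnorm(mean, sd, lower, upper)
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# food table
# ---------------------------------------------------------------------------

def _calibrate_micro_densities() -> dict[str, dict[str, float]]:
    """Absolute micronutrient content per 100 g per sub-category, scaled so
    the whole-sample reference diet covers each recommendation at its
    configured coverage factor."""
    # whole-sample reference amounts: 59/41 mixture of the two groups
    ref = {
        sub: 0.59 * _REFERENCE_AMOUNTS[FS_ACCEPTABLE][sub]
        + 0.41 * _REFERENCE_AMOUNTS[FS_EXCESS][sub]
        for sub in _A
    }
    def rel_of(rel, sub):
        if sub in _MICRO_POOR:
            return rel.get(sub, 0.0)
        return rel.get(sub, rel["_default"])

    out: dict[str, dict[str, float]] = {}
    for nutrient, rel in _MICRO_RELATIVE.items():
        weight = sum(ref[sub] / 100.0 * rel_of(rel, sub) for sub in _A)
        scale = _MICRO_COVERAGE[nutrient] * _MICRO_RI[nutrient] / weight
        out[nutrient] = {sub: rel_of(rel, sub) * scale for sub in _A}
    return out


@dataclass
class SyntheticPopulation:
    table: FoodTable
    recipes: dict[str, Recipe]
    individuals: pd.DataFrame  # indexed by individual_id
    diaries: pd.DataFrame  # event rows
    ground_truth: pd.DataFrame  # true group / share / energy targets
    config: GeneratorConfig

    def to_csv(self, out_dir) -> None:
        """Emit the standard CSVs (foods, individuals, diaries, ground truth,
        recipes)."""
        import os

        from .food_composition import write_food_table

        os.makedirs(out_dir, exist_ok=True)
        write_food_table(self.table, os.path.join(out_dir, "foods.csv"))
        self.individuals.to_csv(os.path.join(out_dir, "individuals.csv"),
                                index_label="individual_id")
        self.diaries.to_csv(os.path.join(out_dir, "diaries.csv"), index=False)
        self.ground_truth.to_csv(os.path.join(out_dir, "ground_truth.csv"),
                                 index_label="individual_id")
        rows = [
            {"food_id": r.food_id, "ingredient_id": ing, "weight_fraction": frac}
            for r in self.recipes.values()
            for ing, frac in r.components
        ]
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "recipes.csv"), index=False)


def generate_food_table(
    config: GeneratorConfig, taxonomy: Taxonomy | None = None
) -> tuple[FoodTable, dict[str, Recipe]]:
    """Generate a validated food table with every sub-category populated.

    Sweet products, sugar-sweetened beverages and fruit juices carry high
    free-sugar contents; fresh fruits high intrinsic sugars; water is an
    energy-free drink.  Free sugars are derived through the same rule classes
    as a real table (sugars_equal_free / recipe / expert_zero), with recipes
    expressed as white-sugar weight fractions."""
    taxonomy = taxonomy or load_taxonomy()
    subcats = list(taxonomy.subcategories)
    if config.n_foods < len(subcats):
        raise GenerationError(
            f"n_foods ({config.n_foods}) below the number of sub-categories "
            f"({len(subcats)})"
        )
    rng = np.random.default_rng([config.seed, 101])
    micro_density = _calibrate_micro_densities()
    conv = load_conversion_table()

    # guaranteed minimum per sub-category, extras proportional to weights
    counts = {sub: _MIN_FOODS.get(sub, 1) for sub in subcats}
    base_total = sum(counts.values())
    if config.n_foods < base_total:
        raise GenerationError(
            f"n_foods ({config.n_foods}) below the minimum table size "
            f"({base_total}) needed to field every sub-category variant"
        )
    weights = np.array([_EXTRA_FOOD_WEIGHTS.get(sub, 1) for sub in subcats], float)
    extra = config.n_foods - base_total
    if extra > 0 and weights.sum() > 0:
        picks = rng.choice(len(subcats), size=extra, p=weights / weights.sum())
        for i in picks:
            counts[subcats[i]] += 1

    rows = []
    recipes: dict[str, Recipe] = {}
    for sub in subcats:
        (protein, fat, sfa_frac, sugars, starch, fiber, sodium, chol,
         fs_rule, fs_frac, is_bev, cost) = _A[sub]
        cat = taxonomy.category_of(sub)
        variants = _VARIANTS.get(sub, [{}])
        for k in range(counts[sub]):
            fid = f"{sub}_{k:02d}"
            var = variants[k % len(variants)]
            base = {
                "protein": protein, "fat": fat, "sfa_frac": sfa_frac,
                "sugars": sugars, "starch": starch, "fiber": fiber,
                "sodium": sodium, "cholesterol": chol,
            }
            base.update(var)
            jit = lambda v, s=0.18: v * rng.lognormal(0.0, s) if v > 0 else 0.0
            p, f_ = jit(base["protein"]), jit(base["fat"])
            su, st = jit(base["sugars"]), jit(base["starch"])
            fb, na = jit(base["fiber"]), jit(base["sodium"], 0.25)
            ch = jit(base["cholesterol"], 0.25)
            sf = f_ * min(0.95, max(0.03, base["sfa_frac"] * rng.lognormal(0.0, 0.15)))
            rule = fs_rule
            # the first food of the honey sub-category is honey itself:
            # its sugars are all free by definition
            if sub == "honey_marmalade_spread" and k == 0:
                rule = "sugars_equal_free"
                p, f_, sf, st, fb, ch = 0.3, 0.0, 0.0, 0.0, 0.2, 0.0
                su = jit(80.0, 0.05)
            frac = 0.0
            if rule == "recipe":
                frac = round(min(0.996, fs_frac * rng.lognormal(0.0, 0.10)), 6)
                recipes[fid] = Recipe(fid, (("white_sugar", frac),))
                fs = 100.0 * frac
                su = max(su, fs * 1.02)  # analyzed sugars cover the estimate
            elif rule == "sugars_equal_free":
                fs = su
            else:
                fs = 0.0
            carb = su + st  # exact carbohydrate closure
            energy = 4.0 * (p + carb) + 9.0 * f_
            row = {
                "food_id": fid,
                "name": f"{sub.replace('_', ' ')} {k + 1}",
                "category": cat,
                "subcategory": sub,
                "energy": energy,
                "protein": p,
                "fat": f_,
                "saturated_fat": sf,
                "carbohydrate": carb,
                "starch": st,
                "total_sugars": su,
                "free_sugars": fs,
                "fiber": fb,
                "sodium": na,
                "cholesterol": ch,
                "is_beverage": is_bev,
                "is_energy_free_drink": bool(is_bev and energy < 4.0),
                "is_alcoholic": False,
                "unit_cost": cost * rng.lognormal(0.0, 0.15),
                "free_sugar_rule": rule,
            }
            for n in MICRONUTRIENTS:
                row[n] = micro_density[n][sub] * rng.lognormal(0.0, 0.25)
            rows.append(row)
    df = pd.DataFrame(rows).set_index("food_id")

    # normalize each micronutrient column against the *realized* table so the
    # reference diet's coverage matches the calibration target regardless of
    # the per-food draws (removes table-level sampling luck)
    ref = {
        sub: 0.59 * _REFERENCE_AMOUNTS[FS_ACCEPTABLE][sub]
        + 0.41 * _REFERENCE_AMOUNTS[FS_EXCESS][sub]
        for sub in _A
    }
    sub_means = df.groupby("subcategory")[list(MICRONUTRIENTS)].mean()
    for n in MICRONUTRIENTS:
        realized = sum(
            ref[sub] / 100.0 * float(sub_means.loc[sub, n]) for sub in _A
        )
        target = _MICRO_COVERAGE[n] * _MICRO_RI[n]
        if realized > 0:
            df[n] *= target / realized
    return FoodTable(df, taxonomy), recipes


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _select_repertoire(rng, sub_foods, group, base_amounts):
    """Pick foods and base daily amounts (g/day) for one individual."""
    p_skip = _P_SKIP[group]
    amounts: dict[str, float] = {}
    mandatory = {"refined_starches", "water", "table_sugar", "vegetables",
                 "meats_eggs_fish", "hot_beverages", "added_fats", "cheese"}
    for sub, foods in sub_foods.items():
        skip = p_skip.get(sub, 0.05)
        if sub in mandatory:
            skip = 0.0
        if rng.random() < skip:
            continue
        consumer_mean = base_amounts[sub] / (1.0 - skip) if skip < 1 else 0.0
        # gamma multiplicative noise, CV ~ 0.45
        amt = consumer_mean * rng.gamma(5.0, 1.0 / 5.0)
        if amt <= 0:
            continue
        k = min(len(foods), 1 + rng.poisson(1.6))
        chosen = rng.choice(len(foods), size=k, replace=False)
        shares = rng.dirichlet(np.full(k, 2.0))
        for idx, share in zip(chosen, shares):
            if amt * share > 0.1:
                amounts[foods[idx]] = amt * share
    return amounts


def generate_population(
    config: GeneratorConfig,
    table: FoodTable | None = None,
    recipes: dict[str, Recipe] | None = None,
) -> SyntheticPopulation:
    """Generate a full synthetic survey: diaries, demographics, weights and
    ground-truth labels.  Identical configuration (including seed) yields
    identical output."""
    if table is None:
        table, recipes = generate_food_table(config)
    rng = np.random.default_rng([config.seed, 202])

    tbl = table.df
    sub_foods = {
        sub: list(tbl.index[tbl["subcategory"] == sub])
        for sub in table.taxonomy.subcategories
    }
    energy_per_g = tbl["energy"] / 100.0
    fs_per_g = tbl["free_sugars"] / 100.0

    n = config.n_individuals
    if config.force_group is not None:
        groups = np.array([config.force_group] * n)
    else:
        groups = np.where(rng.random(n) < config.p_excess, FS_EXCESS, FS_ACCEPTABLE)

    # draw all group-level targets up front (vectorized, deterministic order)
    shares = np.empty(n)
    energies = np.empty(n)
    snack_targets = np.empty(n)
    ages = np.empty(n)
    genders = np.empty(n, dtype=object)
    for gname, gp in config.groups.items():
        mask = groups == gname
        k = int(mask.sum())
        if k == 0:
            continue
        shares[mask] = _draw_truncnorm(
            rng, gp.fs_share_mean, gp.fs_share_sd,
            gp.fs_share_lower, gp.fs_share_upper, k,
        )
        # the energy distribution emulates a plausibility-screened cohort:
        # truncated normal (no under- or gross over-reporters), moment-matched
        energies[mask] = _draw_truncnorm(
            rng, gp.energy_mean, gp.energy_sd, 1500.0, 3700.0, k
        )
        shape = (gp.snack_energy_mean / gp.snack_energy_sd) ** 2
        scale = gp.snack_energy_sd**2 / gp.snack_energy_mean
        snack_targets[mask] = rng.gamma(shape, scale, k)
        ages[mask] = np.clip(rng.normal(gp.age_mean, gp.age_sd, k), 20.0, 75.0)
        genders[mask] = np.where(
            rng.random(k) < gp.p_female, "female", "male"
        )
    snack_targets = np.clip(snack_targets, 5.0, 0.45 * energies)
    survey_weights = rng.lognormal(0.0, 0.5, n)
    survey_weights /= survey_weights.mean()

    heights = np.where(
        genders == "male",
        rng.normal(1.76, 0.07, n),
        rng.normal(1.63, 0.065, n),
    )
    bmi_mean = np.where(groups == FS_EXCESS, 23.6, 25.2)
    bmis = np.clip(rng.normal(bmi_mean, 4.0, n), 16.5, 42.0)
    weights_kg = bmis * heights**2
    pal = rng.choice(
        np.array(["low", "moderate", "high"], dtype=object),
        size=n,
        p=[0.226, 0.305, 0.469],
    )

    diary_frames = []
    truth_rows = []
    ind_rows = []
    for i in range(n):
        ind_id = f"ind{i:05d}"
        group = groups[i]
        s, E, Es = float(shares[i]), float(energies[i]), float(snack_targets[i])
        amounts = _select_repertoire(
            rng, sub_foods, group, _REFERENCE_AMOUNTS[group]
        )
        foods = list(amounts)
        a = np.array([amounts[f] for f in foods])
        e = energy_per_g.loc[foods].to_numpy()
        fs = fs_per_g.loc[foods].to_numpy()
        lever = (tbl.loc[foods, "subcategory"] == "table_sugar").to_numpy()

        # scale to the drawn energy, then set the free-sugar share exactly by
        # rescaling sugar-bearing foods against the table-sugar lever
        a = _fit_energy_and_share(a, e, fs, E, s, lever, ind_id)

        # per-day amounts: gamma jitter, then the same exact fit per day
        day_amounts = np.empty((N_DAYS, len(foods)))
        for d in range(N_DAYS):
            jit = rng.gamma(16.0, 1.0 / 16.0, len(foods))
            day_amounts[d] = _fit_energy_and_share(a * jit, e, fs, E, s, lever, ind_id)

        moments = _assign_moments(
            rng, foods, tbl, day_amounts.mean(axis=0), e, Es
        )
        diary_frames.append(
            _events_frame(ind_id, foods, day_amounts, moments)
        )
        truth_rows.append(
            {
                "individual_id": ind_id,
                "true_group": group,
                "true_fs_share": s,
                "target_energy": E,
                "target_snack_energy": Es,
            }
        )
        ind_rows.append(
            {
                "individual_id": ind_id,
                "age": round(float(ages[i]), 1),
                "gender": genders[i],
                "weight_kg": round(float(weights_kg[i]), 1),
                "height_m": round(float(heights[i]), 3),
                "physical_activity": pal[i],
                "survey_weight": float(survey_weights[i]),
            }
        )

    individuals = pd.DataFrame(ind_rows).set_index("individual_id")
    diaries = pd.concat(diary_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows).set_index("individual_id")
    return SyntheticPopulation(
        table=table,
        recipes=recipes or {},
        individuals=individuals,
        diaries=diaries,
        ground_truth=truth,
        config=config,
    )


def _fit_energy_and_share(a, e, fs, E, s, lever, ind_id):
    """Rescale amounts so total energy is E and the free-sugar energy share is
    s (%), exactly.

    Non-lever free-sugar foods are scaled as a block within safe bounds, the
    residual free-sugar gap is closed with the (nearly pure sugar) lever food,
    and sugar-free energy-bearing foods absorb the energy difference.
    Zero-energy foods (water, diet drinks) are untouched."""
    a = a.copy()
    total_e = float(a @ e)
    if total_e <= 0:
        raise GenerationError(f"{ind_id}: diet has no energy")
    a *= E / total_e
    g_target = s / 100.0 * E / FS_KCAL_PER_G
    sweet = (fs > 0) & ~lever
    other = (fs <= 0) & (e > 0) & ~lever
    g_sweet = float(a[sweet] @ fs[sweet])
    e_sweet = float(a[sweet] @ e[sweet])
    fs_l = float(a[lever] @ fs[lever])
    e_other = float(a[other] @ e[other])
    if fs_l <= 0 or e_other <= 0:
        raise GenerationError(
            f"{ind_id}: repertoire lacks a sugar lever or sugar-free energy "
            f"foods; regenerate the food table or repertoire"
        )
    # scale the sweet block toward the target, keeping its energy below half
    # the total so the energy rebalance stays positive
    if g_sweet > 0:
        lam = np.clip(
            g_target / (g_sweet + fs_l),
            0.01,
            min(3.0, 0.5 * E / e_sweet) if e_sweet > 0 else 3.0,
        )
    else:
        lam = 1.0
    # lever closes the gap exactly (fs and energy of the lever scale together)
    need = g_target - lam * g_sweet
    if need <= 0:
        # sweet block alone overshoots even at the clip floor: shrink it to
        # the exact target and drop the lever to (near) zero
        lam = g_target / g_sweet * 0.98
        need = g_target - lam * g_sweet
    kappa = need / fs_l  # lever amount multiplier
    e_fs_total = lam * e_sweet + kappa * float(a[lever] @ e[lever])
    if e_fs_total >= 0.95 * E:
        raise GenerationError(
            f"{ind_id}: free-sugar share {s:.1f}%E unattainable with this "
            f"repertoire; regenerate the food table or repertoire"
        )
    mu = (E - e_fs_total) / e_other
    a[sweet] *= lam
    a[lever] *= kappa
    a[other] *= mu
    return a


def _assign_moments(rng, foods, tbl, mean_amounts, e, snack_energy):
    """Map each food to a (moment, fraction) allocation so snack energy hits
    the target; the marginal food is split between a snack and a meal."""
    sub = tbl.loc[foods, "subcategory"]
    affinity = {s_: i for i, s_ in enumerate(_SNACK_AFFINITY)}
    snackable = [
        j for j in range(len(foods)) if sub.iloc[j] in affinity
    ]
    snackable.sort(key=lambda j: (affinity[sub.iloc[j]], foods[j]))
    food_energy = mean_amounts * e
    snack_moments = list(SNACK_MOMENTS)
    out: dict[int, list[tuple[str, float]]] = {}
    acc = 0.0
    mi = 0
    for j in snackable:
        if acc >= snack_energy:
            break
        fe = food_energy[j]
        moment = snack_moments[mi % 3]
        mi += 1
        if fe <= 0:
            continue
        if acc + fe <= snack_energy:
            out[j] = [(moment, 1.0)]
            acc += fe
        else:
            # split the marginal food between the snack and a meal
            frac = (snack_energy - acc) / fe
            out[j] = [(moment, frac), ("_meal", 1.0 - frac)]
            acc = snack_energy
    meal_cycle = ["lunch", "dinner"]
    ci = 0
    for j in range(len(foods)):
        alloc = out.get(j, [("_meal", 1.0)])
        fixed = []
        for moment, frac in alloc:
            if moment == "_meal":
                if sub.iloc[j] in _BREAKFAST_SUBCATS:
                    moment = "breakfast"
                elif sub.iloc[j] == "water":
                    moment = "lunch"
                else:
                    moment = meal_cycle[ci % 2]
                    ci += 1
            fixed.append((moment, frac))
        out[j] = fixed
    return out


def _events_frame(ind_id, foods, day_amounts, moments):
    rows = []
    for d in range(N_DAYS):
        for j, fid in enumerate(foods):
            amt = day_amounts[d, j]
            if amt <= 0:
                continue
            for moment, frac in moments[j]:
                if frac <= 0:
                    continue
                rows.append((ind_id, d + 1, moment, fid, amt * frac))
    return pd.DataFrame(
        rows, columns=["individual_id", "day", "moment", "food_id", "amount_g"]
    )


# ---------------------------------------------------------------------------
# moment report
# ---------------------------------------------------------------------------

def moment_report(population: SyntheticPopulation) -> pd.DataFrame:
    """Realized vs target first moments per group (energy, free-sugar share,
    snacking energy), flagging deviations beyond 3 standard errors."""
    from .survey_records import intake_profile, records_from_frames

    records = records_from_frames(population.individuals, population.diaries)
    table = population.table
    rows = []
    truth = population.ground_truth
    realized = {}
    for rec in records:
        prof = intake_profile(rec, table)
        realized[rec.individual_id] = (
            prof.energy,
            100.0 * FS_KCAL_PER_G * prof.free_sugars / prof.energy,
            prof.energy_snacks,
        )
    df = pd.DataFrame.from_dict(
        realized, orient="index", columns=["energy", "fs_share", "snack_energy"]
    )
    df["group"] = truth["true_group"]
    for gname, gp in population.config.groups.items():
        grp = df[df["group"] == gname]
        m = len(grp)
        if m == 0:
            continue
        for var, target, target_sd in (
            ("energy", gp.energy_mean, gp.energy_sd),
            ("fs_share", gp.fs_share_mean, gp.fs_share_sd),
            ("snack_energy", gp.snack_energy_mean, gp.snack_energy_sd),
        ):
            mean = float(grp[var].mean())
            sd = float(grp[var].std(ddof=1)) if m > 1 else float("nan")
            se = sd / np.sqrt(m) if m > 1 else float("nan")
            flagged = bool(m > 1 and abs(mean - target) > 3.0 * se)
            rows.append(
                {
                    "group": gname,
                    "variable": var,
                    "n": m,
                    "realized_mean": mean,
                    "realized_sd": sd,
                    "target_mean": target,
                    "flag": flagged,
                }
            )
    return pd.DataFrame(rows)
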