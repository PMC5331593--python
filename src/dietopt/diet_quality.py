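"""Diet-quality indicators: solid energy density, variety, MAR, MER and the
probabilistic adequacy score (PANDiet).

MAR (mean adequacy ratio) averages, over 23 key nutrients, the percentage of
the recommended intake achieved over the week, each capped at 100%.  MER (mean
excess ratio) averages the percentage points *above* the maximum recommended
value for sodium, saturated fatty acids and free sugars (no credit below the
maximum).  The PANDiet-style score averages per-nutrient probabilities of
adequate usual intake under a Gaussian model whose variance combines the
inter-individual requirement variance and the within-person day-to-day
variance of intake shrunk by the number of diary days.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .food_composition import FoodTable
from .survey_records import (
    FS_KCAL_PER_G,
    N_DAYS,
    IndividualRecord,
    IntakeProfile,
    daily_intake_table,
)

__all__ = [
    "NutrientReference",
    "ReferenceSet",
    "QualityScores",
    "DietQualityError",
    "AllBeverageDietError",
    "load_nutrient_references",
    "solid_energy_density",
    "variety",
    "mar",
    "mer",
    "pandiet",
    "quality_scores",
]


class DietQualityError(ValueError):
    pass


class AllBeverageDietError(DietQualityError):
    """Solid energy density is undefined for an all-beverage diet."""


@dataclass(frozen=True)
class NutrientReference:
    nutrient_id: str
    role: str  # adequacy | moderation
    recommended_intake: float | None = None  # MAR basis
    ear: float | None = None  # average requirement (PANDiet adequacy basis)
    requirement_cv: float = 0.15
    max_value: float | None = None  # MER / moderation basis
    basis: str = "absolute"  # absolute | percent_energy
    kcal_per_g: float | None = None
    units: str = ""

    def max_grams(self, energy: float) -> float:
        """Maximum recommended amount per day at a given energy intake."""
        if self.max_value is None:
            raise DietQualityError(f"{self.nutrient_id}: no maximum on file")
        if self.max_value <= 0:
            raise DietQualityError(f"{self.nutrient_id}: non-positive maximum")
        if self.basis == "percent_energy":
            return self.max_value / 100.0 * energy / self.kcal_per_g
        return self.max_value


@dataclass(frozen=True)
class ReferenceSet:
    """Nutrient references plus the index lists for each score."""

    references: dict[str, NutrientReference]
    mar_nutrients: tuple[str, ...]
    mer_nutrients: tuple[str, ...]
    pandiet_adequacy: tuple[str, ...]
    pandiet_moderation: tuple[str, ...]

    def __getitem__(self, nutrient_id: str) -> NutrientReference:
        return self.references[nutrient_id]


def load_nutrient_references(path=None) -> ReferenceSet:
    """Load the reference configuration (packaged defaults: 23 MAR nutrients,
    3 MER nutrients, 25 PANDiet nutrients)."""
    if path is None:
        src = importlib.resources.files("dietopt.config").joinpath(
            "nutrient_references.yaml"
        )
        with src.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    refs: dict[str, NutrientReference] = {}
    for nid, spec in raw["adequacy"].items():
        refs[nid] = NutrientReference(
            nutrient_id=nid,
            role="adequacy",
            recommended_intake=spec["recommended_intake"],
            ear=spec.get("ear"),
            requirement_cv=spec.get("requirement_cv", 0.15),
            units=spec.get("units", ""),
        )
    for nid, spec in raw["moderation"].items():
        refs[nid] = NutrientReference(
            nutrient_id=nid,
            role="moderation",
            max_value=spec["max_value"],
            basis=spec.get("basis", "absolute"),
            kcal_per_g=spec.get("kcal_per_g"),
            requirement_cv=spec.get("requirement_cv", 0.15),
            units=spec.get("units", ""),
        )
    return ReferenceSet(
        references=refs,
        mar_nutrients=tuple(raw["mar_nutrients"]),
        mer_nutrients=tuple(raw["mer_nutrients"]),
        pandiet_adequacy=tuple(raw["pandiet_adequacy"]),
        pandiet_moderation=tuple(raw["pandiet_moderation"]),
    )


@dataclass(frozen=True)
class QualityScores:
    sed: float  # kcal/100 g
    variety: int  # distinct foods over the week
    mar: float  # % in [0, 100]
    mer: float  # % >= 0
    pandiet: float  # score in [0, 100]


def solid_energy_density(diet: pd.Series, table: FoodTable) -> float:
    """Energy of solid foods divided by their weight, kcal/100 g.

    Solid means not flagged as a beverage; soups count as solid, drinking
    water and items typically drunk (milk, juices, soft drinks) do not."""
    if len(diet) == 0:
        raise AllBeverageDietError("empty diet")
    solid = ~table.df.loc[diet.index, "is_beverage"].to_numpy(bool)
    grams = diet.to_numpy()[solid]
    if grams.sum() <= 0:
        raise AllBeverageDietError("no solid food in the diet")
    energy = (diet.to_numpy() * table.df.loc[diet.index, "energy"].to_numpy() / 100.0)[
        solid
    ]
    return 100.0 * float(energy.sum()) / float(grams.sum())


def variety(record: IndividualRecord) -> int:
    """Number of different foods declared over the 7 days (beverages and
    water included)."""
    if len(record.events) == 0:
        return 0
    return int(record.events["food_id"].nunique())


def mar(profile: IntakeProfile, refs: ReferenceSet) -> float:
    """Mean adequacy ratio over the configured key nutrients, %."""
    ratios = []
    for nid in refs.mar_nutrients:
        if nid not in profile.nutrients.index:
            raise DietQualityError(f"intake profile lacks nutrient {nid!r}")
        rec = refs[nid].recommended_intake
        ratios.append(min(100.0, 100.0 * float(profile.nutrients[nid]) / rec))
    return float(np.mean(ratios))


def mer(profile: IntakeProfile, refs: ReferenceSet) -> float:
    """Mean excess ratio over sodium, saturated fat and free sugars, %.

    Nutrients below their maximum contribute 0 (an excess cannot be
    negative)."""
    excesses = []
    for nid in refs.mer_nutrients:
        if nid not in profile.nutrients.index:
            raise DietQualityError(f"intake profile lacks nutrient {nid!r}")
        max_n = refs[nid].max_grams(profile.energy)
        excesses.append(max(0.0, 100.0 * float(profile.nutrients[nid]) / max_n - 100.0))
    return float(np.mean(excesses))


def _adequacy_probability(mean, ear, cv, within_var, n_days):
    sd = np.sqrt((cv * ear) ** 2 + within_var / n_days)
    if sd == 0:
        return 0.5 if mean == ear else (1.0 if mean > ear else 0.0)
    return float(norm.cdf((mean - ear) / sd))


def _moderation_probability(mean, ref, cv, within_var, n_days):
    sd = np.sqrt((cv * ref) ** 2 + within_var / n_days)
    if sd == 0:
        return 0.5 if mean == ref else (1.0 if mean < ref else 0.0)
    return float(norm.cdf((ref - mean) / sd))


def pandiet(daily_intakes: pd.DataFrame, refs: ReferenceSet) -> float:
    """Probabilistic diet-quality score in [0, 100].

    *daily_intakes* holds one row per diary day and one column per nutrient
    (g or reference units/day; must include ``energy``).  The adequacy
    sub-score averages P(usual intake >= requirement) over the adequacy
    nutrients; the moderation sub-score averages P(usual intake <= maximum)
    over sodium, saturated fat and free sugars (percent-energy maxima are
    taken at the individual's mean energy).  The score is 100 x the mean of
    the two sub-scores."""
    if len(daily_intakes) < 2:
        raise DietQualityError("need at least 2 days to estimate day-to-day variance")
    n_days = len(daily_intakes)
    means = daily_intakes.mean()
    wvars = daily_intakes.var(ddof=1)
    energy = float(means["energy"])
    p_adeq = [
        _adequacy_probability(
            float(means[nid]),
            refs[nid].ear,
            refs[nid].requirement_cv,
            float(wvars[nid]),
            n_days,
        )
        for nid in refs.pandiet_adequacy
    ]
    p_mod = [
        _moderation_probability(
            float(means[nid]),
            refs[nid].max_grams(energy),
            refs[nid].requirement_cv,
            float(wvars[nid]),
            n_days,
        )
        for nid in refs.pandiet_moderation
    ]
    return 100.0 * (float(np.mean(p_adeq)) + float(np.mean(p_mod))) / 2.0


def quality_scores(
    record: IndividualRecord,
    diet: pd.Series,
    profile: IntakeProfile,
    table: FoodTable,
    refs: ReferenceSet | None = None,
) -> QualityScores:
    """All five indicators for one individual's observed diet."""
    refs = refs or load_nutrient_references()
    daily = daily_intake_table(record, table)
    return QualityScores(
        sed=solid_energy_density(diet, table),
        variety=variety(record),
        mar=mar(profile, refs),
        mer=mer(profile, refs),
        pandiet=pandiet(daily, refs),
    )
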