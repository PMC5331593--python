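"""Seven-day diet diaries: intake computation, plausibility screening and
free-sugar group classification.

A diary records one row per consumption event (individual, day 1-7, moment,
food, grams), with six moments: three main meals (breakfast, lunch, dinner)
and three between-meal snacking occasions (morning, afternoon, evening).
Alcoholic beverages are excluded from diet vectors and all downstream
quantities, since nutrient recommendations apply to non-alcoholic intakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .food_composition import NUTRIENT_COLUMNS, FoodTable

__all__ = [
    "MOMENTS",
    "MEAL_MOMENTS",
    "SNACK_MOMENTS",
    "FS_KCAL_PER_G",
    "ConsumptionEvent",
    "IndividualRecord",
    "IntakeProfile",
    "GoldbergParams",
    "SurveyError",
    "build_diet_vector",
    "compute_intakes",
    "intake_profile",
    "daily_intake_table",
    "goldberg_screen",
    "classify_fs_group",
    "free_sugar_energy_share",
    "load_individuals",
    "load_diaries",
]

MEAL_MOMENTS = ("breakfast", "lunch", "dinner")
SNACK_MOMENTS = ("morning_snack", "afternoon_snack", "evening_snack")
MOMENTS = MEAL_MOMENTS + SNACK_MOMENTS

#: energy conversion for free sugars (Atwater factor for carbohydrate)
FS_KCAL_PER_G = 4.0

N_DAYS = 7


class SurveyError(ValueError):
    """Raised for invalid diaries, records or classification inputs."""


@dataclass(frozen=True)
class ConsumptionEvent:
    individual_id: str
    day: int
    moment: str
    food_id: str
    amount: float  # g

    def __post_init__(self):
        if not 1 <= self.day <= N_DAYS:
            raise SurveyError(f"day must be in [1, {N_DAYS}]: {self.day}")
        if self.moment not in MOMENTS:
            raise SurveyError(f"unknown moment: {self.moment!r}")
        if self.amount < 0:
            raise SurveyError(f"negative amount: {self.amount}")


@dataclass
class IndividualRecord:
    """Demographics, survey weight and the 7-day event table.

    ``events`` is a DataFrame with columns day, moment, food_id, amount_g
    (list of :class:`ConsumptionEvent` also accepted)."""

    individual_id: str
    age: float
    gender: str  # male | female
    weight: float | None  # kg
    height: float | None  # m
    physical_activity: str  # low | moderate | high
    survey_weight: float
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if isinstance(self.events, list):
            self.events = pd.DataFrame(
                [
                    {
                        "day": e.day,
                        "moment": e.moment,
                        "food_id": e.food_id,
                        "amount_g": e.amount,
                    }
                    for e in self.events
                ]
            )
        if self.survey_weight <= 0:
            raise SurveyError(f"{self.individual_id}: non-positive survey weight")

    def validate(self, age_bounds=(20, 75)) -> "IndividualRecord":
        if not age_bounds[0] <= self.age <= age_bounds[1]:
            raise SurveyError(
                f"{self.individual_id}: age {self.age} outside {age_bounds}"
            )
        days = set(self.events["day"]) if len(self.events) else set()
        if days != set(range(1, N_DAYS + 1)):
            raise SurveyError(
                f"{self.individual_id}: diary must span all {N_DAYS} days, "
                f"got days {sorted(days)}"
            )
        if (self.events["amount_g"] < 0).any():
            raise SurveyError(f"{self.individual_id}: negative event amount")
        if not self.events["moment"].isin(MOMENTS).all():
            raise SurveyError(f"{self.individual_id}: unknown moment token")
        return self


@dataclass
class IntakeProfile:
    """Mean daily nutrient intakes, with meal/snack sub-totals.

    ``nutrients`` maps nutrient_id -> mean daily intake (energy kcal/day,
    masses g/day, sodium and cholesterol and most micronutrients in the units
    of the composition table).  ``non_free_sugars`` is total minus free by
    construction."""

    nutrients: pd.Series
    energy_meals: float = float("nan")
    energy_snacks: float = float("nan")
    free_sugars_meals: float = float("nan")
    free_sugars_snacks: float = float("nan")

    @property
    def energy(self) -> float:
        return float(self.nutrients["energy"])

    @property
    def free_sugars(self) -> float:
        return float(self.nutrients["free_sugars"])

    @property
    def non_free_sugars(self) -> float:
        return float(self.nutrients["total_sugars"] - self.nutrients["free_sugars"])

    def __getitem__(self, nutrient_id: str) -> float:
        return float(self.nutrients[nutrient_id])


def _resolve(events: pd.DataFrame, table: FoodTable) -> pd.DataFrame:
    unknown = set(events["food_id"]) - set(table.food_ids)
    if unknown:
        raise SurveyError(f"events reference unknown foods: {sorted(unknown)}")
    return events


def build_diet_vector(record: IndividualRecord, table: FoodTable) -> pd.Series:
    """Mean daily amount (g/day) per food over the 7 diary days.

    Alcoholic beverages are excluded (they are not optimizable and are
    tracked separately when needed)."""
    if len(record.events) == 0:
        return pd.Series(dtype=float, name=record.individual_id)
    ev = _resolve(record.events, table)
    alco = table.df["is_alcoholic"]
    ev = ev[~ev["food_id"].map(alco).astype(bool)]
    vec = ev.groupby("food_id")["amount_g"].sum() / N_DAYS
    vec.name = record.individual_id
    return vec


def compute_intakes(
    diet: pd.Series,
    table: FoodTable,
    events: pd.DataFrame | None = None,
) -> IntakeProfile:
    """Nutrient intakes of a diet vector: nutrient = sum_f amount_f * content / 100.

    If *events* are given, meal vs snacking sub-totals of energy and free
    sugars are computed from them (as 7-day means)."""
    if len(diet) == 0:
        nutrients = pd.Series(0.0, index=list(NUTRIENT_COLUMNS))
        return IntakeProfile(nutrients, 0.0, 0.0, 0.0, 0.0)
    contents = table.nutrient_matrix().loc[diet.index]
    nutrients = contents.mul(diet, axis=0).sum() / 100.0
    prof = IntakeProfile(nutrients)
    if events is not None and len(events):
        ev = _resolve(events, table)
        ev = ev[~ev["food_id"].map(table.df["is_alcoholic"]).astype(bool)]
        e = ev["food_id"].map(table.df["energy"]).to_numpy()
        fs = ev["food_id"].map(table.df["free_sugars"]).to_numpy()
        amt = ev["amount_g"].to_numpy()
        is_meal = ev["moment"].isin(MEAL_MOMENTS).to_numpy()
        prof.energy_meals = float((amt * e / 100.0)[is_meal].sum()) / N_DAYS
        prof.energy_snacks = float((amt * e / 100.0)[~is_meal].sum()) / N_DAYS
        prof.free_sugars_meals = float((amt * fs / 100.0)[is_meal].sum()) / N_DAYS
        prof.free_sugars_snacks = float((amt * fs / 100.0)[~is_meal].sum()) / N_DAYS
    return prof


def intake_profile(record: IndividualRecord, table: FoodTable) -> IntakeProfile:
    """Convenience: diet vector + intakes with moment sub-totals."""
    return compute_intakes(build_diet_vector(record, table), table, record.events)


def daily_intake_table(record: IndividualRecord, table: FoodTable) -> pd.DataFrame:
    """Per-day nutrient intakes (7 rows x nutrients), for day-to-day variance
    estimation.  Alcoholic beverages excluded."""
    ev = _resolve(record.events, table)
    ev = ev[~ev["food_id"].map(table.df["is_alcoholic"]).astype(bool)]
    contents = table.nutrient_matrix().loc[ev["food_id"]].to_numpy()
    daily = pd.DataFrame(
        contents * ev["amount_g"].to_numpy()[:, None] / 100.0,
        columns=list(NUTRIENT_COLUMNS),
    )
    daily["day"] = ev["day"].to_numpy()
    out = daily.groupby("day").sum()
    return out.reindex(range(1, N_DAYS + 1), fill_value=0.0)


# ---------------------------------------------------------------------------
# Goldberg plausibility screen
# ---------------------------------------------------------------------------

#: Schofield basal-metabolic-rate equations, kcal/day from weight in kg,
#: keyed by (gender, age band)
SCHOFIELD = {
    ("male", 0): (15.057, 692.2),  # 18-30 y
    ("male", 1): (11.472, 873.1),  # 30-60 y
    ("male", 2): (11.711, 587.7),  # >60 y
    ("female", 0): (14.818, 486.6),
    ("female", 1): (8.126, 845.6),
    ("female", 2): (9.082, 658.5),
}


@dataclass(frozen=True)
class GoldbergParams:
    """Parameters of the Goldberg/Black energy-reporting plausibility cutoff.

    The lower cutoff on r = reported energy / BMR is
    ``PAL * exp(-z * S / 100)`` with
    ``S = sqrt(cv_intake^2 / d + cv_bmr^2 + cv_pal^2)``."""

    pal_by_activity: dict = field(
        default_factory=lambda: {"low": 1.55, "moderate": 1.7, "high": 1.9}
    )
    cv_intake: float = 23.0  # within-person CV of energy intake, %
    cv_bmr: float = 8.5  # CV of BMR estimation, %
    cv_pal: float = 15.0  # between-person CV of PAL, %
    z: float = 2.0
    n_days: int = N_DAYS

    def cutoff(self, pal: float) -> float:
        s = np.sqrt(self.cv_intake**2 / self.n_days + self.cv_bmr**2 + self.cv_pal**2)
        return pal * float(np.exp(-self.z * s / 100.0))


def basal_metabolic_rate(record: IndividualRecord) -> float:
    """Schofield BMR (kcal/day) from gender, age and body weight."""
    if record.weight is None:
        raise SurveyError(f"{record.individual_id}: missing body weight")
    band = 0 if record.age < 30 else (1 if record.age < 60 else 2)
    a, b = SCHOFIELD[(record.gender, band)]
    return a * record.weight + b


def goldberg_screen(
    record: IndividualRecord,
    reported_energy: float,
    params: GoldbergParams | None = None,
) -> str:
    """Classify a record as ``plausible`` / ``under_reporter`` / ``unscreenable``.

    Under-reporting is flagged when reported energy falls below the Goldberg
    lower cutoff times the Schofield BMR."""
    params = params or GoldbergParams()
    if record.weight is None or record.height is None:
        return "unscreenable"
    bmr = basal_metabolic_rate(record)
    pal = params.pal_by_activity[record.physical_activity]
    ratio = reported_energy / bmr
    return "under_reporter" if ratio < params.cutoff(pal) else "plausible"


# ---------------------------------------------------------------------------
# Free-sugar group classification
# ---------------------------------------------------------------------------

FS_ACCEPTABLE = "FS_ACCEPTABLE"
FS_EXCESS = "FS_EXCESS"


def free_sugar_energy_share(profile: IntakeProfile) -> float:
    """% of energy from free sugars (4 kcal/g)."""
    if profile.energy <= 0:
        raise SurveyError("energy intake must be positive")
    return 100.0 * FS_KCAL_PER_G * profile.free_sugars / profile.energy


def classify_fs_group(profile: IntakeProfile) -> str:
    """FS_EXCESS if free sugars exceed 10% of energy; the 10% boundary itself
    is FS_ACCEPTABLE."""
    return FS_EXCESS if free_sugar_energy_share(profile) > 10.0 else FS_ACCEPTABLE


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def load_individuals(path) -> pd.DataFrame:
    """Individuals CSV: individual_id, age, gender, weight_kg, height_m,
    physical_activity, survey_weight (+ pass-through columns)."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    return df.set_index("individual_id")


def load_diaries(path) -> pd.DataFrame:
    """Diary CSV: individual_id, day, moment, food_id, amount_g."""
    df = pd.read_csv(path, dtype={"individual_id": str, "food_id": str})
    bad = df.loc[~df["moment"].isin(MOMENTS), "moment"].unique()
    if len(bad):
        raise SurveyError(f"unknown moment tokens: {list(bad)}")
    return df


def records_from_frames(
    individuals: pd.DataFrame, diaries: pd.DataFrame
) -> list[IndividualRecord]:
    """Assemble IndividualRecords from the two standard CSV frames."""
    by_id = dict(tuple(diaries.groupby("individual_id", sort=False)))
    records = []
    for ind_id, row in individuals.iterrows():
        ev = by_id.get(ind_id, pd.DataFrame(columns=["day", "moment", "food_id", "amount_g"]))
        records.append(
            IndividualRecord(
                individual_id=str(ind_id),
                age=float(row["age"]),
                gender=str(row["gender"]),
                weight=float(row["weight_kg"]) if "weight_kg" in row and pd.notna(row["weight_kg"]) else None,
                height=float(row["height_m"]) if "height_m" in row and pd.notna(row["height_m"]) else None,
                physical_activity=str(row.get("physical_activity", "moderate")),
                survey_weight=float(row["survey_weight"]),
                events=ev.reset_index(drop=True),
            )
        )
    return records
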