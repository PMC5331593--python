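"""Survey-weighted descriptive comparison of observed vs optimized diets.

Two views mirror the study's figure logic: per-category (and sub-category)
weight changes in g/day, and the decomposition of the total-sugar change into
free and non-free sugars per contributing food category.  All summaries are
Hajek-weighted (weights normalized by their sum); no model adjustment or
design-based variance estimation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .food_composition import FoodTable

__all__ = [
    "ReportingError",
    "SugarBalance",
    "weighted_summary",
    "weight_changes",
    "sugar_balance",
    "group_summary_table",
]


class ReportingError(ValueError):
    pass


def weighted_summary(values, weights) -> tuple[float, float]:
    """Hajek-weighted mean and SD.

    The weighted SD uses the frequency-weight normalization
    sqrt(sum w (x - m)^2 / (W - W2/W)) which reduces to the ordinary
    sample SD when all weights are equal; it is NaN for a single
    observation."""
    x = np.asarray(values, float)
    w = np.asarray(weights, float)
    if x.shape != w.shape:
        raise ReportingError("values and weights must have the same length")
    if (w <= 0).any():
        raise ReportingError("weights must be positive")
    mean = float(np.average(x, weights=w))
    if len(x) < 2:
        return mean, float("nan")
    wsum = w.sum()
    denom = wsum - float((w**2).sum()) / wsum
    sd = float(np.sqrt((w * (x - mean) ** 2).sum() / denom))
    return mean, sd


def _per_individual_category_amounts(
    diets: pd.DataFrame, table: FoodTable, level: str
) -> pd.DataFrame:
    """individuals x categories (or sub-categories) amounts in g/day."""
    missing = set(diets.columns) - set(table.food_ids)
    if missing:
        raise ReportingError(f"foods missing from the table: {sorted(missing)}")
    labels = table.df.loc[diets.columns, level]
    return diets.fillna(0.0).T.groupby(labels).sum().T


def weight_changes(
    observed: pd.DataFrame,
    optimized: pd.DataFrame,
    table: FoodTable,
    weights: pd.Series,
) -> pd.DataFrame:
    """Survey-weighted mean change (optimized - observed, g/day) per food
    category and sub-category.

    *observed* / *optimized*: individuals x foods amount frames over the
    same individual set."""
    if not observed.index.equals(optimized.index):
        raise ReportingError("observed and optimized must cover the same individuals")
    w = weights.loc[observed.index]
    rows = []
    for level in ("category", "subcategory"):
        obs = _per_individual_category_amounts(observed, table, level)
        opt = _per_individual_category_amounts(optimized, table, level)
        opt = opt.reindex(columns=obs.columns, fill_value=0.0)
        obs = obs.reindex(columns=opt.columns, fill_value=0.0)
        delta = opt - obs
        for col in delta.columns:
            mean, sd = weighted_summary(delta[col].to_numpy(), w.to_numpy())
            rows.append(
                {"level": level, "group_label": col,
                 "delta_g_per_day": mean, "delta_sd": sd}
            )
    return pd.DataFrame(rows)


@dataclass
class SugarBalance:
    """Total / free / non-free sugar changes (g/day), per category and
    overall.  The identity delta_total = delta_free + delta_non_free holds
    exactly at every level."""

    per_category: pd.DataFrame  # index category; columns d_total, d_free, d_non_free
    overall: pd.Series

    def check_identity(self, tol: float = 1e-9) -> bool:
        d = self.per_category
        ok = np.allclose(
            d["delta_total_sugars"],
            d["delta_free_sugars"] + d["delta_non_free_sugars"],
            atol=tol,
        )
        ok &= np.isclose(
            self.overall["delta_total_sugars"],
            self.overall["delta_free_sugars"] + self.overall["delta_non_free_sugars"],
            atol=tol,
        )
        ok &= np.allclose(d.sum(), self.overall, atol=tol)
        return bool(ok)


def sugar_balance(
    observed: pd.DataFrame,
    optimized: pd.DataFrame,
    table: FoodTable,
    weights: pd.Series,
) -> SugarBalance:
    """Decompose the survey-weighted sugar change by food category.

    Non-free sugars are total minus free per food, so the decomposition is
    exact by construction."""
    if not observed.index.equals(optimized.index):
        raise ReportingError("observed and optimized must cover the same individuals")
    w = weights.loc[observed.index].to_numpy()
    w = w / w.sum()
    foods = observed.columns.union(optimized.columns)
    obs = observed.reindex(columns=foods, fill_value=0.0).fillna(0.0)
    opt = optimized.reindex(columns=foods, fill_value=0.0).fillna(0.0)
    delta = opt - obs  # g/day of food
    total = table.df.loc[foods, "total_sugars"] / 100.0
    free = table.df.loc[foods, "free_sugars"] / 100.0
    cats = table.df.loc[foods, "category"]
    per_ind = {
        "delta_total_sugars": delta * total.to_numpy(),
        "delta_free_sugars": delta * free.to_numpy(),
        "delta_non_free_sugars": delta * (total - free).to_numpy(),
    }
    per_cat = {}
    for key, frame in per_ind.items():
        by_cat = frame.T.groupby(cats).sum().T  # individuals x categories
        per_cat[key] = by_cat.mul(w, axis=0).sum()
    out = pd.DataFrame(per_cat)
    return SugarBalance(per_category=out, overall=out.sum())


def group_summary_table(
    values: pd.DataFrame,
    groups: pd.Series,
    weights: pd.Series,
    decimals: int = 1,
) -> pd.DataFrame:
    """Weighted mean +/- SD of each column per group plus the between-group
    mean difference, rounded to the reporting precision (1 decimal)."""
    rows = []
    for col in values.columns:
        entry = {"variable": col}
        means = {}
        for gname, idx in groups.groupby(groups).groups.items():
            m, sd = weighted_summary(
                values.loc[idx, col].to_numpy(), weights.loc[idx].to_numpy()
            )
            means[gname] = m
            entry[f"{gname}_mean"] = round(m, decimals)
            entry[f"{gname}_sd"] = round(sd, decimals)
        if len(means) == 2:
            a, b = sorted(means)
            entry["difference"] = round(means[b] - means[a], decimals)
        rows.append(entry)
    return pd.DataFrame(rows)
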