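"""End-to-end helpers: observed diets -> per-individual optimization ->
population-level results."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diet_optimizer import (
    BindingReport,
    ConstraintConfig,
    OptimizationResult,
    build_model,
    load_constraints,
    optimize_diet,
    population_parameters,
    rank_binding,
)
from .food_composition import FoodTable
from .survey_records import IndividualRecord, build_diet_vector, compute_intakes

__all__ = ["PopulationRun", "observed_diet_frame", "optimize_population"]


def observed_diet_frame(
    records: list[IndividualRecord], table: FoodTable
) -> pd.DataFrame:
    """individuals x foods observed amounts (g/day), absent foods as 0."""
    vecs = {r.individual_id: build_diet_vector(r, table) for r in records}
    return pd.DataFrame(vecs).T.fillna(0.0)


@dataclass
class PopulationRun:
    observed: pd.DataFrame  # individuals x foods
    optimized: pd.DataFrame  # optimal individuals x foods
    results: dict[str, OptimizationResult]
    binding: BindingReport
    n_infeasible: int

    @property
    def feasible_fraction(self) -> float:
        return len(self.optimized) / len(self.observed)


def optimize_population(
    records: list[IndividualRecord],
    table: FoodTable,
    config: ConstraintConfig | None = None,
) -> PopulationRun:
    """Optimize every individual against the population-derived acceptability
    context; infeasible individuals are reported, not silently dropped."""
    config = config or load_constraints()
    observed = observed_diet_frame(records, table)
    population = population_parameters(
        observed, table, config.food_max_quantile, config.group_max_quantile
    )
    results: dict[str, OptimizationResult] = {}
    optimized_rows = {}
    n_infeasible = 0
    for rec in records:
        o = observed.loc[rec.individual_id]
        o = o[o > 0]
        profile = compute_intakes(o, table)
        model = build_model(o, profile, table, config, population)
        res = optimize_diet(model)
        results[rec.individual_id] = res
        if res.status == "optimal":
            optimized_rows[rec.individual_id] = res.optimized
        else:
            n_infeasible += 1
    optimized = (
        pd.DataFrame(optimized_rows).T.reindex(columns=observed.columns).fillna(0.0)
        if optimized_rows
        else pd.DataFrame(columns=observed.columns)
    )
    binding = rank_binding(
        list(results.values()), config.params.dual_tolerance
    )
    return PopulationRun(
        observed=observed,
        optimized=optimized,
        results=results,
        binding=binding,
        n_infeasible=n_infeasible,
    )
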