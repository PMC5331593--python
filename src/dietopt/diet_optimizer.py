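"""Iso-energy individual diet optimization by linear programming.

For one individual with observed diet ``o`` (g/day per food), find optimized
amounts ``q >= 0`` that keep energy exactly at the observed (non-alcoholic)
level, satisfy 33 nutrient recommendations plus acceptability, total-weight
and total-cost constraints, and depart least from ``o``.

Departure is measured on relative deviations.  Repertoire foods (``o_f > 0``)
are split as ``q_f = o_f + d+_f - d-_f`` and the objective is

    sum_repertoire (w+ d+_f + w- d-_f) / o_f
    + pi * sum_nonrepertoire q_f / m_f

with ``w- >= w+`` so reductions of habitual foods cost more than increases,
and ``pi`` penalizing the introduction of non-repertoire foods scaled by the
population mean consumption among consumers ``m_f`` (which also caps them).
This realizes three aims: prefer repertoire foods, minimize their reduction,
and control the entry of non-repertoire foods.

The free-sugar constraint is conditional: individuals above 10% of energy
from free sugars get a ceiling of 10% of energy; those at or below 10% get a
"no increase" ceiling at their observed free-sugar amount.  "Energy-free"
drinks (< 4 kcal/100 mL) are excluded from the total-weight constraint so
they do not compete with nutrient-dense foods.

Dual values are reported per constraint as the sensitivity of the optimal
objective to the constraint's stated bound; a null dual marks an inactive
constraint, a non-null dual a binding one.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linprog

from .food_composition import FoodTable
from .survey_records import FS_KCAL_PER_G, IntakeProfile

__all__ = [
    "ConstraintSpec",
    "ConstraintConfig",
    "ModelParameters",
    "PopulationContext",
    "LPModel",
    "OptimizationResult",
    "BindingReport",
    "OptimizerError",
    "SolverFailure",
    "load_constraints",
    "population_parameters",
    "build_model",
    "optimize_diet",
    "extract_duals",
    "rank_binding",
]

FS_SHARE_LIMIT = 10.0  # % of energy


class OptimizerError(ValueError):
    pass


class SolverFailure(RuntimeError):
    """Solver did not return a clean optimal/infeasible status."""


@dataclass(frozen=True)
class ConstraintSpec:
    constraint_id: str
    kind: str  # nutrient_min | nutrient_max | ...
    nutrient: str | None = None
    bound: float | None = None
    basis: str = "absolute_per_day"  # or percent_energy
    kcal_per_g: float | None = None
    condition: str | None = None  # fs_conditional


@dataclass(frozen=True)
class ModelParameters:
    repertoire_increase_weight: float = 1.0  # w+
    repertoire_decrease_weight: float = 2.0  # w-
    nonrepertoire_penalty: float = 5.0  # pi
    dual_tolerance: float = 1e-6
    solver_tolerance: float = 1e-8

    def __post_init__(self):
        if min(
            self.repertoire_increase_weight,
            self.repertoire_decrease_weight,
            self.nonrepertoire_penalty,
        ) <= 0:
            raise OptimizerError("objective weights must be positive")
        if self.repertoire_decrease_weight < self.repertoire_increase_weight:
            raise OptimizerError("w- must be >= w+")
        if self.dual_tolerance <= 0:
            raise OptimizerError("dual_tolerance must be positive")


@dataclass(frozen=True)
class ConstraintConfig:
    nutritional: tuple[ConstraintSpec, ...]
    total_weight_multiplier: float = 1.0
    total_cost_multiplier: float = 1.0
    food_max_quantile: float = 0.95
    group_max_quantile: float = 0.95
    params: ModelParameters = field(default_factory=ModelParameters)


def load_constraints(path=None) -> ConstraintConfig:
    """Load the constraint configuration (packaged default: 33 nutrient rows)."""
    if path is None:
        src = importlib.resources.files("dietopt.config").joinpath("constraints.yaml")
        with src.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rows = tuple(
        ConstraintSpec(
            constraint_id=r["id"],
            kind=r["kind"],
            nutrient=r.get("nutrient"),
            bound=r.get("bound"),
            basis=r.get("basis", "absolute_per_day"),
            kcal_per_g=r.get("kcal_per_g"),
            condition=r.get("condition"),
        )
        for r in raw["nutritional"]
    )
    structural = raw.get("structural", {})
    p = raw.get("parameters", {})
    return ConstraintConfig(
        nutritional=rows,
        total_weight_multiplier=structural.get("total_weight_multiplier", 1.0),
        total_cost_multiplier=structural.get("total_cost_multiplier", 1.0),
        food_max_quantile=structural.get("food_max_quantile", 0.95),
        group_max_quantile=structural.get("group_max_quantile", 0.95),
        params=ModelParameters(
            repertoire_increase_weight=p.get("repertoire_increase_weight", 1.0),
            repertoire_decrease_weight=p.get("repertoire_decrease_weight", 2.0),
            nonrepertoire_penalty=p.get("nonrepertoire_penalty", 5.0),
            dual_tolerance=p.get("dual_tolerance", 1e-6),
            solver_tolerance=p.get("solver_tolerance", 1e-8),
        ),
    )


@dataclass
class PopulationContext:
    """Population statistics that parameterize acceptability constraints.

    ``mean_among_consumers``: m_f, mean g/day among individuals who consume
    food f (also the non-repertoire cap).  ``food_caps`` / ``group_caps``:
    per-food and per-sub-category consumption quantiles among consumers."""

    mean_among_consumers: pd.Series
    food_caps: pd.Series
    group_caps: dict[str, float]


def population_parameters(
    diets: pd.DataFrame,
    table: FoodTable,
    food_quantile: float = 0.95,
    group_quantile: float = 0.95,
) -> PopulationContext:
    """Compute m_f and acceptability caps from a population of diet vectors.

    *diets*: individuals x foods amounts (g/day), absent foods as 0/NaN.
    Foods never consumed in the population are dropped (they are not LP
    variables)."""
    amounts = diets.fillna(0.0)
    consumed = amounts.gt(0)
    any_consumer = consumed.any(axis=0)
    amounts = amounts.loc[:, any_consumer]
    consumed = consumed.loc[:, any_consumer]
    m = amounts.where(consumed).mean()
    caps = amounts.where(consumed).quantile(food_quantile)
    sub = table.df.loc[amounts.columns, "subcategory"]
    group_caps: dict[str, float] = {}
    for subcat, cols in amounts.T.groupby(sub):
        totals = cols.sum(axis=0)  # per-individual sub-category total
        totals = totals[totals > 0]
        if len(totals):
            group_caps[subcat] = float(totals.quantile(group_quantile))
    return PopulationContext(
        mean_among_consumers=m, food_caps=caps, group_caps=group_caps
    )


@dataclass
class LPModel:
    """A fully specified LP: minimize c.x s.t. A_ub x <= b_ub, A_eq x = b_eq,
    bounds; x = [q (foods), d+ (repertoire), d- (repertoire)]."""

    food_ids: list[str]
    repertoire: np.ndarray  # bool mask over foods
    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_ids: list[str]
    ub_senses: list[str]  # "max" or "min" per inequality row
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_ids: list[str]
    bounds: list[tuple[float, float | None]]
    observed: pd.Series
    energy_target: float
    params: ModelParameters

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)


@dataclass
class OptimizationResult:
    status: str  # optimal | infeasible
    optimized: pd.Series | None
    objective_value: float | None
    duals: dict[str, float] | None
    departures: pd.Series | None
    observed: pd.Series
    slacks: dict[str, float] | None = None


def _absolute_bound(spec: ConstraintSpec, energy: float) -> float:
    if spec.basis == "percent_energy":
        if energy <= 0:
            raise OptimizerError(
                f"{spec.constraint_id}: percent-energy bound with zero energy"
            )
        if not spec.kcal_per_g:
            raise OptimizerError(f"{spec.constraint_id}: kcal_per_g required")
        return spec.bound / 100.0 * energy / spec.kcal_per_g
    return float(spec.bound)


def build_model(
    observed: pd.Series,
    profile: IntakeProfile,
    table: FoodTable,
    config: ConstraintConfig | None = None,
    population: PopulationContext | None = None,
) -> LPModel:
    """Assemble the LP for one individual.

    *observed* is the (non-alcoholic) diet vector; *profile* its intakes.
    Without a population context, the model is restricted to the individual's
    own repertoire (no non-repertoire candidates, caps inactive)."""
    if len(observed) == 0 or observed.sum() <= 0:
        raise OptimizerError("observed diet is empty")
    config = config or load_constraints()
    params = config.params

    if population is None:
        food_ids = [f for f in observed.index if not table.df.loc[f, "is_alcoholic"]]
        m = observed.loc[food_ids].astype(float)
        food_caps = pd.Series(np.inf, index=food_ids)
        group_caps: dict[str, float] = {}
    else:
        food_ids = [
            f
            for f in population.mean_among_consumers.index
            if not table.df.loc[f, "is_alcoholic"]
        ]
        missing = set(observed.index[observed > 0]) - set(food_ids) - set(
            table.df.index[table.df["is_alcoholic"]]
        )
        if missing:
            raise OptimizerError(
                f"observed foods lack population mean m_f: {sorted(missing)}"
            )
        m = population.mean_among_consumers.loc[food_ids]
        food_caps = population.food_caps.reindex(food_ids).fillna(np.inf)
        group_caps = population.group_caps
    if (m <= 0).any():
        raise OptimizerError("m_f must be positive for every candidate food")

    o = observed.reindex(food_ids).fillna(0.0).astype(float)
    rep = (o > 0).to_numpy()
    n = len(food_ids)
    rep_idx = np.flatnonzero(rep)
    r = len(rep_idx)
    nvar = n + 2 * r
    energy_target = profile.energy
    if energy_target <= 0:
        raise OptimizerError("observed energy must be positive")

    tbl = table.df.loc[food_ids]
    e = tbl["energy"].to_numpy() / 100.0  # kcal per g

    # objective
    c = np.zeros(nvar)
    w_plus = params.repertoire_increase_weight
    w_minus = params.repertoire_decrease_weight
    pi = params.nonrepertoire_penalty
    nonrep = ~rep
    c[:n][nonrep] = pi / m.to_numpy()[nonrep]
    c[n : n + r] = w_plus / o.to_numpy()[rep_idx]
    c[n + r :] = w_minus / o.to_numpy()[rep_idx]

    # equalities: repertoire linking rows, then the energy row
    A_eq = np.zeros((r + 1, nvar))
    b_eq = np.zeros(r + 1)
    eq_ids = []
    for j, i in enumerate(rep_idx):
        A_eq[j, i] = 1.0
        A_eq[j, n + j] = -1.0
        A_eq[j, n + r + j] = 1.0
        b_eq[j] = o.iloc[i]
        eq_ids.append(f"link:{food_ids[i]}")
    A_eq[r, :n] = e
    b_eq[r] = energy_target
    eq_ids.append("energy_equality")

    # inequalities
    rows, bs, ids, senses = [], [], [], []

    def add_row(coeff_q: np.ndarray, bound: float, cid: str, sense: str):
        row = np.zeros(nvar)
        if sense == "max":
            row[:n] = coeff_q
            rows.append(row)
            bs.append(bound)
        else:  # min: -a q <= -bound
            row[:n] = -coeff_q
            rows.append(row)
            bs.append(-bound)
        ids.append(cid)
        senses.append(sense)

    observed_fs = profile.free_sugars
    observed_share = 100.0 * FS_KCAL_PER_G * observed_fs / energy_target
    for spec in config.nutritional:
        a = tbl[spec.nutrient].to_numpy() / 100.0
        if spec.condition == "fs_conditional":
            if observed_share > FS_SHARE_LIMIT:
                bound = _absolute_bound(spec, energy_target)
            else:
                bound = observed_fs  # no-increase ceiling
            add_row(a, bound, spec.constraint_id, "max")
            continue
        bound = _absolute_bound(spec, energy_target)
        if spec.kind == "nutrient_min":
            add_row(a, bound, spec.constraint_id, "min")
        elif spec.kind == "nutrient_max":
            add_row(a, bound, spec.constraint_id, "max")
        elif spec.kind == "nutrient_no_increase":
            add_row(a, float((a * o.to_numpy()).sum()), spec.constraint_id, "max")
        else:
            raise OptimizerError(f"unknown constraint kind: {spec.kind!r}")

    # sub-category acceptability rows (relaxed to the observed level so the
    # individual's own diet is never acceptability-infeasible)
    sub = tbl["subcategory"]
    for subcat, cap in sorted(group_caps.items()):
        mask = (sub == subcat).to_numpy(dtype=float)
        if mask.sum() == 0:
            continue
        observed_total = float((mask * o.to_numpy()).sum())
        add_row(mask, max(cap, observed_total), f"group_max:{subcat}", "max")

    # total diet weight, energy-free drinks excluded
    not_efd = ~tbl["is_energy_free_drink"].to_numpy(bool)
    observed_weight = float(o.to_numpy()[not_efd].sum())
    add_row(
        not_efd.astype(float),
        config.total_weight_multiplier * observed_weight,
        "total_weight_max",
        "max",
    )

    # total diet cost
    cost = tbl["unit_cost"].to_numpy() / 100.0  # per g
    observed_cost = float((cost * o.to_numpy()).sum())
    if observed_cost > 0:
        add_row(
            cost,
            config.total_cost_multiplier * observed_cost,
            "total_cost_max",
            "max",
        )

    # variable bounds: repertoire foods capped at max(acceptability cap, o_f);
    # non-repertoire foods capped at m_f
    bounds: list[tuple[float, float | None]] = []
    for i, f in enumerate(food_ids):
        if rep[i]:
            cap = food_caps.iloc[i]
            ub = max(cap, o.iloc[i]) if np.isfinite(cap) else None
        else:
            ub = float(m.iloc[i])
        bounds.append((0.0, ub))
    bounds += [(0.0, None)] * r  # d+
    bounds += [(0.0, float(o.iloc[i])) for i in rep_idx]  # d- <= o_f

    return LPModel(
        food_ids=list(food_ids),
        repertoire=rep,
        c=c,
        A_ub=np.array(rows) if rows else np.zeros((0, nvar)),
        b_ub=np.array(bs),
        ub_ids=ids,
        ub_senses=senses,
        A_eq=A_eq,
        b_eq=b_eq,
        eq_ids=eq_ids,
        bounds=bounds,
        observed=o,
        energy_target=energy_target,
        params=params,
    )


def optimize_diet(model: LPModel) -> OptimizationResult:
    """Solve the LP with HiGHS; deterministic under fixed variable ordering.

    Duals are reported per constraint as d(objective)/d(bound), so a binding
    minimum has a positive dual (tightening it costs) and a binding maximum a
    negative one."""
    res = linprog(
        model.c,
        A_ub=model.A_ub if len(model.b_ub) else None,
        b_ub=model.b_ub if len(model.b_ub) else None,
        A_eq=model.A_eq,
        b_eq=model.b_eq,
        bounds=model.bounds,
        method="highs",
    )
    if res.status == 2:
        return OptimizationResult(
            status="infeasible",
            optimized=None,
            objective_value=None,
            duals=None,
            departures=None,
            observed=model.observed,
        )
    if res.status != 0:
        raise SolverFailure(f"solver status {res.status}: {res.message}")

    n = model.n_foods
    q = pd.Series(res.x[:n], index=model.food_ids)
    q[q.abs() < 1e-12] = 0.0
    duals: dict[str, float] = {}
    slacks: dict[str, float] = {}
    if len(model.b_ub):
        for cid, sense, marg, slack in zip(
            model.ub_ids, model.ub_senses, res.ineqlin.marginals, res.ineqlin.residual
        ):
            # min rows are stored as -a.q <= -bound, so the sensitivity to the
            # *stated* bound flips sign
            duals[cid] = float(marg) if sense == "max" else -float(marg)
            slacks[cid] = float(slack)
    for cid, marg, in zip(model.eq_ids, res.eqlin.marginals):
        if cid == "energy_equality":
            duals[cid] = float(marg)
            slacks[cid] = 0.0
    return OptimizationResult(
        status="optimal",
        optimized=q,
        objective_value=float(res.fun),
        duals=duals,
        departures=q - model.observed,
        observed=model.observed,
        slacks=slacks,
    )


def extract_duals(result: OptimizationResult) -> dict[str, float]:
    """Dual value per constraint row of an optimal result."""
    if result.status != "optimal":
        raise OptimizerError("duals are only defined for optimal results")
    return dict(result.duals)


@dataclass
class BindingReport:
    """Per-constraint percentage of individuals with a non-null dual,
    ranked in decreasing order (ties broken by constraint id)."""

    table: pd.DataFrame  # columns: constraint_id, pct_binding

    def ranking(self) -> list[str]:
        return list(self.table["constraint_id"])


def rank_binding(
    results: list[OptimizationResult],
    dual_tolerance: float = 1e-6,
) -> BindingReport:
    """Rank constraints by the share of (optimal) individuals binding them."""
    optimal = [r for r in results if r.status == "optimal"]
    if not optimal:
        raise OptimizerError("no optimal results to rank")
    counts: dict[str, int] = {}
    present: dict[str, int] = {}
    for r in optimal:
        for cid, d in r.duals.items():
            present[cid] = present.get(cid, 0) + 1
            if abs(d) > dual_tolerance:
                counts[cid] = counts.get(cid, 0) + 1
    rows = [
        {
            "constraint_id": cid,
            "pct_binding": 100.0 * counts.get(cid, 0) / present[cid],
        }
        for cid in present
    ]
    df = pd.DataFrame(rows).sort_values(
        ["pct_binding", "constraint_id"], ascending=[False, True], kind="stable"
    )
    return BindingReport(df.reset_index(drop=True))
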