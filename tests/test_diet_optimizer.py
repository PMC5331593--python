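import numpy as np
import pandas as pd
import pytest

from dietopt.diet_optimizer import (
    ConstraintConfig,
    ConstraintSpec,
    ModelParameters,
    OptimizerError,
    PopulationContext,
    build_model,
    extract_duals,
    load_constraints,
    optimize_diet,
    population_parameters,
    rank_binding,
)
from dietopt.survey_records import compute_intakes

from conftest import make_table
from lp_oracle import solve_by_enumeration


@pytest.fixture(scope="module")
def two_food_table(taxonomy):
    return make_table(
        [
            dict(food_id="veg", subcategory="vegetables", energy=50.0,
                 protein=2.0, carbohydrate=8.0, starch=4.0, total_sugars=3.0,
                 fiber=3.0, unit_cost=0.5),
            dict(food_id="cake", subcategory="cakes_pastries", energy=400.0,
                 protein=5.0, fat=18.0, saturated_fat=8.0, carbohydrate=50.0,
                 starch=25.0, total_sugars=25.0, free_sugars=22.0,
                 unit_cost=0.8),
        ],
        taxonomy,
    )


def _config(rows, **kw):
    return ConstraintConfig(
        nutritional=tuple(rows),
        total_weight_multiplier=kw.get("weight", 10.0),
        total_cost_multiplier=kw.get("cost", 10.0),
        params=kw.get("params", ModelParameters()),
    )


def _solve(observed, table, rows, population=None, **kw):
    o = pd.Series(observed, dtype=float)
    profile = compute_intakes(o, table)
    model = build_model(o, profile, table, _config(rows, **kw), population)
    return model, optimize_diet(model)


class TestModelConstruction:
    def test_default_config_has_33_nutritional_rows(self):
        cfg = load_constraints()
        assert len(cfg.nutritional) == 33
        assert sum(c.condition == "fs_conditional" for c in cfg.nutritional) == 1

    def test_two_food_model_matrix(self, two_food_table):
        rows = [ConstraintSpec("fiber_min", "nutrient_min", "fiber", 5.0)]
        o = {"veg": 200.0, "cake": 100.0}
        model, res = _solve(o, two_food_table, rows)
        # variables: q_veg, q_cake, d+ x2, d- x2
        assert model.c.shape == (6,)
        # energy row: 0.5 and 4.0 kcal/g at the observed 500 kcal
        energy_row = model.A_eq[-1]
        assert np.allclose(energy_row[:2], [0.5, 4.0])
        assert model.b_eq[-1] == pytest.approx(500.0)
        # fiber min encoded as -a q <= -bound
        i = model.ub_ids.index("fiber_min")
        assert np.allclose(model.A_ub[i][:2], [-0.03, -0.0])
        assert model.b_ub[i] == pytest.approx(-5.0)

    def test_fs_rule_caps_at_ten_percent_for_excess_intake(self, two_food_table):
        rows = [ConstraintSpec("free_sugars_max", "nutrient_max", "free_sugars",
                               10.0, basis="percent_energy", kcal_per_g=4.0,
                               condition="fs_conditional")]
        # 100 g cake: 22 g FS of 400 kcal -> 22% of energy
        model, _ = _solve({"veg": 100.0, "cake": 100.0}, two_food_table, rows)
        i = model.ub_ids.index("free_sugars_max")
        energy = 50.0 + 400.0
        assert model.b_ub[i] == pytest.approx(0.10 * energy / 4.0)

    def test_fs_rule_no_increase_for_acceptable_intake(self, two_food_table):
        rows = [ConstraintSpec("free_sugars_max", "nutrient_max", "free_sugars",
                               10.0, basis="percent_energy", kcal_per_g=4.0,
                               condition="fs_conditional")]
        # 10 g cake in 1010 g diet: 2.2 g FS of 450 kcal -> ~2%E
        model, _ = _solve({"veg": 800.0, "cake": 10.0}, two_food_table, rows)
        i = model.ub_ids.index("free_sugars_max")
        assert model.b_ub[i] == pytest.approx(2.2)  # observed grams

    def test_empty_diet_rejected(self, two_food_table):
        with pytest.raises(OptimizerError):
            _solve({}, two_food_table, [])

    def test_parameter_invariants(self):
        with pytest.raises(OptimizerError):
            ModelParameters(repertoire_increase_weight=2.0,
                            repertoire_decrease_weight=1.0)
        with pytest.raises(OptimizerError):
            ModelParameters(nonrepertoire_penalty=0.0)
        with pytest.raises(OptimizerError):
            ModelParameters(dual_tolerance=0.0)


class TestOptimize:
    def test_satisfied_constraints_keep_observed_diet(self, two_food_table):
        rows = [ConstraintSpec("fiber_min", "nutrient_min", "fiber", 2.0)]
        o = {"veg": 200.0, "cake": 50.0}
        _, res = _solve(o, two_food_table, rows)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.optimized, pd.Series(o, dtype=float), atol=1e-7)

    def test_contradictory_requirement_infeasible(self, two_food_table):
        # more fiber than any iso-energy combination can carry
        rows = [ConstraintSpec("fiber_min", "nutrient_min", "fiber", 500.0)]
        _, res = _solve({"veg": 200.0, "cake": 100.0}, two_food_table, rows)
        assert res.status == "infeasible"
        assert res.optimized is None
        with pytest.raises(OptimizerError):
            extract_duals(res)

    def test_solution_respects_rows_within_tolerance(self, two_food_table):
        rows = [
            ConstraintSpec("fiber_min", "nutrient_min", "fiber", 8.0),
            ConstraintSpec("fs_max", "nutrient_max", "free_sugars", 15.0),
        ]
        model, res = _solve({"veg": 150.0, "cake": 120.0}, two_food_table, rows)
        assert res.status == "optimal"
        q = res.optimized
        intk = compute_intakes(q[q > 0], two_food_table)
        assert intk["fiber"] >= 8.0 - 1e-7
        assert intk["free_sugars"] <= 15.0 + 1e-7
        assert intk.energy == pytest.approx(555.0, rel=1e-8)


class TestDuals:
    def test_slack_constraint_has_zero_dual(self, two_food_table):
        rows = [
            ConstraintSpec("fiber_min", "nutrient_min", "fiber", 8.0),
            ConstraintSpec("protein_min", "nutrient_min", "protein", 0.5),
        ]
        model, res = _solve({"veg": 150.0, "cake": 120.0}, two_food_table, rows)
        duals = extract_duals(res)
        assert res.slacks["protein_min"] > 1e-3
        assert duals["protein_min"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "cid, fiber_bound, fs_bound, delta",
        [
            # fiber binds when the sugar ceiling is slack, and vice versa
            ("fiber_min", 8.0, 40.0, 0.05),
            ("fs_max", 1.0, 12.0, -0.05),
        ],
    )
    def test_dual_is_shadow_price_by_finite_difference(
        self, two_food_table, cid, fiber_bound, fs_bound, delta
    ):
        def solve_with(bound_shift):
            rows = [
                ConstraintSpec("fiber_min", "nutrient_min", "fiber",
                               fiber_bound + (bound_shift if cid == "fiber_min" else 0)),
                ConstraintSpec("fs_max", "nutrient_max", "free_sugars",
                               fs_bound + (bound_shift if cid == "fs_max" else 0)),
            ]
            return _solve({"veg": 150.0, "cake": 120.0}, two_food_table, rows)

        _, base = solve_with(0.0)
        _, shifted = solve_with(delta)
        dual = base.duals[cid]
        assert abs(dual) > 1e-6  # the row binds in this configuration
        fd = (shifted.objective_value - base.objective_value) / delta
        assert fd == pytest.approx(dual, rel=1e-4, abs=1e-8)

    def test_complementary_slackness_on_toy(self, two_food_table):
        rows = [
            ConstraintSpec("fiber_min", "nutrient_min", "fiber", 8.0),
            ConstraintSpec("fs_max", "nutrient_max", "free_sugars", 12.0),
            ConstraintSpec("protein_min", "nutrient_min", "protein", 0.1),
        ]
        _, res = _solve({"veg": 150.0, "cake": 120.0}, two_food_table, rows)
        for cid, slack in res.slacks.items():
            if slack > 1e-6:
                assert abs(res.duals[cid]) <= 1e-6


class TestRanking:
    def test_energy_always_binds_and_sorts_first(self, small_run):
        table = small_run.binding.table
        top = table.iloc[0]
        assert top["constraint_id"] == "energy_equality"
        assert top["pct_binding"] == pytest.approx(100.0)

    def test_unbound_rows_rank_last_with_zero(self, small_run):
        tbl = small_run.binding.table.set_index("constraint_id")["pct_binding"]
        assert (tbl.sort_values(ascending=False).values == tbl.values).all()

    def test_empty_input_rejected(self):
        with pytest.raises(OptimizerError):
            rank_binding([])


def _random_small_model(rng, taxonomy):
    """A random iso-energy LP over 2-6 foods with finite caps (bounded)."""
    n = int(rng.integers(2, 7))
    rows_spec = []
    foods = []
    subcats = ["vegetables", "refined_starches", "cakes_pastries",
               "meats_eggs_fish", "fresh_fruits", "added_fats"]
    for i in range(n):
        sugars = float(rng.uniform(0, 30))
        foods.append(dict(
            food_id=f"f{i}", subcategory=subcats[i % len(subcats)],
            energy=float(rng.uniform(40, 450)),
            protein=float(rng.uniform(0, 20)),
            fat=float(rng.uniform(0, 30)),
            carbohydrate=sugars + float(rng.uniform(0, 40)),
            total_sugars=sugars,
            free_sugars=sugars * float(rng.uniform(0, 1)),
            fiber=float(rng.uniform(0, 6)),
            sodium=float(rng.uniform(0, 800)),
            unit_cost=float(rng.uniform(0.1, 1.5)),
        ))
    table = make_table(foods, taxonomy)
    ids = [f["food_id"] for f in foods]
    observed = pd.Series(
        rng.uniform(20, 250, size=n), index=ids
    ) * (rng.random(n) < 0.75)  # some foods non-repertoire
    if observed.sum() <= 0:
        observed.iloc[0] = 100.0
    observed = observed[observed > 0]
    profile = compute_intakes(observed, table)
    if profile.energy <= 0:
        observed.iloc[0] = 150.0
        profile = compute_intakes(observed, table)
    nutr_pool = [
        ("protein", "nutrient_min"), ("fiber", "nutrient_min"),
        ("free_sugars", "nutrient_max"), ("sodium", "nutrient_max"),
        ("fat", "nutrient_max"),
    ]
    k = int(rng.integers(1, 4))
    picks = rng.choice(len(nutr_pool), size=k, replace=False)
    rows = []
    for j in picks:
        nutrient, kind = nutr_pool[j]
        current = profile[nutrient]
        if kind == "nutrient_min":
            bound = current * float(rng.uniform(0.6, 1.5)) + 0.1
        else:
            bound = current * float(rng.uniform(0.5, 1.4)) + 0.1
        rows.append(ConstraintSpec(f"{nutrient}_{kind}", kind, nutrient, bound))
    population = PopulationContext(
        mean_among_consumers=pd.Series(rng.uniform(30, 200, size=n), index=ids),
        food_caps=pd.Series(rng.uniform(100, 500, size=n), index=ids),
        group_caps={},
    )
    cfg = ConstraintConfig(nutritional=tuple(rows),
                           total_weight_multiplier=float(rng.uniform(1.0, 1.6)),
                           total_cost_multiplier=float(rng.uniform(1.0, 1.6)))
    model = build_model(observed, profile, table, cfg, population)
    return model


class TestOracleEquivalence:
    def test_solver_matches_vertex_enumeration_sample(self, taxonomy):
        """Unit-scale spot check; the full 200-instance sweep runs in the
        acceptance suite."""
        rng = np.random.default_rng(2024)
        for _ in range(40):
            model = _random_small_model(rng, taxonomy)
            res = optimize_diet(model)
            status, best = solve_by_enumeration(model)
            assert status == res.status
            if status == "optimal":
                assert res.objective_value == pytest.approx(best, abs=1e-8, rel=1e-8)

    def test_nonrepertoire_grams_monotone_in_penalty(self, taxonomy):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 10:
            model = _random_small_model(rng, taxonomy)
            if model.repertoire.all():
                continue
            totals = []
            o = model.observed.copy()
            table_ok = True
            for pi in (1.0, 5.0, 25.0):
                # rebuild objective with the new penalty on non-repertoire vars
                c = model.c.copy()
                n = model.n_foods
                nonrep = ~model.repertoire
                base = model.c[:n][nonrep]
                c[:n][nonrep] = base * pi / model.params.nonrepertoire_penalty
                from scipy.optimize import linprog
                res = linprog(c, A_ub=model.A_ub if len(model.b_ub) else None,
                              b_ub=model.b_ub if len(model.b_ub) else None,
                              A_eq=model.A_eq, b_eq=model.b_eq,
                              bounds=model.bounds, method="highs")
                if res.status != 0:
                    table_ok = False
                    break
                totals.append(res.x[:n][nonrep].sum())
            if not table_ok:
                continue
            assert totals[0] >= totals[1] - 1e-7 >= totals[2] - 2e-7
            checked += 1
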