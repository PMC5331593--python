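import numpy as np
import pandas as pd
import pytest

from dietopt.survey_records import (
    ConsumptionEvent,
    GoldbergParams,
    IndividualRecord,
    IntakeProfile,
    SurveyError,
    basal_metabolic_rate,
    build_diet_vector,
    classify_fs_group,
    compute_intakes,
    daily_intake_table,
    free_sugar_energy_share,
    goldberg_screen,
    intake_profile,
)

from conftest import make_table


def _record(events, **kw):
    defaults = dict(
        individual_id="i1", age=40.0, gender="female", weight=65.0,
        height=1.65, physical_activity="moderate", survey_weight=1.0,
    )
    defaults.update(kw)
    return IndividualRecord(events=pd.DataFrame(events), **defaults)


def _events(rows):
    return [dict(day=d, moment=m, food_id=f, amount_g=a) for d, m, f, a in rows]


class TestDietVector:
    def test_single_event_averaged_over_week(self, tiny_table):
        rec = _record(_events([(1, "lunch", "apple", 140.0)]))
        vec = build_diet_vector(rec, tiny_table)
        assert vec["apple"] == pytest.approx(20.0)

    def test_empty_diary_gives_empty_vector_and_zero_energy(self, tiny_table):
        rec = _record([])
        vec = build_diet_vector(rec, tiny_table)
        assert len(vec) == 0
        assert compute_intakes(vec, tiny_table).energy == 0.0

    def test_daily_bread_and_one_cola(self, tiny_table):
        rows = [(d, "lunch", "bread", 100.0) for d in range(1, 8)]
        rows.append((3, "afternoon_snack", "cola", 330.0))
        vec = build_diet_vector(_record(_events(rows)), tiny_table)
        assert vec["bread"] == pytest.approx(100.0)
        assert vec["cola"] == pytest.approx(330.0 / 7)

    def test_alcoholic_beverages_excluded(self, taxonomy):
        table = make_table(
            [
                dict(food_id="beer", subcategory="diet_beverages", energy=43.0,
                     carbohydrate=3.0, total_sugars=0.0, is_beverage=True,
                     is_alcoholic=True),
                dict(food_id="bread", subcategory="refined_starches",
                     energy=240.0, carbohydrate=50.0, starch=48.0,
                     total_sugars=2.0),
            ],
            taxonomy,
        )
        rec = _record(_events([(1, "dinner", "beer", 700.0),
                               (1, "dinner", "bread", 70.0)]))
        vec = build_diet_vector(rec, table)
        assert "beer" not in vec.index
        assert vec["bread"] == pytest.approx(10.0)

    def test_unknown_food_rejected(self, tiny_table):
        rec = _record(_events([(1, "lunch", "dragonfruit", 10.0)]))
        with pytest.raises(SurveyError, match="dragonfruit"):
            build_diet_vector(rec, tiny_table)


class TestIntakes:
    def test_energy_from_energy_density(self, tiny_table):
        vec = pd.Series({"bread": 100.0})
        prof = compute_intakes(vec, tiny_table)
        assert prof.energy == pytest.approx(240.0)

    def test_linearity_in_amounts(self, tiny_table):
        vec = pd.Series({"bread": 80.0, "apple": 150.0, "cola": 100.0})
        single = compute_intakes(vec, tiny_table).nutrients
        double = compute_intakes(2 * vec, tiny_table).nutrients
        assert np.allclose(double, 2 * single)

    def test_sugar_identity_and_moment_decomposition(self, tiny_table):
        rows = [(d, m, f, a)
                for d in range(1, 8)
                for m, f, a in [("breakfast", "bread", 60.0),
                                ("lunch", "apple", 120.0),
                                ("afternoon_snack", "cola", 150.0),
                                ("evening_snack", "sugar", 5.0)]]
        rec = _record(_events(rows))
        prof = intake_profile(rec, tiny_table)
        assert prof.non_free_sugars == pytest.approx(
            prof.nutrients["total_sugars"] - prof.nutrients["free_sugars"]
        )
        assert prof.energy_meals + prof.energy_snacks == pytest.approx(
            prof.energy, rel=1e-9
        )
        assert prof.free_sugars_meals + prof.free_sugars_snacks == pytest.approx(
            prof.free_sugars, rel=1e-9
        )
        # snack moments carry exactly the cola + sugar energy
        assert prof.energy_snacks == pytest.approx(150 * 0.42 + 5 * 3.98)

    def test_daily_table_mean_matches_diet_vector_intakes(self, tiny_table):
        rng = np.random.default_rng(0)
        rows = [(d, "lunch", f, float(rng.uniform(10, 200)))
                for d in range(1, 8) for f in ("apple", "bread", "cola")]
        rec = _record(_events(rows))
        daily = daily_intake_table(rec, tiny_table)
        prof = intake_profile(rec, tiny_table)
        assert np.allclose(daily.mean()[prof.nutrients.index], prof.nutrients)


class TestRecordValidation:
    def test_event_bounds(self):
        with pytest.raises(SurveyError):
            ConsumptionEvent("i", 8, "lunch", "apple", 10.0)
        with pytest.raises(SurveyError):
            ConsumptionEvent("i", 3, "brunch", "apple", 10.0)
        with pytest.raises(SurveyError):
            ConsumptionEvent("i", 3, "lunch", "apple", -1.0)

    def test_record_must_span_seven_days(self):
        rec = _record(_events([(d, "lunch", "apple", 100.0) for d in range(1, 7)]))
        with pytest.raises(SurveyError, match="7 days"):
            rec.validate()
        ok = _record(_events([(d, "lunch", "apple", 100.0) for d in range(1, 8)]))
        ok.validate()

    def test_age_bounds(self):
        rec = _record(
            _events([(d, "lunch", "apple", 100.0) for d in range(1, 8)]),
            age=18.0,
        )
        with pytest.raises(SurveyError, match="age"):
            rec.validate()


class TestGoldberg:
    def test_far_below_bmr_is_under_reporter(self):
        rec = _record([], age=40, gender="male", weight=80.0, height=1.80)
        bmr = basal_metabolic_rate(rec)
        assert goldberg_screen(rec, 0.5 * bmr) == "under_reporter"

    def test_energy_at_requirement_is_plausible(self):
        params = GoldbergParams()
        rec = _record([], age=40, gender="female", weight=60.0, height=1.65)
        bmr = basal_metabolic_rate(rec)
        pal = params.pal_by_activity["moderate"]
        assert goldberg_screen(rec, bmr * pal, params) == "plausible"

    def test_boundary_flips_at_cutoff(self):
        params = GoldbergParams()
        rec = _record([], age=40, gender="female", weight=60.0, height=1.65)
        bmr = basal_metabolic_rate(rec)
        # independent recomputation of the cutoff formula
        s = np.sqrt(23.0**2 / 7 + 8.5**2 + 15.0**2)
        cutoff = params.pal_by_activity["moderate"] * np.exp(-2 * s / 100)
        assert goldberg_screen(rec, bmr * cutoff + 1.0, params) == "plausible"
        assert goldberg_screen(rec, bmr * cutoff - 1.0, params) == "under_reporter"

    def test_missing_anthropometrics_unscreenable(self):
        rec = _record([], weight=None)
        assert goldberg_screen(rec, 2000.0) == "unscreenable"


class TestFsClassification:
    def _profile(self, share, energy=2000.0):
        fs = share / 100.0 * energy / 4.0
        nutrients = pd.Series({"energy": energy, "free_sugars": fs,
                               "total_sugars": fs + 10.0})
        return IntakeProfile(nutrients)

    @pytest.mark.parametrize(
        "share, expected",
        [(14.2, "FS_EXCESS"), (10.0, "FS_ACCEPTABLE"), (6.3, "FS_ACCEPTABLE"),
         (10.0001, "FS_EXCESS")],
    )
    def test_ten_percent_rule_boundary_inclusive(self, share, expected):
        assert classify_fs_group(self._profile(share)) == expected

    def test_share_computation(self):
        assert free_sugar_energy_share(self._profile(12.5)) == pytest.approx(12.5)

    def test_zero_energy_rejected(self):
        prof = IntakeProfile(pd.Series({"energy": 0.0, "free_sugars": 0.0,
                                        "total_sugars": 0.0}))
        with pytest.raises(SurveyError):
            classify_fs_group(prof)
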