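"""Removal models and the gram-for-gram swap."""

import numpy as np
import pandas as pd
import pytest

from fatswap.composition import derive_food_metrics, COMPONENT_COLUMNS
from fatswap.profiles import StratificationConfig, build_replacement_profiles
from fatswap.scores import daily_totals
from fatswap.substitution import apply_swap, remove_all_dairy, remove_capped_dairy

from conftest import toy_foods, toy_participants

CFG = StratificationConfig()


def intake_df(rows):
    return pd.DataFrame(rows, columns=["participant_id", "food_code", "grams", "occasion"])


# foods: M = dairy milk-like, C = dairy cheese-like, N = plain non-dairy
FOODS = toy_foods(
    {
        "M": dict(energy_kcal=150, fat_g=6, sat_fat_g=4, mufa_g=1.5, pufa_g=0.3,
                  dairy_fat_g=6, calcium_mg=120),
        "C": dict(energy_kcal=300, fat_g=25, sat_fat_g=15, mufa_g=7, pufa_g=1,
                  dairy_fat_g=20, calcium_mg=500),
        "N": dict(energy_kcal=100, fat_g=3, sat_fat_g=0.5, mufa_g=1.5, pufa_g=1,
                  carb_g=15, protein_g=3),
    }
)
DAIRY = FOODS["dairy_fat_g"]


class TestModel1:
    def test_no_dairy_day_unchanged(self):
        day = intake_df([(1, "N", 200.0, "lunch")])
        res = remove_all_dairy(day, DAIRY)
        assert len(res.removed) == 0
        pd.testing.assert_frame_equal(res.intake, day)

    def test_constructed_day_energy(self):
        # two dairy items totalling 300 kcal + one non-dairy 200 kcal
        day = intake_df(
            [(1, "M", 100.0, "breakfast"), (1, "C", 50.0, "dinner"), (1, "N", 200.0, "lunch")]
        )
        res = remove_all_dairy(day, DAIRY)
        totals = daily_totals(res.intake, FOODS)
        assert totals.loc[1, "energy_kcal"] == pytest.approx(200.0)
        assert totals.loc[1, "dairy_fat_g"] == 0.0
        assert len(res.removed) == 2

    def test_population_dairy_energy_zero(self, small_study):
        assert (small_study.totals["M1_remove"]["dairy_fat_g"] == 0).all()


class TestModel2:
    def _day_8pct(self):
        # dairy item carries 8% of a 1,000 kcal day as dairy fat:
        # 100 g x 8.888... g/100 g x 9 kcal/g = 80 kcal
        foods = toy_foods(
            {
                "D": dict(energy_kcal=300, fat_g=10, dairy_fat_g=80 / 9),
                "N": dict(energy_kcal=100, carb_g=25),
            }
        )
        day = intake_df([(1, "D", 100.0, "dinner"), (1, "N", 700.0, "lunch")])
        energy = pd.Series({1: 1000.0})
        return day, foods, energy

    def test_exact_cap_partial_removal(self):
        day, foods, energy = self._day_8pct()
        res = remove_capped_dairy(day, foods["dairy_fat_g"], energy, cap=0.05, seed=1)
        # 5/8 of the item's grams go; removed dairy-fat energy == 5%E exactly
        assert res.removed["grams_removed"].sum() == pytest.approx(100 * 5 / 8)
        removed_e = res.dairy_fat_energy_removed(foods["dairy_fat_g"])
        assert removed_e.loc[1] == pytest.approx(50.0)
        kept = res.intake.set_index("food_code")
        assert kept.loc["D", "grams"] == pytest.approx(100 * 3 / 8)

    def test_below_cap_equals_full_removal(self):
        day = intake_df([(1, "M", 50.0, "breakfast"), (1, "N", 500.0, "lunch")])
        # dairy-fat energy = 50 x 0.06 x 9 = 27 kcal; 3% of 900 kcal day
        energy = pd.Series({1: 900.0})
        res = remove_capped_dairy(day, DAIRY, energy, cap=0.05, seed=9)
        full = remove_all_dairy(day, DAIRY)
        assert sorted(res.removed["food_code"]) == sorted(full.removed["food_code"])
        assert res.removed["grams_removed"].sum() == pytest.approx(
            full.removed["grams_removed"].sum()
        )

    def test_skip_mode_stays_under_cap(self):
        day, foods, energy = self._day_8pct()
        res = remove_capped_dairy(
            day, foods["dairy_fat_g"], energy, cap=0.05, seed=1, boundary="skip"
        )
        removed_e = res.dairy_fat_energy_removed(foods["dairy_fat_g"])
        assert removed_e.get(1, 0.0) <= 50.0

    def test_same_seed_reproducible_and_seeds_vary(self):
        day = intake_df(
            [(1, "M", 80.0, "breakfast"), (1, "M", 60.0, "snack"),
             (1, "C", 40.0, "dinner"), (1, "N", 400.0, "lunch")]
        )
        energy = pd.Series({1: 800.0})
        a = remove_capped_dairy(day, DAIRY, energy, seed=3)
        b = remove_capped_dairy(day, DAIRY, energy, seed=3)
        pd.testing.assert_frame_equal(a.removed, b.removed)
        partials = set()
        for seed in range(30):
            r = remove_capped_dairy(day, DAIRY, energy, seed=seed)
            grams = r.removed.set_index("food_code")["grams_removed"]
            partials.add(tuple(np.round(np.sort(grams.to_numpy()), 6)))
        assert len(partials) > 1  # randomized order changes the partial item

    def test_cap_bound_holds_population(self, small_study):
        res = small_study.substitutions["M2_remove"]
        removed = res.dairy_fat_energy_removed(small_study.db.dairy_fat)
        observed = small_study.totals["observed"]["energy_kcal"]
        cap = 0.05 * observed.loc[removed.index]
        assert (removed <= cap + 1e-6).all()

    def test_model1_dominates_model2(self, small_study):
        m1 = small_study.substitutions["M1_remove"].dairy_fat_energy_removed(
            small_study.db.dairy_fat
        )
        m2 = small_study.substitutions["M2_remove"].dairy_fat_energy_removed(
            small_study.db.dairy_fat
        )
        aligned = pd.concat([m1, m2], axis=1, keys=["m1", "m2"]).fillna(0.0)
        assert (aligned["m1"] >= aligned["m2"] - 1e-9).all()


class TestSwap:
    def _profiles(self):
        # one eligible food at 2.0 kcal/g consumed once -> global composite
        parts = toy_participants({1: (30, 1.0)})
        foods = toy_foods(
            {"R": dict(energy_kcal=200, fat_g=5, mufa_g=2.5, pufa_g=1.5, calcium_mg=50)}
        )
        metrics = derive_food_metrics(foods, foods["dairy_fat_g"])
        profiles = build_replacement_profiles(
            intake_df([(1, "R", 100.0, "lunch")]), parts, foods, metrics, CFG
        )
        return profiles, parts

    def test_no_removed_items_identity(self):
        profiles, parts = self._profiles()
        day = intake_df([(1, "N", 200.0, "lunch")])
        res = remove_all_dairy(day, DAIRY)
        metrics = derive_food_metrics(FOODS, DAIRY)
        swapped = apply_swap(res, profiles, parts, metrics, CFG)
        assert swapped.replacement is None
        pd.testing.assert_frame_equal(swapped.intake, day)
        assert swapped.model_id == "M1_swap"

    def test_linear_replacement(self):
        profiles, parts = self._profiles()
        day = intake_df([(1, "M", 100.0, "breakfast"), (1, "N", 100.0, "lunch")])
        res = remove_all_dairy(day, DAIRY)
        metrics = derive_food_metrics(FOODS, DAIRY)
        swapped = apply_swap(res, profiles, parts, metrics, CFG)
        assert swapped.replacement["grams"].sum() == pytest.approx(100.0)
        assert swapped.replacement["energy_kcal"].sum() == pytest.approx(200.0)
        assert (swapped.replacement["dairy_fat_g"] == 0).all()

    @pytest.mark.parametrize("model", ["M1_swap", "M2_swap"])
    def test_swap_preserves_total_grams(self, small_study, model):
        observed = small_study.intake.groupby("participant_id")["grams"].sum()
        sub = small_study.substitutions[model]
        modified = sub.intake.groupby("participant_id")["grams"].sum()
        added = (
            sub.replacement.groupby("participant_id")["grams"].sum()
            if sub.replacement is not None
            else 0.0
        )
        total = modified.add(added, fill_value=0.0).reindex(observed.index, fill_value=0.0)
        np.testing.assert_allclose(total, observed, rtol=1e-9)

    def test_no_new_dairy_in_any_model(self, small_study):
        for model in ["M1_remove", "M2_remove", "M1_swap", "M2_swap"]:
            sub = small_study.substitutions[model]
            if sub.replacement is not None:
                assert (sub.replacement["dairy_fat_g"] == 0).all()
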