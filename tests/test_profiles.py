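"""Stratum assignment, weighted quantiles and replacement profiles."""

import numpy as np
import pandas as pd
import pytest

from fatswap.composition import COMPONENT_COLUMNS, derive_food_metrics
from fatswap.profiles import (
    DEFAULT_ED_CUTPOINTS,
    DEFAULT_FAT_CUTPOINTS,
    EmptyProfileError,
    ReplacementProfiles,
    StratificationConfig,
    StratumKey,
    UnmappedOccasionError,
    assign_stratum,
    build_replacement_profiles,
    stratum_key_space,
    weighted_quantile_cutpoints,
)

from conftest import toy_foods, toy_participants

CFG = StratificationConfig()


def brute_weighted_quantile(values, weights, p):
    """Independent oracle: scan the sorted sample until mass >= p."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum / total >= p - 1e-12:
            return v
    return pairs[-1][0]


class TestWeightedQuantiles:
    def test_identical_values(self):
        got = weighted_quantile_cutpoints([7.0] * 10, [1.0] * 10, CFG.quantile_probs)
        assert (got == 7.0).all()

    def test_median_of_1_to_10(self):
        got = weighted_quantile_cutpoints(range(1, 11), [1.0] * 10, [0.5])
        assert got[0] == 5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = rng.integers(1, 50)
            values = np.round(rng.uniform(0, 100, n), 1)  # ties likely
            weights = rng.uniform(0, 2, n)
            if weights.sum() == 0:
                continue
            probs = np.sort(rng.uniform(0.05, 0.95, 3))
            got = weighted_quantile_cutpoints(values, weights, probs)
            want = [brute_weighted_quantile(values, weights, p) for p in probs]
            np.testing.assert_allclose(got, want)

    def test_reference_cutpoints_loadable_as_fixed_config(self):
        cfg = StratificationConfig(
            ed_cutpoints=(49.8, 70.7, 151.5, 235.6, 308.8),
            fat_cutpoints=(16.4, 24.9, 38.4, 48.3, 63.5),
        )
        assert cfg.ed_cutpoints == DEFAULT_ED_CUTPOINTS
        assert cfg.fat_cutpoints == DEFAULT_FAT_CUTPOINTS

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            weighted_quantile_cutpoints([], [], [0.5])


class TestAssignStratum:
    def test_reference_examples(self):
        key = assign_stratum(45, "lunch", 100.0, 20.0, CFG)
        assert key.age_group == 3  # 40-64 y
        assert key.ed_category == 3  # 70.7-151.4 kcal/100 g
        assert key.fat_category == 2  # 16.4-24.8 %E

    def test_boundary_value_falls_upper(self):
        key = assign_stratum(20, "breakfast", 49.8, 16.4, CFG)
        assert key.age_group == 2
        assert key.ed_category == 2
        assert key.fat_category == 2

    def test_meal_categories(self):
        for label, expected in [("breakfast", 1), ("snack", 2), ("lunch", 3),
                                ("dinner", 3), ("dessert", 4)]:
            assert assign_stratum(10, label, 10, 10, CFG).meal_type == expected

    def test_unmapped_occasion(self):
        with pytest.raises(UnmappedOccasionError, match="brunch"):
            assign_stratum(30, "brunch", 100, 20, CFG)

    def test_key_space_has_576_cells(self):
        keys = stratum_key_space(CFG)
        assert len(keys) == len(set(keys)) == 576


def _build(events, foods_cols, participants):
    """events: (pid, code, grams, occasion); foods_cols: {code: cols}."""
    intake = pd.DataFrame(events, columns=["participant_id", "food_code", "grams", "occasion"])
    foods = toy_foods(foods_cols)
    metrics = derive_food_metrics(foods, foods["dairy_fat_g"])
    return build_replacement_profiles(intake, participants, foods, metrics, CFG), foods


class TestBuildProfiles:
    def test_single_food_profile_is_that_food(self):
        parts = toy_participants({1: (30, 2.0)})
        profiles, foods = _build(
            [(1, "A", 150.0, "lunch")],
            {"A": dict(energy_kcal=200, fat_g=4, mufa_g=2, pufa_g=1, calcium_mg=80)},
            parts,
        )
        assert len(profiles) == 1
        key = next(iter(profiles.strata))
        prof = profiles.profile(key)
        pd.testing.assert_series_equal(
            prof.per_gram, foods.loc["A", COMPONENT_COLUMNS] / 100.0, check_names=False
        )

    def test_equal_weight_events_average(self):
        # weight x grams equal: (w=2, g=100) vs (w=1, g=200)
        parts = toy_participants({1: (30, 2.0), 2: (35, 1.0)})
        cols = dict(energy_kcal=100, fat_g=2, mufa_g=1, pufa_g=0.5)
        profiles, foods = _build(
            [(1, "A", 100.0, "lunch"), (2, "B", 200.0, "lunch")],
            {"A": dict(cols, calcium_mg=100), "B": dict(cols, calcium_mg=300)},
            parts,
        )
        key = next(iter(profiles.strata))
        prof = profiles.resolve(key)
        assert prof.per_gram["calcium_mg"] == pytest.approx(2.0)  # mean of 1 and 3 per g
        assert prof.n_foods == 2

    def test_matches_brute_force_on_random_events(self):
        rng = np.random.default_rng(3)
        parts = toy_participants({i: (int(rng.integers(4, 80)), rng.uniform(0.5, 3)) for i in range(1, 11)})
        foods_cols = {
            f"F{j}": dict(
                energy_kcal=rng.uniform(50, 400), fat_g=rng.uniform(0, 10),
                mufa_g=rng.uniform(1, 4), pufa_g=rng.uniform(1, 4),
                calcium_mg=rng.uniform(0, 500), fiber_g=rng.uniform(0, 5),
            )
            for j in range(4)
        }
        events = [
            (int(rng.integers(1, 11)), f"F{int(rng.integers(0, 4))}",
             float(rng.uniform(10, 300)), "lunch")
            for _ in range(10)
        ]
        profiles, foods = _build(events, foods_cols, parts)
        # brute force: accumulate weight x per-gram nutrient per stratum key
        sums, wsums = {}, {}
        for pid, code, grams, occ in events:
            age = parts.loc[pid, "age"]
            w = parts.loc[pid, "survey_weight"] * grams
            ag = 1 if age < 20 else 2 if age < 40 else 3 if age < 65 else 4
            ed = foods.loc[code, "energy_kcal"]
            fat_pct = 100 * 9 * foods.loc[code, "fat_g"] / ed
            edc = 1 + sum(ed >= c for c in DEFAULT_ED_CUTPOINTS)
            fc = 1 + sum(fat_pct >= c for c in DEFAULT_FAT_CUTPOINTS)
            key = (ag, 3, edc, fc)
            vec = foods.loc[code, COMPONENT_COLUMNS].to_numpy() / 100.0
            sums[key] = sums.get(key, 0) + w * vec
            wsums[key] = wsums.get(key, 0) + w
        assert profiles.strata == {StratumKey(*k) for k in wsums}
        for key, w in wsums.items():
            prof = profiles.profile(StratumKey(*key))
            np.testing.assert_allclose(prof.per_gram.to_numpy(), sums[key] / w)

    def test_convexity_and_no_dairy(self, small_db, small_population, small_intake):
        from fatswap.composition import NUTRIENT_COLUMNS, FPED_COLUMNS
        comps = small_db.foods[NUTRIENT_COLUMNS + FPED_COLUMNS].assign(
            dairy_fat_g=small_db.dairy_fat
        )[COMPONENT_COLUMNS]
        metrics = derive_food_metrics(small_db.foods, small_db.dairy_fat)
        profiles = build_replacement_profiles(
            small_intake, small_population, comps, metrics, CFG
        )
        eligible = metrics["replacement_eligible"]
        per_gram = comps[eligible] / 100.0
        lo, hi = per_gram.min(), per_gram.max()
        for key in list(profiles.strata)[:50]:
            prof = profiles.profile(key)
            assert (prof.per_gram >= lo - 1e-12).all()
            assert (prof.per_gram <= hi + 1e-12).all()
            assert prof.per_gram["dairy_fat_g"] == 0.0


class TestResolveFallback:
    def _profiles(self):
        parts = toy_participants({1: (30, 1.0), 2: (30, 1.0)})
        cols_a = dict(energy_kcal=100, fat_g=1, mufa_g=0.5, pufa_g=0.3, calcium_mg=100)
        cols_b = dict(energy_kcal=100, fat_g=5, mufa_g=2.5, pufa_g=1.5, calcium_mg=300)
        profiles, foods = _build(
            [(1, "A", 100.0, "lunch"), (2, "B", 100.0, "lunch")],
            {"A": cols_a, "B": cols_b},
            parts,
        )
        return profiles, foods

    def test_exact_key_is_identity(self):
        profiles, _ = self._profiles()
        key = next(iter(profiles.strata))
        assert profiles.resolve(key).fallback_level == 0

    def test_fat_marginal_composite(self):
        profiles, foods = self._profiles()
        keys = sorted(profiles.strata)
        # A: %E fat 9 -> fat cat 1; B: 45 -> cat 4; ask for an absent fat cat
        absent = StratumKey(keys[0].age_group, keys[0].meal_type, keys[0].ed_category, 6)
        assert absent not in profiles.strata
        prof = profiles.resolve(absent)
        assert prof.fallback_level == 1
        # equal weights -> marginal over fat = mean of both foods per gram
        assert prof.per_gram["calcium_mg"] == pytest.approx(2.0)

    def test_empty_profiles_fail(self):
        empty, _ = _build(
            [(1, "A", 100.0, "lunch")],
            {"A": dict(energy_kcal=100, fat_g=5, sat_fat_g=4, mufa_g=0.5, pufa_g=0.2)},
            toy_participants({1: (30, 1.0)}),
        )  # sole food is saturated-heavy, hence ineligible
        assert len(empty) == 0
        with pytest.raises(EmptyProfileError):
            empty.resolve(StratumKey(1, 1, 1, 1))
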