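"""Synthetic food composition, recipes, survey population and 24-h recalls.

The generator emulates the statistical structure a national 24-h recall
survey linked to a recipe-level food composition database would supply:

* foods spanning wide ranges of energy density (~0-682 kcal/100 g) and
  percent energy from fat (~0.7-97.8 %E), with internally consistent
  nutrient vectors (Atwater energy, fat subtypes summing below total fat);
* dairy fat reaching mixed dishes only through 1-3-level recipes built on
  a small set of dairy leaf ingredients (milk, cream, butter, cheese,
  yogurt, ice-cream mix), so recipe expansion is genuinely exercised;
* a stratified survey population with two PSUs per stratum and positive
  weights;
* participant-days calibrated so the survey-weighted mean percent of
  energy from dairy fat converges to a configurable target (default 5.6),
  with a configurable fraction of zero consumers and mild age/ethnicity
  gradients in dairy-fat propensity.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import composition
from .composition import (
    COMPONENT_COLUMNS,
    FPED_COLUMNS,
    KCAL_PER_G_CARB,
    KCAL_PER_G_FAT,
    KCAL_PER_G_PROTEIN,
    NUTRIENT_COLUMNS,
)
from .profiles import DEFAULT_ED_CUTPOINTS, DEFAULT_FAT_CUTPOINTS

ALL_FOOD_COLUMNS = ["description", "archetype", "is_ingredient", "popularity"] + (
    NUTRIENT_COLUMNS + FPED_COLUMNS
)


class DegenerateConfigError(ValueError):
    """The config cannot populate every energy-density x fat sextile cell
    with a replacement-eligible food."""


class SyntheticConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    ``target_dairy_pct_energy`` is the population survey-weighted mean
    percent of energy from dairy fat the recalls are calibrated to (5.6 is
    the reference population value); ``zero_consumer_frac`` is the share of
    persons consuming no dairy fat at all (0.16 matches a consumer
    subgroup of ~84% of the population).
    """

    n_foods: int = 400
    n_participants: int = 1000
    target_dairy_pct_energy: float = 5.6
    frac_dairy_foods: float = 0.25
    zero_consumer_frac: float = 0.16
    dairy_pct_e_gamma_shape: float = 2.0
    n_strata: int = 15
    psus_per_stratum: int = 2
    age_range: tuple[int, int] = (4, 85)
    meal_labels: tuple[str, ...] = ("breakfast", "lunch", "dinner", "snack", "dessert")
    occasion_probs: tuple[float, ...] = (0.20, 0.25, 0.25, 0.25, 0.05)
    mean_energy_kcal: float = 2080.0
    energy_log_sd: float = 0.28
    items_range: tuple[int, int] = (6, 12)
    dairy_items_range: tuple[int, int] = (1, 3)
    seed: int = 0

    @field_validator("n_foods", "n_participants", "n_strata", "psus_per_stratum")
    @classmethod
    def _positive_counts(cls, v):
        if v < 1:
            raise ValueError("counts must be >= 1")
        return v

    @field_validator("frac_dairy_foods", "zero_consumer_frac")
    @classmethod
    def _fractions(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @field_validator("target_dairy_pct_energy")
    @classmethod
    def _target(cls, v):
        if not 0 <= v < 100:
            raise ValueError("target dairy %E must lie in [0, 100)")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if abs(sum(self.occasion_probs) - 1) > 1e-9:
            raise ValueError("occasion probabilities must sum to 1")
        if len(self.occasion_probs) != len(self.meal_labels):
            raise ValueError("one occasion probability per meal label")
        if self.age_range[0] < 4:
            raise ValueError("study population is aged >= 4 y")
        return self


def _vec(**kwargs) -> pd.Series:
    """Per-100 g component vector with zeros elsewhere; energy recomputed
    from Atwater factors so macro energy is exact."""
    v = pd.Series(0.0, index=NUTRIENT_COLUMNS + FPED_COLUMNS)
    for key, value in kwargs.items():
        v[key] = float(value)
    v["energy_kcal"] = (
        KCAL_PER_G_FAT * v["fat_g"]
        + KCAL_PER_G_PROTEIN * v["protein_g"]
        + KCAL_PER_G_CARB * v["carb_g"]
    )
    return v


# Dairy leaf ingredients (per 100 g), hand-set to realistic magnitudes so
# that removing dairy foods depresses calcium, vitamins A/D, riboflavin and
# B12 the way real diets do.
DAIRY_INGREDIENTS = {
    9001: ("whole milk", _vec(fat_g=3.3, sat_fat_g=1.9, mufa_g=0.8, pufa_g=0.2,
                              protein_g=3.2, carb_g=4.8, calcium_mg=113, vit_d_mcg=1.3,
                              riboflavin_mg=0.17, vit_b12_mcg=0.45, potassium_mg=132,
                              vit_a_mcg=46, sodium_mg=40, magnesium_mg=10,
                              dairy_cup=0.41)),
    9002: ("heavy cream", _vec(fat_g=36.0, sat_fat_g=23.0, mufa_g=9.0, pufa_g=1.5,
                               protein_g=2.1, carb_g=2.8, calcium_mg=66, vit_d_mcg=1.6,
                               riboflavin_mg=0.19, vit_b12_mcg=0.2, vit_a_mcg=411,
                               potassium_mg=95, sodium_mg=27)),
    9003: ("butter", _vec(fat_g=81.0, sat_fat_g=51.0, mufa_g=21.0, pufa_g=3.0,
                          protein_g=0.9, carb_g=0.1, calcium_mg=24, vit_d_mcg=1.5,
                          riboflavin_mg=0.03, vit_b12_mcg=0.17, vit_a_mcg=684,
                          sodium_mg=576)),
    9004: ("cheddar cheese", _vec(fat_g=33.0, sat_fat_g=19.0, mufa_g=9.0, pufa_g=1.4,
                                  protein_g=23.0, carb_g=3.0, calcium_mg=710,
                                  vit_d_mcg=0.6, riboflavin_mg=0.43, vit_b12_mcg=1.1,
                                  vit_a_mcg=263, sodium_mg=653, dairy_cup=2.35,
                                  protein_oz=0.0)),
    9005: ("whole yogurt", _vec(fat_g=3.3, sat_fat_g=2.1, mufa_g=0.9, pufa_g=0.1,
                                protein_g=3.5, carb_g=4.7, calcium_mg=121,
                                riboflavin_mg=0.14, vit_b12_mcg=0.37, potassium_mg=155,
                                vit_a_mcg=27, sodium_mg=46, dairy_cup=0.41)),
    9006: ("ice cream mix", _vec(fat_g=11.0, sat_fat_g=6.8, mufa_g=2.9, pufa_g=0.5,
                                 protein_g=3.5, carb_g=23.6, added_sugar_g=21.0,
                                 calcium_mg=128, riboflavin_mg=0.24, vit_b12_mcg=0.39,
                                 vit_a_mcg=118, sodium_mg=80, dairy_cup=0.30)),
}

# Non-dairy leaf ingredients used as recipe filler and mixture bases.
FILLER_INGREDIENTS = {
    9101: ("wheat flour", _vec(fat_g=1.0, sat_fat_g=0.2, mufa_g=0.1, pufa_g=0.4,
                               protein_g=10.0, carb_g=76.0, fiber_g=2.7, iron_mg=4.6,
                               thiamin_mg=0.8, folic_acid_mcg=180, niacin_mg=5.9,
                               refined_grain_oz=3.5, sodium_mg=2)),
    9102: ("sugar", _vec(carb_g=100.0, added_sugar_g=100.0)),
    9103: ("vegetable oil", _vec(fat_g=100.0, sat_fat_g=14.0, mufa_g=40.0,
                                 pufa_g=42.0)),
    9104: ("water", _vec()),
    9105: ("tomato-vegetable base", _vec(fat_g=0.2, sat_fat_g=0.03, mufa_g=0.03,
                                         pufa_g=0.08, protein_g=1.2, carb_g=5.0,
                                         fiber_g=1.5, potassium_mg=290, vit_c_mg=14,
                                         vit_a_mcg=42, folic_acid_mcg=15,
                                         veg_cup=0.4, sodium_mg=10)),
}

# Archetype parameters: (protein energy-share range, added-sugar carb
# fraction range, fiber carb fraction range, micronutrient medians, FPED
# medians). Micronutrient draws are log-normal around the medians.
_ARCHETYPES = {
    "grain": dict(protein=(0.08, 0.18), sugar=(0.05, 0.25), fiber=(0.03, 0.12),
                  micro=dict(iron_mg=2.0, thiamin_mg=0.25, folic_acid_mcg=55,
                             niacin_mg=1.6, magnesium_mg=30, sodium_mg=350,
                             potassium_mg=90, calcium_mg=35, riboflavin_mg=0.12,
                             vit_b6_mg=0.07),
                  fped=dict(whole_grain_oz=0.8, refined_grain_oz=1.6)),
    "vegetable": dict(protein=(0.10, 0.25), sugar=(0.0, 0.08), fiber=(0.15, 0.40),
                      micro=dict(potassium_mg=230, vit_c_mg=20, vit_a_mcg=120,
                                 folic_acid_mcg=35, magnesium_mg=20, iron_mg=0.8,
                                 sodium_mg=120, calcium_mg=45, riboflavin_mg=0.07,
                                 vit_b6_mg=0.11),
                      fped=dict(veg_cup=0.55, greens_beans_cup=0.05)),
    "fruit": dict(protein=(0.02, 0.08), sugar=(0.0, 0.05), fiber=(0.08, 0.25),
                  micro=dict(potassium_mg=150, vit_c_mg=25, vit_a_mcg=30,
                             folic_acid_mcg=10, magnesium_mg=10, calcium_mg=12),
                  fped=dict(fruit_cup=0.55, whole_fruit_cup=0.45)),
    "meat": dict(protein=(0.35, 0.70), sugar=(0.0, 0.02), fiber=(0.0, 0.02),
                 micro=dict(iron_mg=1.5, niacin_mg=4.0, vit_b6_mg=0.30,
                            vit_b12_mcg=0.9, potassium_mg=240, sodium_mg=400,
                            magnesium_mg=20, riboflavin_mg=0.18, calcium_mg=12),
                 fped=dict(protein_oz=3.2)),
    "seafood": dict(protein=(0.40, 0.75), sugar=(0.0, 0.02), fiber=(0.0, 0.02),
                    micro=dict(vit_d_mcg=2.0, vit_b12_mcg=2.0, niacin_mg=3.0,
                               potassium_mg=280, magnesium_mg=25, iron_mg=0.6,
                               sodium_mg=300, calcium_mg=20, riboflavin_mg=0.1),
                    fped=dict(protein_oz=3.0, seafood_plant_oz=3.0)),
    "legume_nut": dict(protein=(0.15, 0.30), sugar=(0.0, 0.05), fiber=(0.12, 0.35),
                       micro=dict(magnesium_mg=70, iron_mg=2.0, potassium_mg=320,
                                  folic_acid_mcg=55, niacin_mg=1.2, calcium_mg=50,
                                  riboflavin_mg=0.08, vit_b6_mg=0.12),
                       fped=dict(protein_oz=1.8, seafood_plant_oz=1.8,
                                 greens_beans_cup=0.08)),
    "oil": dict(protein=(0.0, 0.03), sugar=(0.0, 0.05), fiber=(0.0, 0.05),
                micro=dict(sodium_mg=250), fped=dict()),
    "sweets": dict(protein=(0.02, 0.08), sugar=(0.50, 0.90), fiber=(0.01, 0.06),
                   micro=dict(sodium_mg=200, iron_mg=1.0, calcium_mg=30,
                              riboflavin_mg=0.06),
                   fped=dict(refined_grain_oz=1.0)),
    "beverage": dict(protein=(0.0, 0.10), sugar=(0.50, 1.00), fiber=(0.0, 0.02),
                     micro=dict(potassium_mg=40, vit_c_mg=8, calcium_mg=8),
                     fped=dict()),
    "mixed": dict(protein=(0.15, 0.35), sugar=(0.0, 0.12), fiber=(0.04, 0.15),
                  micro=dict(sodium_mg=380, potassium_mg=160, iron_mg=1.2,
                             niacin_mg=1.6, vit_b6_mg=0.14, folic_acid_mcg=22,
                             magnesium_mg=20, calcium_mg=35, riboflavin_mg=0.10),
                  fped=dict(veg_cup=0.15, refined_grain_oz=0.8, protein_oz=1.0)),
}
_ARCHETYPE_NAMES = list(_ARCHETYPES)
_ARCHETYPE_PROBS = np.array([0.18, 0.18, 0.10, 0.13, 0.06, 0.10, 0.07, 0.08, 0.07, 0.03])

_ED_BOUNDS = (0.0,) + DEFAULT_ED_CUTPOINTS + (682.0,)
_FAT_BOUNDS = (0.7,) + DEFAULT_FAT_CUTPOINTS + (97.8,)

# Dairy leaf sampling: (code, grams range per 100 g parent, selection prob)
_DAIRY_USE = [
    (9001, (30, 90), 0.30),
    (9005, (30, 90), 0.10),
    (9002, (5, 30), 0.10),
    (9004, (10, 45), 0.25),
    (9003, (2, 15), 0.15),
    (9006, (40, 90), 0.10),
]


@dataclass
class FoodDatabase:
    """Composition table, recipe table, and the derived dairy-fat column."""

    foods: pd.DataFrame
    recipes: pd.DataFrame
    dairy_fat: pd.Series = dc_field(init=False)

    def __post_init__(self):
        self.dairy_fat = composition.compute_dairy_fat_table(self.foods, self.recipes)

    @property
    def consumable(self) -> pd.DataFrame:
        return self.foods[~self.foods["is_ingredient"]]


def _micro_draws(rng, archetype: str) -> dict:
    params = _ARCHETYPES[archetype]
    return {
        key: median * rng.lognormal(0.0, 0.5)
        for key, median in params["micro"].items()
    }


def _fped_draws(rng, archetype: str) -> dict:
    params = _ARCHETYPES[archetype]
    return {
        key: median * rng.lognormal(0.0, 0.4)
        for key, median in params["fped"].items()
    }


def _nondairy_food(rng, ed: float, fat_pct: float, archetype: str, eligible: bool) -> pd.Series:
    """Build a per-100 g vector hitting the requested energy density and
    percent energy from fat exactly."""
    fat = fat_pct / 100.0 * ed / KCAL_PER_G_FAT
    rest_kcal = ed - KCAL_PER_G_FAT * fat
    p_lo, p_hi = _ARCHETYPES[archetype]["protein"]
    protein = rng.uniform(p_lo, p_hi) * rest_kcal / KCAL_PER_G_PROTEIN
    carb = (rest_kcal - KCAL_PER_G_PROTEIN * protein) / KCAL_PER_G_CARB
    if eligible:
        sat_f, mufa_f, pufa_f = rng.uniform(0.08, 0.28), rng.uniform(0.32, 0.50), rng.uniform(0.18, 0.38)
    else:
        sat_f, mufa_f, pufa_f = rng.uniform(0.52, 0.78), rng.uniform(0.10, 0.28), rng.uniform(0.02, 0.12)
    total_f = sat_f + mufa_f + pufa_f
    if total_f > 0.97:
        scale = 0.97 / total_f
        sat_f, mufa_f, pufa_f = sat_f * scale, mufa_f * scale, pufa_f * scale
    s_lo, s_hi = _ARCHETYPES[archetype]["sugar"]
    f_lo, f_hi = _ARCHETYPES[archetype]["fiber"]
    kwargs = dict(
        fat_g=fat, sat_fat_g=sat_f * fat, mufa_g=mufa_f * fat, pufa_g=pufa_f * fat,
        protein_g=protein, carb_g=carb,
        added_sugar_g=rng.uniform(s_lo, s_hi) * carb,
        fiber_g=rng.uniform(f_lo, f_hi) * carb,
    )
    kwargs.update(_micro_draws(rng, archetype))
    kwargs.update(_fped_draws(rng, archetype))
    return _vec(**kwargs)


def generate_food_database(config: SyntheticConfig) -> FoodDatabase:
    """Foods + recipes with guaranteed eligible coverage of every
    energy-density x %E-fat sextile cell.

    Dairy status is Bernoulli(``frac_dairy_foods``) per food; dairy foods
    get 1-3-level recipes over the dairy leaf ingredients. The first 36
    non-dairy foods are pinned, one per sextile cell, to a replacement-
    eligible composition so the substitution model can always resolve a
    same-cell profile.

    Raises
    ------
    DegenerateConfigError
        If fewer than 36 non-dairy foods are available to cover the cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    is_dairy_food = rng.random(config.n_foods) < config.frac_dairy_foods
    n_nondairy = int((~is_dairy_food).sum())
    cells = [(e, f) for e in range(1, 7) for f in range(1, 7)]
    if n_nondairy < len(cells):
        missing = cells[n_nondairy]
        raise DegenerateConfigError(
            f"only {n_nondairy} non-dairy foods for 36 coverage cells; first "
            f"empty cell (ed_category={missing[0]}, fat_category={missing[1]})"
        )

    rows: dict[int, pd.Series] = {}
    meta: dict[int, tuple[str, str, bool]] = {}  # code -> (description, archetype, is_ingredient)
    recipe_rows: list[tuple] = []
    next_intermediate = 5001

    for code, (name, vec) in {**DAIRY_INGREDIENTS, **FILLER_INGREDIENTS}.items():
        rows[code] = vec
        meta[code] = (name, "ingredient", True)

    dairy_codes = [c for c, _, _ in _DAIRY_USE]
    dairy_probs = np.array([p for _, _, p in _DAIRY_USE])
    dairy_ranges = {c: r for c, r, _ in _DAIRY_USE}

    nondairy_seen = 0
    for i in range(config.n_foods):
        code = 1001 + i
        if not is_dairy_food[i]:
            if nondairy_seen < len(cells):
                ed_cat, fat_cat = cells[nondairy_seen]
                ed = rng.uniform(max(_ED_BOUNDS[ed_cat - 1], 20.0), _ED_BOUNDS[ed_cat])
                fat_pct = rng.uniform(_FAT_BOUNDS[fat_cat - 1], _FAT_BOUNDS[fat_cat])
                eligible = True
            elif rng.random() < 0.05:
                ed, fat_pct, eligible = 0.0, 0.0, True  # water/diet beverage
            else:
                ed = float(np.clip(rng.lognormal(np.log(150.0), 0.9), 5.0, 682.0))
                fat_pct = float(np.clip(97.8 * rng.beta(1.6, 2.2), 0.7, 97.8))
                eligible = rng.random() < 0.65
            archetype = (
                "beverage" if ed == 0.0
                else str(rng.choice(_ARCHETYPE_NAMES, p=_ARCHETYPE_PROBS))
            )
            rows[code] = _nondairy_food(rng, ed, fat_pct, archetype, eligible)
            meta[code] = (f"{archetype} food {code}", archetype, False)
            nondairy_seen += 1
            continue

        # dairy-containing food: build its recipe, then its composition as a
        # mixture of the recipe parts plus an archetype-flavoured remainder
        depth = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        leaf = int(rng.choice(dairy_codes, p=dairy_probs / dairy_probs.sum()))
        lo, hi = dairy_ranges[leaf]
        leaf_grams = rng.uniform(lo, hi)
        parent_of_leaf = code
        for level in range(depth - 1):
            inter = next_intermediate
            next_intermediate += 1
            carrier_grams = rng.uniform(25, 60)
            recipe_rows.append((parent_of_leaf, inter, carrier_grams, False))
            meta[inter] = (f"component {inter}", "mixed", True)
            parent_of_leaf = inter
        recipe_rows.append((parent_of_leaf, leaf, leaf_grams, True))
        filler = int(rng.choice(list(FILLER_INGREDIENTS)))
        filler_grams = rng.uniform(5, 30)
        recipe_rows.append((parent_of_leaf, filler, filler_grams, False))

        # compositions for intermediates and the parent, innermost first
        def _mixture(parent):
            mix = pd.Series(0.0, index=NUTRIENT_COLUMNS + FPED_COLUMNS)
            used = 0.0
            for p, ing, grams, _ in recipe_rows:
                if p != parent:
                    continue
                part = rows[ing] if ing in rows else None
                if part is None:
                    continue
                mix = mix + grams / 100.0 * part
                used += grams
            # remainder behaves like a bland base (water/flour blend)
            remainder = max(0.0, 100.0 - used)
            base = 0.8 * rows[9104] + 0.2 * rows[9101]
            mix = mix + remainder / 100.0 * base
            return mix

        # walk back out from the leaf's parent to the food code
        chain_codes = [parent_of_leaf]
        while chain_codes[-1] != code:
            parent = next(p for p, ing, _, _ in recipe_rows if ing == chain_codes[-1])
            chain_codes.append(parent)
        for c in chain_codes:
            mixed = _mixture(c)
            if c == code:
                # season the consumed dish with archetype micronutrients
                extra = _micro_draws(rng, "mixed")
                for key, value in extra.items():
                    mixed[key] += 0.5 * value
            mixed["energy_kcal"] = (
                KCAL_PER_G_FAT * mixed["fat_g"]
                + KCAL_PER_G_PROTEIN * mixed["protein_g"]
                + KCAL_PER_G_CARB * mixed["carb_g"]
            )
            rows[c] = mixed
            if c == code:
                meta[c] = (f"dairy dish {c}", "dairy_dish", False)

    foods = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    foods.index.name = "food_code"
    info = pd.DataFrame.from_dict(
        meta, orient="index", columns=["description", "archetype", "is_ingredient"]
    ).sort_index()
    foods = pd.concat([info, foods], axis=1)
    foods["popularity"] = rng.lognormal(0.0, 0.8, size=len(foods))
    foods = foods[ALL_FOOD_COLUMNS]
    foods.index.name = "food_code"

    recipes = pd.DataFrame(
        recipe_rows,
        columns=["parent_code", "ingredient_code", "grams_per_100g_parent", "is_dairy"],
    )
    db = FoodDatabase(foods=foods, recipes=recipes)

    # verify the eligible-coverage invariant on the generated data
    metrics = composition.derive_food_metrics(db.consumable, db.dairy_fat)
    ok = metrics[metrics["replacement_eligible"] & ~metrics["fat_unclassifiable"]]
    ed_cat = np.searchsorted(DEFAULT_ED_CUTPOINTS, ok["energy_density"], side="right") + 1
    fat_cat = np.searchsorted(DEFAULT_FAT_CUTPOINTS, ok["pct_energy_fat"], side="right") + 1
    occupied = set(zip(ed_cat, fat_cat))
    for cell in cells:
        if cell not in occupied:
            raise DegenerateConfigError(
                f"no replacement-eligible food in cell (ed_category={cell[0]}, "
                f"fat_category={cell[1]}); increase n_foods"
            )
    return db


_ETHNICITIES = ("nh_white", "hispanic", "nh_black", "nh_asian", "other")
_ETHNICITY_PROBS = np.array([0.40, 0.25, 0.20, 0.10, 0.05])
_ETHNICITY_FACTORS = {"nh_white": 1.09, "hispanic": 0.96, "nh_black": 0.73,
                      "nh_asian": 0.68, "other": 0.89}


def _age_factor(age: np.ndarray) -> np.ndarray:
    """Mild decline of dairy-fat share with age, as dietary surveys show."""
    return np.select(
        [age <= 13, age <= 19, age <= 39, age <= 59],
        [1.20, 1.04, 0.95, 0.93],
        default=1.0,
    )


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Participants with ages, demographics, weights and design labels.

    Every stratum receives both PSU labels (the first
    n_strata x psus_per_stratum persons are dealt round-robin to guarantee
    it); weights are log-normal and independent of everything else.
    """
    if config.psus_per_stratum < 2:
        raise ValueError(
            "psus_per_stratum must be >= 2 (between-PSU variance estimation)"
        )
    n_cells = config.n_strata * config.psus_per_stratum
    if config.n_participants < n_cells:
        raise ValueError(
            f"need at least {n_cells} participants to occupy every stratum/PSU cell"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_participants
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    sex = rng.choice(["female", "male"], size=n)
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_PROBS)
    weight = rng.lognormal(np.log(1000.0), 0.5, size=n)

    stratum = np.empty(n, dtype=int)
    psu = np.empty(n, dtype=int)
    grid = np.arange(n_cells)
    stratum[:n_cells] = grid // config.psus_per_stratum + 1
    psu[:n_cells] = grid % config.psus_per_stratum + 1
    stratum[n_cells:] = rng.integers(1, config.n_strata + 1, size=n - n_cells)
    psu[n_cells:] = rng.integers(1, config.psus_per_stratum + 1, size=n - n_cells)

    participants = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "survey_weight": weight,
            "stratum": stratum,
            "psu": psu,
        },
        index=pd.RangeIndex(1, n + 1, name="participant_id"),
    )
    return participants


def generate_recalls(
    population: pd.DataFrame,
    food_db: FoodDatabase,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """One 24-h recall day per participant.

    Each person gets an energy target, a dairy-fat %E propensity (zero for
    a configurable fraction; gamma-distributed with age/ethnicity
    gradients for consumers), dairy item grams sized to meet the dairy-fat
    energy target, and non-dairy items filling the remaining energy.
    Returns columns participant_id, food_code, grams, occasion.
    """
    if len(food_db.foods) == 0:
        raise ValueError("food database is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    consumable = food_db.consumable
    dairy_per_g = food_db.dairy_fat / 100.0
    dairy_foods = consumable.index[dairy_per_g.loc[consumable.index] > 0.005]
    nondairy_foods = consumable.index[dairy_per_g.loc[consumable.index] == 0.0]
    if len(nondairy_foods) == 0:
        raise ValueError("no dairy-free foods to build base diets from")
    target = config.target_dairy_pct_energy
    if target > 0 and len(dairy_foods) == 0:
        raise ValueError("target dairy %E > 0 but the database has no dairy foods")

    nd_pop = food_db.foods.loc[nondairy_foods, "popularity"].to_numpy()
    nd_probs = nd_pop / nd_pop.sum()
    nd_ed_per_g = food_db.foods.loc[nondairy_foods, "energy_kcal"].to_numpy() / 100.0
    if target > 0:
        d_dfe_per_g = dairy_per_g.loc[dairy_foods].to_numpy() * KCAL_PER_G_FAT
        d_ed_per_g = food_db.foods.loc[dairy_foods, "energy_kcal"].to_numpy() / 100.0
        # favour foods where dairy fat is a meaningful share of the food's
        # energy, as the major dairy-fat sources are in real diets
        dairy_share = np.clip(d_dfe_per_g / np.maximum(d_ed_per_g, 1e-9), 0.0, 1.0)
        d_pop = food_db.foods.loc[dairy_foods, "popularity"].to_numpy() * dairy_share
        d_probs = d_pop / d_pop.sum()

    ages = population["age"].to_numpy()
    eth = population["ethnicity"].to_numpy()
    factor = _age_factor(ages) * np.vectorize(_ETHNICITY_FACTORS.get)(eth)
    factor = factor / float(np.mean(factor)) if len(factor) else factor

    p0 = config.zero_consumer_frac
    consumer_mean = target / (1 - p0) if (target > 0 and p0 < 1) else 0.0
    shape = config.dairy_pct_e_gamma_shape

    is_consumer = (rng.random(len(population)) >= p0) if target > 0 else np.zeros(len(population), bool)
    propensity = np.zeros(len(population))
    if target > 0:
        raw = rng.gamma(shape, consumer_mean / shape, size=len(population))
        propensity = np.where(is_consumer, np.clip(raw * factor, 0.3, 30.0), 0.0)

    labels = list(config.meal_labels)
    probs = np.asarray(config.occasion_probs)
    lo_items, hi_items = config.items_range
    lo_d, hi_d = config.dairy_items_range

    pids, codes, grams_out, occ_out = [], [], [], []
    for row, pid in enumerate(population.index):
        energy = rng.lognormal(
            np.log(config.mean_energy_kcal) - config.energy_log_sd**2 / 2,
            config.energy_log_sd,
        )
        p = propensity[row] / 100.0
        dairy_energy_used = 0.0
        n_d = 0
        d_picks = np.empty(0, dtype=int)
        d_grams = np.empty(0)
        if p > 0:
            n_d = int(min(rng.integers(lo_d, hi_d + 1), len(dairy_foods)))
            d_picks = rng.choice(len(dairy_foods), size=n_d, replace=False, p=d_probs)
            split = rng.dirichlet(np.ones(n_d))
            d_grams = p * energy * split / d_dfe_per_g[d_picks]
            dairy_energy_used = float(d_grams @ d_ed_per_g[d_picks])
        n_items = int(min(rng.integers(max(lo_items, 3), hi_items + 1), len(nondairy_foods)))
        picks = rng.choice(len(nondairy_foods), size=n_items, replace=False, p=nd_probs)
        remaining = max(energy - dairy_energy_used, 0.10 * energy)
        split = rng.dirichlet(np.ones(n_items))
        nd_energy = 0.0
        for k, pick in enumerate(picks):
            ed = nd_ed_per_g[pick]
            if ed > 0.05:
                g = float(np.clip(remaining * split[k] / ed, 5.0, 1500.0))
            else:
                g = float(rng.uniform(100.0, 500.0))
            pids.append(pid)
            codes.append(nondairy_foods[pick])
            grams_out.append(g)
            nd_energy += g * ed
        if p > 0:
            # rescale dairy grams so dairy-fat energy is exactly the target
            # share of the realized day's total energy
            dfe0 = float(d_grams @ d_dfe_per_g[d_picks])
            de0 = float(d_grams @ d_ed_per_g[d_picks])
            denom = dfe0 - p * de0
            # denom <= 0 means the picked foods are too dairy-dilute to ever
            # reach the target share; best effort with a bounded scale-up
            scale = p * nd_energy / denom if denom > 1e-9 else 5.0
            d_grams = np.clip(d_grams * np.clip(scale, 0.0, None), 1.0, 800.0)
            for k, pick in enumerate(d_picks):
                pids.append(pid)
                codes.append(dairy_foods[pick])
                grams_out.append(float(d_grams[k]))
        n_new = n_d + n_items
        occ_out.extend(rng.choice(labels, size=n_new, p=probs))

    intake = pd.DataFrame(
        {
            "participant_id": pids,
            "food_code": codes,
            "grams": grams_out,
            "occasion": occ_out,
        }
    )
    return intake


def generate_study(config: SyntheticConfig):
    """Convenience: (food database, population, recalls) from one config."""
    db = generate_food_database(config)
    population = generate_population(config)
    intake = generate_recalls(population, db, config)
    return db, population, intake
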