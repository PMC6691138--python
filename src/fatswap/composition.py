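"""Food-level composition: dairy fat via recipe expansion, energy density,
percent energy from fat, and replacement eligibility.

Every food is described per 100 g edible portion by the nutrient vector in
:data:`NUTRIENT_COLUMNS` plus the food-pattern equivalents in
:data:`FPED_COLUMNS`. Dairy fat per 100 g is not an input column: it is
derived by recursively expanding each food's recipe down to dairy-flagged
ingredients (milk, cream, cheese, yogurt, butter, ice cream, ...) and
summing the fat those ingredients contribute.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Atwater energy conversion factors (kcal per gram).
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_PROTEIN = 4.0
KCAL_PER_G_CARB = 4.0

#: Nutrients carried per 100 g edible portion in a food composition table.
NUTRIENT_COLUMNS = [
    "energy_kcal",
    "protein_g",
    "fat_g",
    "sat_fat_g",
    "mufa_g",
    "pufa_g",
    "carb_g",
    "added_sugar_g",
    "fiber_g",
    "sodium_mg",
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "potassium_mg",
    "vit_a_mcg",
    "vit_c_mg",
    "vit_d_mcg",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vit_b6_mg",
    "vit_b12_mcg",
    "folic_acid_mcg",
]

#: Food-pattern equivalents per 100 g (cup or ounce equivalents), used by
#: the HEI-2015 food-group components.
FPED_COLUMNS = [
    "fruit_cup",
    "whole_fruit_cup",
    "veg_cup",
    "greens_beans_cup",
    "whole_grain_oz",
    "refined_grain_oz",
    "dairy_cup",
    "protein_oz",
    "seafood_plant_oz",
]

#: Derived column: grams of dairy fat per 100 g, from recipe expansion.
DAIRY_FAT_COLUMN = "dairy_fat_g"

#: Full per-100 g component vector tracked through substitution and scoring.
COMPONENT_COLUMNS = NUTRIENT_COLUMNS + FPED_COLUMNS + [DAIRY_FAT_COLUMN]

#: Recipe tables are shallow in practice; deeper nesting indicates bad data.
MAX_RECIPE_DEPTH = 10


class RecipeCycleError(ValueError):
    """A food's recipe graph contains a cycle."""


class MissingIngredientError(KeyError):
    """A recipe references an ingredient with no composition record."""


def _recipe_index(recipes: pd.DataFrame) -> dict:
    """Group recipe rows by parent code for O(1) lookup."""
    idx: dict = {}
    for parent, ing, grams, is_dairy in recipes[
        ["parent_code", "ingredient_code", "grams_per_100g_parent", "is_dairy"]
    ].itertuples(index=False):
        idx.setdefault(parent, []).append((ing, float(grams), bool(is_dairy)))
    return idx


def compute_dairy_fat_per_100g(
    food_code,
    recipes: pd.DataFrame,
    fat_per_100g: Mapping,
    max_depth: int = MAX_RECIPE_DEPTH,
) -> float:
    """Grams of dairy fat per 100 g of ``food_code``.

    Recursively expands the recipe: a dairy-flagged ingredient contributes
    (effective grams per 100 g parent) x (its fat per gram); a non-dairy
    ingredient that itself has a recipe is expanded further; a non-dairy
    leaf contributes nothing. Expansion is linear, so scaling every dairy
    proportion scales the result identically.

    Parameters
    ----------
    food_code
        Code of the parent food.
    recipes
        Table with columns ``parent_code``, ``ingredient_code``,
        ``grams_per_100g_parent``, ``is_dairy``.
    fat_per_100g
        Mapping from ingredient code to total fat g per 100 g; required for
        every dairy-flagged ingredient reached.

    Raises
    ------
    RecipeCycleError
        If the recipe graph revisits a food already on the expansion path.
    MissingIngredientError
        If a dairy-flagged ingredient lacks a fat record.
    """
    index = recipes if isinstance(recipes, dict) else _recipe_index(recipes)
    return _expand_dairy_fat(food_code, index, fat_per_100g, 1.0, (), max_depth)


def _expand_dairy_fat(code, index, fat_per_100g, scale, path, depth_left) -> float:
    if code in path:
        cycle = " -> ".join(map(str, path + (code,)))
        raise RecipeCycleError(f"recipe cycle detected: {cycle}")
    if depth_left < 0:
        raise RecipeCycleError(
            f"recipe expansion for {path[0] if path else code} exceeds depth "
            f"{MAX_RECIPE_DEPTH}"
        )
    total = 0.0
    for ingredient, grams, is_dairy in index.get(code, ()):
        fraction = grams / 100.0
        if is_dairy:
            try:
                fat = float(fat_per_100g[ingredient])
            except KeyError:
                raise MissingIngredientError(
                    f"dairy ingredient {ingredient!r} (in recipe of {code!r}) "
                    "has no fat record"
                ) from None
            total += scale * fraction * fat
        elif ingredient in index:
            total += _expand_dairy_fat(
                ingredient, index, fat_per_100g, scale * fraction,
                path + (code,), depth_left - 1,
            )
        # non-dairy leaf: contributes no dairy fat
    return total


def compute_dairy_fat_table(
    foods: pd.DataFrame, recipes: pd.DataFrame
) -> pd.Series:
    """Dairy fat g/100 g for every food in ``foods`` (indexed by food code).

    Fat contents for recipe expansion come from ``foods['fat_g']``. Values
    exceeding the food's own total fat (possible when recipe proportions and
    the nutrient record disagree) are clamped to total fat and logged.
    """
    fat_lookup = foods["fat_g"].to_dict()
    index = _recipe_index(recipes)
    values = pd.Series(
        [compute_dairy_fat_per_100g(code, index, fat_lookup) for code in foods.index],
        index=foods.index,
        name=DAIRY_FAT_COLUMN,
        dtype=float,
    )
    over = values > foods["fat_g"]
    if over.any():
        logger.info(
            "clamped dairy fat to total fat for %d foods: %s",
            int(over.sum()), list(foods.index[over][:10]),
        )
        values = values.clip(upper=foods["fat_g"])
    return values


def is_replacement_eligible(sat_fat_g, mufa_g, pufa_g, dairy_fat_g):
    """Replacement-pool rule: no dairy fat, and not more saturated than
    unsaturated fat. A tie (SFA == MUFA+PUFA) stays eligible — only a strict
    excess of saturated fat excludes. Accepts scalars or aligned arrays.
    """
    sat = np.asarray(sat_fat_g, dtype=float)
    unsat = np.asarray(mufa_g, dtype=float) + np.asarray(pufa_g, dtype=float)
    dairy = np.asarray(dairy_fat_g, dtype=float)
    out = (dairy == 0.0) & ~(sat > unsat)
    return bool(out) if out.ndim == 0 else out


def derive_food_metrics(foods: pd.DataFrame, dairy_fat: pd.Series) -> pd.DataFrame:
    """Per-food energy density, %E from fat, and eligibility flags.

    Energy density is kcal per 100 g (the composition table's energy
    column). Percent energy from fat is ``100 * 9 * fat_g / energy_kcal``,
    with two degenerate conventions: zero-energy zero-fat foods (water,
    diet drinks) are defined to have 0 %E fat so they remain classifiable,
    while zero-energy foods reporting fat are flagged
    ``fat_unclassifiable`` (NaN %E) and excluded from fat-sextile use.
    """
    energy = foods["energy_kcal"].astype(float)
    fat = foods["fat_g"].astype(float)
    pct = pd.Series(np.nan, index=foods.index, dtype=float)
    pos = energy > 0
    pct[pos] = 100.0 * KCAL_PER_G_FAT * fat[pos] / energy[pos]
    zero_ok = (~pos) & (fat == 0)
    pct[zero_ok] = 0.0
    unclassifiable = (~pos) & (fat > 0)
    if unclassifiable.any():
        logger.warning(
            "%d foods report fat with zero energy; %%E-fat left undefined: %s",
            int(unclassifiable.sum()), list(foods.index[unclassifiable][:10]),
        )
    eligible = is_replacement_eligible(
        foods["sat_fat_g"], foods["mufa_g"], foods["pufa_g"],
        dairy_fat.reindex(foods.index),
    )
    return pd.DataFrame(
        {
            "energy_density": energy,
            "pct_energy_fat": pct,
            "replacement_eligible": eligible,
            "fat_unclassifiable": unclassifiable,
        },
        index=foods.index,
    )
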