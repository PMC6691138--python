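"""Dairy-fat removal and gram-for-gram MUFA/PUFA replacement.

Two removal models, each optionally followed by a swap:

* Model 1 removes every dairy-fat-containing item outright (no limit).
* Model 2 removes dairy-fat-containing items, visited in a seeded random
  order per person, only until the removed dairy-fat energy reaches 5% of
  that person's observed total energy; the boundary item is partially
  removed so the cap is met exactly (default) or skipped (config).

The swap then adds, for every removed gram, an equal number of grams of the
composite replacement profile resolved for (consumer age group, occasion of
the removed item, energy-density and %E-fat category of the removed food).
Replacements carry zero dairy fat by construction, so total grams are
preserved and the substitution is approximately iso-caloric.

Intake tables have columns ``participant_id``, ``food_code``, ``grams``,
``occasion``; a one-person table is a single participant-day.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .composition import COMPONENT_COLUMNS, KCAL_PER_G_FAT
from .profiles import (
    ReplacementProfiles,
    StratificationConfig,
    StratumKey,
    _category,
    age_group_of,
    meal_category_of,
)

INTAKE_COLUMNS = ["participant_id", "food_code", "grams", "occasion"]


@dataclass
class SubstitutionResult:
    """Outcome of one removal (and optionally swap) pass.

    ``intake`` holds the surviving items (partial items with reduced
    grams); ``removed`` the removed portions; ``replacement`` (after a
    swap) one row per removed portion with the grams added back and the
    nutrient totals they contribute.
    """

    intake: pd.DataFrame
    removed: pd.DataFrame
    model_id: Literal["M1_remove", "M2_remove", "M1_swap", "M2_swap"]
    seed: Optional[int] = None
    replacement: Optional[pd.DataFrame] = None

    def dairy_fat_energy_removed(self, dairy_fat_per_100g: pd.Series) -> pd.Series:
        """kcal of dairy fat removed per participant."""
        if len(self.removed) == 0:
            return pd.Series(dtype=float)
        dfe = (
            self.removed["grams_removed"].to_numpy()
            * dairy_fat_per_100g.loc[self.removed["food_code"]].to_numpy()
            / 100.0
            * KCAL_PER_G_FAT
        )
        return pd.Series(dfe, index=self.removed.index).groupby(
            self.removed["participant_id"]
        ).sum()


def _dairy_energy_per_row(intake: pd.DataFrame, dairy_fat_per_100g: pd.Series) -> np.ndarray:
    return (
        intake["grams"].to_numpy()
        * dairy_fat_per_100g.loc[intake["food_code"]].to_numpy()
        / 100.0
        * KCAL_PER_G_FAT
    )


def remove_all_dairy(
    intake: pd.DataFrame, dairy_fat_per_100g: pd.Series
) -> SubstitutionResult:
    """Model 1: drop every item whose food carries any dairy fat.

    Whole items are removed, mixed/combination dishes included, leaving the
    modified day with exactly zero dairy-fat energy.
    """
    has_dairy = dairy_fat_per_100g.loc[intake["food_code"]].to_numpy() > 0
    removed = intake.loc[has_dairy, INTAKE_COLUMNS].rename(
        columns={"grams": "grams_removed"}
    )
    return SubstitutionResult(
        intake=intake.loc[~has_dairy].copy(),
        removed=removed.reset_index(drop=True),
        model_id="M1_remove",
    )


def _person_rng(seed: int, participant_id) -> np.random.Generator:
    """Independent stream per participant-day so population results do not
    depend on processing order."""
    tag = zlib.crc32(str(participant_id).encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def remove_capped_dairy(
    intake: pd.DataFrame,
    dairy_fat_per_100g: pd.Series,
    observed_energy: pd.Series,
    cap: float = 0.05,
    seed: int = 0,
    boundary: Literal["scale", "skip"] = "scale",
) -> SubstitutionResult:
    """Model 2: remove up to ``cap`` (default 5%) of observed energy as
    dairy fat per person.

    Dairy items are visited in a uniformly random seeded order. Items are
    removed whole while the cumulative removed dairy-fat energy stays under
    the person's cap. The first item that would overshoot is partially
    removed, scaling its grams so the cap is met exactly (``boundary=
    'scale'``), or left untouched while later items are still tried
    (``boundary='skip'``). Persons whose total dairy-fat energy is at or
    below the cap lose all dairy items, exactly as under Model 1.

    ``observed_energy``: kcal per participant of the unmodified day.
    """
    if not 0 < cap <= 1:
        raise ValueError(f"cap must be in (0, 1]: {cap}")
    dfe = _dairy_energy_per_row(intake, dairy_fat_per_100g)
    is_dairy_row = dfe > 0

    kept_rows = [intake.loc[~is_dairy_row, INTAKE_COLUMNS]]
    removed_parts: list[pd.DataFrame] = []

    dairy = intake.loc[is_dairy_row].assign(_dfe=dfe[is_dairy_row])
    for pid, rows in dairy.groupby("participant_id", sort=True):
        cap_energy = cap * float(observed_energy.loc[pid])
        total_dfe = float(rows["_dfe"].sum())
        if total_dfe <= cap_energy:
            removed_parts.append(rows)
            continue
        rng = _person_rng(seed, pid)
        order = rng.permutation(len(rows))
        cum = 0.0
        removed_mask = np.zeros(len(rows), dtype=bool)
        partial: Optional[tuple[int, float]] = None  # (positional row, fraction)
        for j in order:
            item_dfe = float(rows["_dfe"].iloc[j])
            if cum + item_dfe <= cap_energy:
                removed_mask[j] = True
                cum += item_dfe
            elif boundary == "scale":
                partial = (j, (cap_energy - cum) / item_dfe)
                cum = cap_energy
                break
            # skip mode: leave item, keep trying smaller ones
        kept = rows.loc[~removed_mask]
        removed = rows.loc[removed_mask]
        if partial is not None:
            j, frac = partial
            row = rows.iloc[[j]].copy()
            removed_piece = row.copy()
            removed_piece["grams"] *= frac
            removed_piece["_dfe"] *= frac
            removed_parts.append(removed_piece)
            row["grams"] *= 1 - frac
            kept = pd.concat([kept.drop(index=row.index), row])
        removed_parts.append(removed)
        kept_rows.append(kept[INTAKE_COLUMNS])

    removed_df = (
        pd.concat(removed_parts)[INTAKE_COLUMNS].rename(columns={"grams": "grams_removed"})
        if removed_parts
        else intake.iloc[0:0][INTAKE_COLUMNS].rename(columns={"grams": "grams_removed"})
    )
    modified = pd.concat(kept_rows)[INTAKE_COLUMNS].sort_index()
    return SubstitutionResult(
        intake=modified.reset_index(drop=True),
        removed=removed_df.reset_index(drop=True),
        model_id="M2_remove",
        seed=seed,
    )


def apply_swap(
    result: SubstitutionResult,
    profiles: ReplacementProfiles,
    participants: pd.DataFrame,
    metrics: pd.DataFrame,
    config: StratificationConfig,
) -> SubstitutionResult:
    """Replace every removed portion gram-for-gram with its stratum
    composite.

    The stratum is keyed by the consumer's age group, the occasion at which
    the removed item was eaten, and the removed food's own energy-density
    and %E-fat categories; unoccupied strata fall back through marginal
    pools. The returned result carries a ``replacement`` table whose
    nutrient columns are grams x per-gram composite (zero dairy fat by
    construction).
    """
    removed = result.removed
    if len(removed) == 0:
        return SubstitutionResult(
            intake=result.intake,
            removed=removed,
            model_id=result.model_id.replace("_remove", "_swap"),  # type: ignore[arg-type]
            seed=result.seed,
            replacement=None,
        )
    ages = participants.loc[removed["participant_id"], "age"].to_numpy()
    keys = pd.DataFrame(
        {
            "age_group": age_group_of(ages, config),
            "meal_type": meal_category_of(removed["occasion"], config),
            "ed_category": _category(
                metrics.loc[removed["food_code"], "energy_density"], config.ed_cutpoints
            ),
            "fat_category": _category(
                metrics.loc[removed["food_code"], "pct_energy_fat"], config.fat_cutpoints
            ),
        },
        index=removed.index,
    )
    cache: dict[StratumKey, tuple[pd.Series, int]] = {}
    per_gram_rows = np.empty((len(removed), len(COMPONENT_COLUMNS)))
    levels = np.empty(len(removed), dtype=int)
    for i, key_vals in enumerate(keys.itertuples(index=False)):
        key = StratumKey(*key_vals)
        if key not in cache:
            prof = profiles.resolve(key)
            cache[key] = (prof.per_gram, prof.fallback_level)
        per_gram, level = cache[key]
        per_gram_rows[i] = per_gram.to_numpy()
        levels[i] = level

    grams = removed["grams_removed"].to_numpy()
    replacement = pd.DataFrame(
        per_gram_rows * grams[:, None], columns=COMPONENT_COLUMNS, index=removed.index
    )
    replacement.insert(0, "participant_id", removed["participant_id"].to_numpy())
    replacement.insert(1, "occasion", removed["occasion"].to_numpy())
    replacement.insert(2, "grams", grams)
    replacement["fallback_level"] = levels
    for j, name in enumerate(keys.columns):
        replacement[name] = keys[name].to_numpy()
    return SubstitutionResult(
        intake=result.intake,
        removed=removed,
        model_id=result.model_id.replace("_remove", "_swap"),  # type: ignore[arg-type]
        seed=result.seed,
        replacement=replacement,
    )
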