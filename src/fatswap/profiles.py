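"""Substitution strata and consumption-weighted replacement profiles.

Every eating event is assigned to one of 4 x 4 x 6 x 6 = 576 strata defined
by the consumer's age group (4-19, 20-39, 40-64, 65+ y), the meal occasion
(breakfast, snack, lunch/dinner, dessert), and sextiles of food energy
density (kcal/100 g) and percent energy from fat. Within each stratum the
replacement "food" is a composite: the survey-weight x grams weighted
average of the per-gram nutrient vectors of all replacement-eligible foods
eaten there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from .composition import COMPONENT_COLUMNS, DAIRY_FAT_COLUMN

logger = logging.getLogger(__name__)

#: Canonical meal categories, in fixed index order 1..4.
MEAL_CATEGORIES = ("breakfast", "snack", "lunch/dinner", "dessert")

#: Energy-density sextile cutpoints (kcal/100 g) from the reference
#: consumption distribution; lower bounds of categories 2-6.
DEFAULT_ED_CUTPOINTS = (49.8, 70.7, 151.5, 235.6, 308.8)

#: %E-from-fat sextile cutpoints; lower bounds of categories 2-6.
DEFAULT_FAT_CUTPOINTS = (16.4, 24.9, 38.4, 48.3, 63.5)

DEFAULT_MEAL_MAP = {
    "breakfast": "breakfast",
    "lunch": "lunch/dinner",
    "dinner": "lunch/dinner",
    "lunch/dinner": "lunch/dinner",
    "snack": "snack",
    "dessert": "dessert",
}

STRATUM_INDEX_NAMES = ["age_group", "meal_type", "ed_category", "fat_category"]


class UnmappedOccasionError(KeyError):
    """An intake row carries an occasion label absent from the meal map."""


class EmptyProfileError(LookupError):
    """No replacement-eligible consumption anywhere; nothing to resolve."""


class StratumKey(NamedTuple):
    age_group: int
    meal_type: int
    ed_category: int
    fat_category: int


class StratificationConfig(BaseModel):
    """Stratum definitions for the substitution model.

    ``age_lower_bounds`` are the lower bounds of the four age groups;
    ``ed_cutpoints`` / ``fat_cutpoints`` are the five sextile cutpoints
    acting as lower bounds of categories 2-6 (a boundary value falls in the
    upper category). When a cutpoint list is None the pipeline computes it
    from weighted consumption via :func:`weighted_quantile_cutpoints`.
    """

    age_lower_bounds: tuple[float, float, float, float] = (4.0, 20.0, 40.0, 65.0)
    meal_map: dict[str, str] = dict(DEFAULT_MEAL_MAP)
    quantile_probs: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 0.90)
    ed_cutpoints: Optional[tuple[float, ...]] = DEFAULT_ED_CUTPOINTS
    fat_cutpoints: Optional[tuple[float, ...]] = DEFAULT_FAT_CUTPOINTS
    consumption_weighting: Literal["grams", "kcal", "events"] = "grams"

    @field_validator("ed_cutpoints", "fat_cutpoints")
    @classmethod
    def _strictly_increasing(cls, v):
        if v is not None:
            if len(v) != 5:
                raise ValueError("exactly 5 cutpoints define 6 categories")
            if not all(a < b for a, b in zip(v, v[1:])):
                raise ValueError("cutpoints must be strictly increasing")
        return v

    @field_validator("meal_map")
    @classmethod
    def _targets_known(cls, v):
        bad = set(v.values()) - set(MEAL_CATEGORIES)
        if bad:
            raise ValueError(f"meal_map targets must be in {MEAL_CATEGORIES}: {bad}")
        return v

    def n_strata(self) -> int:
        return 4 * 4 * 6 * 6


def stratum_key_space(config: StratificationConfig | None = None) -> list[StratumKey]:
    """All stratum keys in the cross product (576 with defaults)."""
    return [
        StratumKey(a, m, e, f)
        for a in range(1, 5)
        for m in range(1, 5)
        for e in range(1, 7)
        for f in range(1, 7)
    ]


def weighted_quantile_cutpoints(
    values: Sequence[float],
    weights: Sequence[float],
    probs: Iterable[float],
) -> np.ndarray:
    """Left-continuous weighted quantiles: for each probability p, the
    smallest value whose cumulative normalized weight reaches p."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute quantiles of an empty sample")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order]) / total
    out = []
    for p in probs:
        if not 0 < p < 1:
            raise ValueError(f"probabilities must lie in (0,1): {p}")
        # tiny slack so exact-mass boundaries are not missed to rounding
        idx = int(np.searchsorted(cw, p - 1e-12, side="left"))
        out.append(v[min(idx, v.size - 1)])
    return np.asarray(out)


def _category(values, cutpoints) -> np.ndarray:
    """1-based category; a value equal to a cutpoint falls in the upper one."""
    return np.searchsorted(np.asarray(cutpoints), np.asarray(values, float),
                           side="right") + 1


def age_group_of(ages, config: StratificationConfig) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < config.age_lower_bounds[0]):
        raise ValueError(
            f"ages below {config.age_lower_bounds[0]} are outside the study population"
        )
    return _category(ages, config.age_lower_bounds[1:])


def meal_category_of(labels, config: StratificationConfig) -> np.ndarray:
    labels = pd.Series(labels, dtype=object)
    mapped = labels.map(config.meal_map)
    if mapped.isna().any():
        missing = sorted(labels[mapped.isna()].unique())
        raise UnmappedOccasionError(f"unmapped occasion labels: {missing}")
    codes = mapped.map({name: i + 1 for i, name in enumerate(MEAL_CATEGORIES)})
    return codes.to_numpy(dtype=int)


def assign_stratum(
    age: float,
    occasion: str,
    energy_density: float,
    pct_energy_fat: float,
    config: StratificationConfig,
) -> StratumKey:
    """Stratum key for one consumption event (deterministic)."""
    if config.ed_cutpoints is None or config.fat_cutpoints is None:
        raise ValueError("cutpoints must be set (fixed or computed) before assignment")
    if np.isnan(pct_energy_fat):
        raise ValueError("pct_energy_fat is undefined for this food (zero energy, fat > 0)")
    return StratumKey(
        int(age_group_of([age], config)[0]),
        int(meal_category_of([occasion], config)[0]),
        int(_category([energy_density], config.ed_cutpoints)[0]),
        int(_category([pct_energy_fat], config.fat_cutpoints)[0]),
    )


@dataclass
class ReplacementProfile:
    """Composite per-gram replacement vector for one stratum (or the
    marginal pool it fell back to)."""

    key: StratumKey
    per_gram: pd.Series  # COMPONENT_COLUMNS, per gram
    total_weight: float
    n_foods: int
    fallback_level: int  # 0 exact .. 4 global pool

    @property
    def energy_per_gram(self) -> float:
        return float(self.per_gram["energy_kcal"])


#: Dimensions dropped at each fallback level, most granular first.
_FALLBACK_DROPS = ("fat_category", "ed_category", "meal_type", "age_group")


class ReplacementProfiles:
    """Weighted nutrient sums per stratum with marginal fallback.

    Holds, per occupied stratum, the weighted sums of per-gram component
    vectors and the total weight, so any marginal composite is the ratio of
    summed numerators to summed denominators over the matching strata.
    """

    def __init__(self, sums: pd.DataFrame):
        # sums: MultiIndex (age_group, meal_type, ed_category, fat_category);
        # columns: one weighted-sum column per component, plus `weight`,
        # plus `n_foods`.
        self.sums = sums

    def __len__(self) -> int:
        return len(self.sums)

    @property
    def strata(self) -> set[StratumKey]:
        return {StratumKey(*k) for k in self.sums.index}

    def _composite(self, frame: pd.DataFrame, key: StratumKey, level: int) -> ReplacementProfile:
        weight = float(frame["weight"].sum())
        per_gram = frame[COMPONENT_COLUMNS].sum(axis=0) / weight
        return ReplacementProfile(
            key=key,
            per_gram=per_gram,
            total_weight=weight,
            n_foods=int(frame["n_foods"].sum()),
            fallback_level=level,
        )

    def profile(self, key: StratumKey) -> Optional[ReplacementProfile]:
        """Exact-stratum profile, or None if the stratum is unoccupied."""
        try:
            row = self.sums.loc[tuple(key)]
        except KeyError:
            return None
        return self._composite(row.to_frame().T, key, level=0)

    def resolve(self, key: StratumKey) -> ReplacementProfile:
        """Profile for ``key``, marginalizing fat, then energy-density, then
        meal, then age until an occupied pool is found."""
        exact = self.profile(key)
        if exact is not None:
            return exact
        if len(self.sums) == 0:
            raise EmptyProfileError("no replacement-eligible consumption anywhere")
        keep = dict(zip(STRATUM_INDEX_NAMES, key))
        for level, drop in enumerate(_FALLBACK_DROPS, start=1):
            keep.pop(drop)
            mask = np.ones(len(self.sums), dtype=bool)
            for name, value in keep.items():
                mask &= self.sums.index.get_level_values(name) == value
            if mask.any():
                logger.debug("stratum %s resolved at fallback level %d", key, level)
                return self._composite(self.sums.loc[mask], key, level)
        raise EmptyProfileError("no replacement-eligible consumption anywhere")


def build_replacement_profiles(
    intake: pd.DataFrame,
    participants: pd.DataFrame,
    foods: pd.DataFrame,
    metrics: pd.DataFrame,
    config: StratificationConfig,
) -> ReplacementProfiles:
    """Consumption-weighted composite profiles from observed intake.

    Each eligible event contributes its food's per-gram component vector
    with weight survey_weight x grams (or x kcal / x 1 per
    ``config.consumption_weighting``). Strata with no eligible events are
    simply absent; :meth:`ReplacementProfiles.resolve` handles them.

    ``intake`` columns: participant_id, food_code, grams, occasion.
    ``participants`` indexed by participant id with ``age`` and
    ``survey_weight``. ``foods`` indexed by food code with COMPONENT_COLUMNS
    per 100 g. ``metrics`` from :func:`~fatswap.composition.derive_food_metrics`.
    """
    ev = intake.merge(
        participants[["age", "survey_weight"]],
        left_on="participant_id", right_index=True, validate="many_to_one",
    ).merge(
        metrics, left_on="food_code", right_index=True, validate="many_to_one",
    )
    ev = ev[ev["replacement_eligible"] & ~ev["fat_unclassifiable"]]
    if len(ev) == 0:
        return ReplacementProfiles(
            pd.DataFrame(
                columns=COMPONENT_COLUMNS + ["weight", "n_foods"],
                index=pd.MultiIndex.from_arrays([[]] * 4, names=STRATUM_INDEX_NAMES),
            )
        )
    ev["age_group"] = age_group_of(ev["age"], config)
    ev["meal_type"] = meal_category_of(ev["occasion"], config)
    ev["ed_category"] = _category(ev["energy_density"], config.ed_cutpoints)
    ev["fat_category"] = _category(ev["pct_energy_fat"], config.fat_cutpoints)

    if config.consumption_weighting == "grams":
        ev["weight"] = ev["survey_weight"] * ev["grams"]
    elif config.consumption_weighting == "kcal":
        ev["weight"] = ev["survey_weight"] * ev["grams"] * ev["energy_density"] / 100.0
    else:  # events
        ev["weight"] = ev["survey_weight"]

    per_gram = foods.loc[ev["food_code"], COMPONENT_COLUMNS].to_numpy() / 100.0
    weighted = per_gram * ev["weight"].to_numpy()[:, None]
    contrib = pd.DataFrame(weighted, columns=COMPONENT_COLUMNS, index=ev.index)
    contrib["weight"] = ev["weight"]
    for name in STRATUM_INDEX_NAMES:
        contrib[name] = ev[name]
    contrib["food_code"] = ev["food_code"]

    grouped = contrib.groupby(STRATUM_INDEX_NAMES)
    sums = grouped[COMPONENT_COLUMNS + ["weight"]].sum()
    sums["n_foods"] = grouped["food_code"].nunique()
    sums = sums[sums["weight"] > 0]

    profiles = ReplacementProfiles(sums)
    # eligibility guarantees no dairy fat can leak into any composite
    assert (sums[DAIRY_FAT_COLUMN] == 0).all()
    return profiles
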