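"""Daily nutrient totals, energy adjustment, NRF 9.3 and HEI-2015 scoring.

NRF 9.3 = NR - LIM. NR sums, over nine qualifying nutrients (protein,
fiber, vitamins A/C/D, calcium, iron, potassium, magnesium), the percent of
the reference daily value supplied per 2,000 kcal, truncated at 100, so NR
lies in [0, 900]. LIM scores three nutrients to limit (added sugars %E,
saturated fat %E, sodium) proportionally between a minimum threshold (0
points) and a maximum threshold (full points), 100 points per nutrient, so
LIM lies in [0, 300] and NRF 9.3 in [-300, 900].

HEI-2015 scores 13 components against per-1,000 kcal density standards:
nine adequacy components (proportional up to the standard) and four
moderation components (proportional down from a lower threshold), totalling
0-100. The fatty-acids component scores the (MUFA+PUFA)/SFA ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from .composition import (
    COMPONENT_COLUMNS,
    DAIRY_FAT_COLUMN,
    KCAL_PER_G_CARB,
    KCAL_PER_G_FAT,
    KCAL_PER_G_PROTEIN,
)

logger = logging.getLogger(__name__)

#: Reference daily values for the nine NR qualifying nutrients.
DEFAULT_DAILY_VALUES = {
    "protein_g": 50.0,
    "fiber_g": 28.0,
    "vit_a_mcg": 900.0,
    "vit_c_mg": 90.0,
    "vit_d_mcg": 20.0,
    "calcium_mg": 1300.0,
    "iron_mg": 18.0,
    "potassium_mg": 4700.0,
    "magnesium_mg": 420.0,
}


@dataclass(frozen=True)
class HEIComponent:
    """One HEI-2015 component: ``std_full`` earns the full score and, for
    moderation/ratio components, ``std_zero`` earns zero. Units are
    cup/oz equivalents per 1,000 kcal, g per 1,000 kcal (sodium), %E
    (added sugars, saturated fat), or a unitless ratio (fatty acids)."""

    name: str
    max_points: float
    kind: Literal["adequacy", "moderation", "ratio"]
    source: Optional[str]  # component column, or None for derived inputs
    std_full: float
    std_zero: float = 0.0


#: Published HEI-2015 scoring standards (density per 1,000 kcal unless noted).
HEI2015_COMPONENTS = (
    HEIComponent("total_fruits", 5, "adequacy", "fruit_cup", 0.8),
    HEIComponent("whole_fruits", 5, "adequacy", "whole_fruit_cup", 0.4),
    HEIComponent("total_vegetables", 5, "adequacy", "veg_cup", 1.1),
    HEIComponent("greens_and_beans", 5, "adequacy", "greens_beans_cup", 0.2),
    HEIComponent("whole_grains", 10, "adequacy", "whole_grain_oz", 1.5),
    HEIComponent("dairy", 10, "adequacy", "dairy_cup", 1.3),
    HEIComponent("total_protein_foods", 5, "adequacy", "protein_oz", 2.5),
    HEIComponent("seafood_plant_proteins", 5, "adequacy", "seafood_plant_oz", 0.8),
    HEIComponent("fatty_acids", 10, "ratio", None, 2.5, 1.2),
    HEIComponent("refined_grains", 10, "moderation", "refined_grain_oz", 1.8, 4.3),
    HEIComponent("sodium", 10, "moderation", None, 1.1, 2.0),  # g/1,000 kcal
    HEIComponent("added_sugars", 10, "moderation", None, 6.5, 26.0),  # %E
    HEIComponent("saturated_fat", 10, "moderation", None, 8.0, 16.0),  # %E
)

HEI_MAXIMA = tuple(c.max_points for c in HEI2015_COMPONENTS)


class ScoreConfig(BaseModel):
    """Daily values, LIM thresholds and the energy-adjustment basis."""

    daily_values: dict[str, float] = dict(DEFAULT_DAILY_VALUES)
    energy_basis_kcal: float = 2000.0
    lim_added_sugar_pct_e: tuple[float, float] = (6.0, 26.0)
    lim_sat_fat_pct_e: tuple[float, float] = (8.0, 16.0)
    lim_sodium_mg: tuple[float, float] = (1100.0, 2000.0)
    #: evaluate the sodium LIM on the 2,000 kcal energy-adjusted amount
    #: (default) or on raw mg/day.
    sodium_energy_adjusted: bool = True

    @field_validator("daily_values")
    @classmethod
    def _positive_dvs(cls, v):
        if any(x <= 0 for x in v.values()):
            raise ValueError("all daily values must be positive")
        return v

    @field_validator("lim_added_sugar_pct_e", "lim_sat_fat_pct_e", "lim_sodium_mg")
    @classmethod
    def _min_below_max(cls, v):
        if not v[0] < v[1]:
            raise ValueError(f"LIM minimum must be below maximum: {v}")
        return v


def daily_totals(
    intake: pd.DataFrame,
    foods: pd.DataFrame,
    replacement: Optional[pd.DataFrame] = None,
    participant_ids: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Per-participant daily sums of all components.

    Item contributions are grams x the food's per-gram vector; replacement
    rows (from a swap) already carry nutrient totals and are added as-is.
    ``participant_ids``, if given, fixes the output index (persons with no
    surviving items get all-zero rows).
    """
    missing = set(intake["food_code"]) - set(foods.index)
    if missing:
        raise KeyError(f"food codes not in composition table: {sorted(missing)[:10]}")
    per_gram = foods.loc[intake["food_code"], COMPONENT_COLUMNS].to_numpy() / 100.0
    contrib = pd.DataFrame(
        per_gram * intake["grams"].to_numpy()[:, None],
        columns=COMPONENT_COLUMNS,
        index=intake["participant_id"].to_numpy(),
    )
    totals = contrib.groupby(level=0).sum()
    if replacement is not None and len(replacement):
        extra = replacement.set_index("participant_id")[COMPONENT_COLUMNS].groupby(level=0).sum()
        totals = totals.add(extra, fill_value=0.0)
    if participant_ids is not None:
        totals = totals.reindex(participant_ids, fill_value=0.0)
    totals.index.name = "participant_id"
    return totals


def macro_pct_energy(totals: pd.DataFrame) -> pd.DataFrame:
    """Percent of energy from each macro component (Atwater factors).

    Rows with zero energy come back as NaN.
    """
    energy = totals["energy_kcal"].replace(0.0, np.nan)
    out = pd.DataFrame(index=totals.index)
    out["protein_pct_e"] = 100 * KCAL_PER_G_PROTEIN * totals["protein_g"] / energy
    out["fat_pct_e"] = 100 * KCAL_PER_G_FAT * totals["fat_g"] / energy
    out["sat_fat_pct_e"] = 100 * KCAL_PER_G_FAT * totals["sat_fat_g"] / energy
    out["mufa_pct_e"] = 100 * KCAL_PER_G_FAT * totals["mufa_g"] / energy
    out["pufa_pct_e"] = 100 * KCAL_PER_G_FAT * totals["pufa_g"] / energy
    out["carb_pct_e"] = 100 * KCAL_PER_G_CARB * totals["carb_g"] / energy
    out["added_sugar_pct_e"] = 100 * KCAL_PER_G_CARB * totals["added_sugar_g"] / energy
    out["dairy_fat_pct_e"] = 100 * KCAL_PER_G_FAT * totals[DAIRY_FAT_COLUMN] / energy
    return out


def energy_adjust(totals: pd.DataFrame, basis_kcal: float = 2000.0) -> pd.DataFrame:
    """Scale each person's totals to a fixed energy basis (default 2,000
    kcal). Percent-of-energy quantities are unchanged by construction.
    Zero-energy rows cannot be adjusted and come back NaN (callers exclude
    them from scoring; a warning is logged)."""
    energy = totals["energy_kcal"]
    zero = energy <= 0
    if zero.any():
        logger.warning("%d zero-energy days excluded from energy adjustment", int(zero.sum()))
    factor = basis_kcal / energy.where(~zero)
    return totals.mul(factor, axis=0)


def nr_score(adjusted: pd.DataFrame, config: ScoreConfig) -> pd.DataFrame:
    """NR components (truncated %DV per nutrient) and their sum.

    ``adjusted`` must already be on the 2,000 kcal basis.
    """
    out = pd.DataFrame(index=adjusted.index)
    for nutrient, dv in config.daily_values.items():
        out[f"nr_{nutrient}"] = np.minimum(100.0, 100.0 * adjusted[nutrient] / dv)
    out["nr"] = out.sum(axis=1, skipna=False)
    return out


def lim_component(value, min_t: float, max_t: float):
    """Proportional limiting fraction in [0, 1]: 0 at/below ``min_t``, 1
    at/above ``max_t``, linear between. Accepts scalars or arrays."""
    if not min_t < max_t:
        raise ValueError(f"min threshold must be below max: {min_t} >= {max_t}")
    frac = (np.asarray(value, dtype=float) - min_t) / (max_t - min_t)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def lim_score(
    totals: pd.DataFrame, config: ScoreConfig, adjusted: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """LIM components (fractions) and the total on the 0-300 scale.

    Added sugars and saturated fat enter as %E (invariant to energy
    adjustment); sodium enters energy-adjusted per config default, raw
    otherwise (``adjusted`` is then not needed).
    """
    pct = macro_pct_energy(totals)
    out = pd.DataFrame(index=totals.index)
    out["lim_added_sugar"] = lim_component(
        pct["added_sugar_pct_e"], *config.lim_added_sugar_pct_e
    )
    out["lim_sat_fat"] = lim_component(pct["sat_fat_pct_e"], *config.lim_sat_fat_pct_e)
    if config.sodium_energy_adjusted:
        if adjusted is None:
            adjusted = energy_adjust(totals, config.energy_basis_kcal)
        sodium = adjusted["sodium_mg"]
    else:
        sodium = totals["sodium_mg"]
    out["lim_sodium"] = lim_component(sodium, *config.lim_sodium_mg)
    out["lim"] = 100.0 * (
        out["lim_added_sugar"] + out["lim_sat_fat"] + out["lim_sodium"]
    )
    return out


def nrf93(nr, lim):
    """NRF 9.3 = NR - LIM, in [-300, 900]."""
    return nr - lim


def hei2015_score(totals: pd.DataFrame, config: ScoreConfig | None = None) -> pd.DataFrame:
    """All 13 HEI-2015 component scores plus ``hei_total``.

    Densities are per 1,000 kcal; added sugars and saturated fat are %E;
    the fatty-acids component scores (MUFA+PUFA)/SFA, with zero saturated
    fat defined as the maximum ratio score (logged). Zero-energy days come
    back NaN.
    """
    energy = totals["energy_kcal"].replace(0.0, np.nan)
    pct = macro_pct_energy(totals)
    per_1000 = lambda col: 1000.0 * totals[col] / energy  # noqa: E731

    out = pd.DataFrame(index=totals.index)
    for comp in HEI2015_COMPONENTS:
        if comp.kind == "adequacy":
            value = per_1000(comp.source)
            score = comp.max_points * np.clip(value / comp.std_full, 0.0, 1.0)
        elif comp.kind == "ratio":
            sat = totals["sat_fat_g"]
            unsat = totals["mufa_g"] + totals["pufa_g"]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(sat > 0, unsat / sat.replace(0.0, np.nan), np.inf)
            n_zero_sat = int((sat == 0).sum())
            if n_zero_sat:
                logger.info(
                    "%d days with zero saturated fat: fatty-acid ratio set to max",
                    n_zero_sat,
                )
            score = comp.max_points * np.clip(
                (ratio - comp.std_zero) / (comp.std_full - comp.std_zero), 0.0, 1.0
            )
            score = pd.Series(score, index=totals.index).where(energy.notna())
        else:  # moderation
            if comp.name == "sodium":
                value = per_1000("sodium_mg") / 1000.0  # g per 1,000 kcal
            elif comp.name == "added_sugars":
                value = pct["added_sugar_pct_e"]
            elif comp.name == "saturated_fat":
                value = pct["sat_fat_pct_e"]
            else:
                value = per_1000(comp.source)
            score = comp.max_points * np.clip(
                (comp.std_zero - value) / (comp.std_zero - comp.std_full), 0.0, 1.0
            )
        out[f"hei_{comp.name}"] = score
    out["hei_total"] = out.sum(axis=1, skipna=False)
    return out


def score_table(totals: pd.DataFrame, config: ScoreConfig | None = None) -> pd.DataFrame:
    """One row per person: NR/LIM components, NRF 9.3, and HEI-2015."""
    config = config or ScoreConfig()
    adjusted = energy_adjust(totals, config.energy_basis_kcal)
    nr = nr_score(adjusted, config)
    lim = lim_score(totals, config, adjusted=adjusted)
    hei = hei2015_score(totals, config)
    out = pd.concat([nr, lim, hei], axis=1)
    out["nrf93"] = nrf93(out["nr"], out["lim"])
    return out
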