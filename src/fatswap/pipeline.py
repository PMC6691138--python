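"""End-to-end study orchestration.

Generate (or load) data -> derive dairy fat and food metrics -> build
replacement profiles -> run the four modeled diets (Model 1/2, remove and
swap) -> score every person-day -> survey-weighted summaries for the total
population and for dairy-fat consumers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from . import io
from .composition import (
    COMPONENT_COLUMNS,
    DAIRY_FAT_COLUMN,
    FPED_COLUMNS,
    KCAL_PER_G_FAT,
    NUTRIENT_COLUMNS,
    derive_food_metrics,
)
from .profiles import (
    ReplacementProfiles,
    StratificationConfig,
    build_replacement_profiles,
    weighted_quantile_cutpoints,
)
from .scores import ScoreConfig, energy_adjust, daily_totals, macro_pct_energy, score_table
from .substitution import (
    SubstitutionResult,
    apply_swap,
    remove_all_dairy,
    remove_capped_dairy,
)
from .survey import (
    SurveyDesign,
    SurveyEstimate,
    relative_change_test,
    share_above_threshold,
    survey_mean_ci,
)
from .synthetic import FoodDatabase, SyntheticConfig, generate_population, generate_recalls, generate_food_database

logger = logging.getLogger(__name__)

MODEL_IDS = ("M1_remove", "M2_remove", "M1_swap", "M2_swap")

#: Energy-adjusted micronutrient outcomes reported in the summaries.
MICRO_OUTCOMES = [
    "calcium_mg", "vit_d_mcg", "fiber_g", "potassium_mg", "vit_a_mcg",
    "thiamin_mg", "riboflavin_mg", "niacin_mg", "vit_b6_mg", "vit_b12_mcg",
    "folic_acid_mcg",
]

PCT_E_OUTCOMES = [
    "protein_pct_e", "fat_pct_e", "sat_fat_pct_e", "pufa_pct_e",
    "mufa_pct_e", "dairy_fat_pct_e", "carb_pct_e", "added_sugar_pct_e",
]


class StudyConfig(BaseModel):
    """Full study configuration: exactly one data source (synthetic config
    or a directory of input CSVs), plus stratification, scoring, the
    Model-2 cap, and a global seed that fans out to the per-stage random
    streams."""

    synthetic: Optional[SyntheticConfig] = None
    input_dir: Optional[Path] = None
    stratification: StratificationConfig = StratificationConfig()
    scores: ScoreConfig = ScoreConfig()
    cap: float = 0.05
    boundary: Literal["scale", "skip"] = "scale"
    seed: int = 0
    calcium_threshold_mg: float = 1000.0
    output_dir: Optional[Path] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of synthetic config or input_dir")
        return self


@dataclass
class StudyResult:
    """Everything the study produced, with the summary tables at the top."""

    config: StudyConfig
    db: FoodDatabase
    participants: pd.DataFrame
    intake: pd.DataFrame
    components: pd.DataFrame  # per-100 g vectors incl. derived dairy fat
    metrics: pd.DataFrame
    profiles: ReplacementProfiles
    substitutions: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    design: Optional[SurveyDesign] = None

    @property
    def consumers(self) -> pd.Series:
        """Persons with any observed dairy-fat energy (the domain mask)."""
        return self.totals["observed"][DAIRY_FAT_COLUMN] > 0


def _load_inputs(config: StudyConfig):
    d = Path(config.input_dir)
    foods = io.read_foods(d / "foods.csv")
    recipes = io.read_recipes(d / "recipes.csv")
    db = FoodDatabase(foods=foods, recipes=recipes)
    participants = io.read_participants(d / "participants.csv")
    intake = io.read_intake(d / "intake.csv")
    return db, participants, intake


def _resolve_cutpoints(
    config: StratificationConfig,
    intake: pd.DataFrame,
    participants: pd.DataFrame,
    metrics: pd.DataFrame,
) -> StratificationConfig:
    """Fill in any unset sextile cutpoints from weighted consumption."""
    if config.ed_cutpoints is not None and config.fat_cutpoints is not None:
        return config
    ev = intake.merge(
        participants[["survey_weight"]], left_on="participant_id", right_index=True
    ).merge(metrics, left_on="food_code", right_index=True)
    w = ev["survey_weight"] * ev["grams"]
    update = {}
    if config.ed_cutpoints is None:
        update["ed_cutpoints"] = tuple(
            weighted_quantile_cutpoints(ev["energy_density"], w, config.quantile_probs)
        )
    if config.fat_cutpoints is None:
        ok = ~ev["fat_unclassifiable"]
        update["fat_cutpoints"] = tuple(
            weighted_quantile_cutpoints(
                ev.loc[ok, "pct_energy_fat"], w[ok], config.quantile_probs
            )
        )
    return config.model_copy(update=update)


def run_substitution_study(config: StudyConfig) -> StudyResult:
    """Run the whole study; fully reproducible given ``config.seed``."""
    logger.info("stage: data")
    if config.synthetic is not None:
        syn = config.synthetic.model_copy(update={"seed": config.seed})
        db = generate_food_database(syn)
        participants = generate_population(syn)
        intake = generate_recalls(participants, db, syn)
    else:
        db, participants, intake = _load_inputs(config)

    logger.info("stage: composition")
    components = db.foods[NUTRIENT_COLUMNS + FPED_COLUMNS].assign(
        **{DAIRY_FAT_COLUMN: db.dairy_fat}
    )[COMPONENT_COLUMNS]
    metrics = derive_food_metrics(db.foods, db.dairy_fat)

    logger.info("stage: profiles")
    strat = _resolve_cutpoints(config.stratification, intake, participants, metrics)
    profiles = build_replacement_profiles(intake, participants, components, metrics, strat)

    logger.info("stage: substitution")
    result = StudyResult(
        config=config, db=db, participants=participants, intake=intake,
        components=components, metrics=metrics, profiles=profiles,
    )
    observed_totals = daily_totals(intake, components, participant_ids=participants.index)
    result.totals["observed"] = observed_totals

    m1 = remove_all_dairy(intake, db.dairy_fat)
    m2 = remove_capped_dairy(
        intake, db.dairy_fat, observed_totals["energy_kcal"],
        cap=config.cap, seed=config.seed, boundary=config.boundary,
    )
    result.substitutions["M1_remove"] = m1
    result.substitutions["M2_remove"] = m2
    result.substitutions["M1_swap"] = apply_swap(m1, profiles, participants, metrics, strat)
    result.substitutions["M2_swap"] = apply_swap(m2, profiles, participants, metrics, strat)

    logger.info("stage: scoring")
    for model_id in MODEL_IDS:
        sub = result.substitutions[model_id]
        result.totals[model_id] = daily_totals(
            sub.intake, components, replacement=sub.replacement,
            participant_ids=participants.index,
        )
    for diet, totals in result.totals.items():
        result.scores[diet] = score_table(totals, config.scores)

    logger.info("stage: summaries")
    result.design = SurveyDesign.from_frame(participants)
    consumers = result.consumers
    result.summaries["total"] = summarize(result, domain=None)
    result.summaries["consumers"] = summarize(result, domain=consumers)

    if config.output_dir is not None:
        persist(result, Path(config.output_dir))
    return result


def _outcome_series(result: StudyResult, diet: str) -> pd.DataFrame:
    """Per-person outcome matrix for one diet version."""
    totals = result.totals[diet]
    adjusted = energy_adjust(totals, result.config.scores.energy_basis_kcal)
    pct = macro_pct_energy(totals)
    scores = result.scores[diet]
    out = pd.DataFrame(index=totals.index)
    out["energy_kcal"] = totals["energy_kcal"]
    for col in PCT_E_OUTCOMES:
        out[col] = pct[col]
    # persons whose modeled diet is empty have no defined %E; dairy fat is
    # still zero by construction of the removal models
    if diet != "observed":
        out["dairy_fat_pct_e"] = out["dairy_fat_pct_e"].fillna(0.0)
    for col in MICRO_OUTCOMES:
        out[f"{col}_adj"] = adjusted[col]
    out["calcium_raw_mg"] = totals["calcium_mg"]
    for col in ["nr", "lim", "nrf93", "hei_total"]:
        out[col] = scores[col]
    for col in scores.columns:
        if col.startswith("hei_") and col != "hei_total":
            out[col] = scores[col]
    return out


def summarize(result: StudyResult, domain: Optional[pd.Series]) -> pd.DataFrame:
    """One row per outcome: observed and modeled survey estimates plus the
    10%-relative-change significance flag for each model."""
    design = result.design
    threshold = result.config.calcium_threshold_mg
    frames = {diet: _outcome_series(result, diet) for diet in ("observed",) + MODEL_IDS}
    outcomes = [c for c in frames["observed"].columns if c != "calcium_raw_mg"]

    rows = []
    for outcome in outcomes:
        obs = survey_mean_ci(frames["observed"][outcome], design, domain=domain)
        row = {
            "outcome": outcome,
            "observed_mean": obs.mean, "observed_ci_low": obs.ci_low,
            "observed_ci_high": obs.ci_high, "n": obs.n,
        }
        for model_id in MODEL_IDS:
            est = survey_mean_ci(frames[model_id][outcome], design, domain=domain)
            test = relative_change_test(obs, est)
            row.update({
                f"{model_id}_mean": est.mean,
                f"{model_id}_ci_low": est.ci_low,
                f"{model_id}_ci_high": est.ci_high,
                f"{model_id}_rel_change": test.relative_change,
                f"{model_id}_p": test.p_value,
                f"{model_id}_significant": test.significant,
            })
        rows.append(row)

    # share consuming >= threshold mg calcium per day (raw intake)
    obs = share_above_threshold(frames["observed"]["calcium_raw_mg"], design, threshold, domain=domain)
    row = {
        "outcome": f"share_calcium_ge_{threshold:g}mg",
        "observed_mean": obs.mean, "observed_ci_low": obs.ci_low,
        "observed_ci_high": obs.ci_high, "n": obs.n,
    }
    for model_id in MODEL_IDS:
        est = share_above_threshold(frames[model_id]["calcium_raw_mg"], design, threshold, domain=domain)
        test = relative_change_test(obs, est)
        row.update({
            f"{model_id}_mean": est.mean,
            f"{model_id}_ci_low": est.ci_low,
            f"{model_id}_ci_high": est.ci_high,
            f"{model_id}_rel_change": test.relative_change,
            f"{model_id}_p": test.p_value,
            f"{model_id}_significant": test.significant,
        })
    rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")


def persist(result: StudyResult, outdir: Path) -> None:
    """Write every intermediate artifact as CSV plus a sha256 manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "foods": result.db.foods,
        "recipes": result.db.recipes,
        "dairy_fat": result.db.dairy_fat.to_frame(),
        "participants": result.participants,
        "intake": result.intake,
        "metrics": result.metrics,
        "profiles": result.profiles.sums,
        "summary_total": result.summaries["total"],
        "summary_consumers": result.summaries["consumers"],
    }
    for model_id, sub in result.substitutions.items():
        tables[f"intake_{model_id}"] = sub.intake
        tables[f"removed_{model_id}"] = sub.removed
        if sub.replacement is not None:
            tables[f"replacement_{model_id}"] = sub.replacement
    for diet, scores in result.scores.items():
        tables[f"scores_{diet}"] = scores
    io.write_tables(outdir, **tables)
    manifest = {}
    for name in tables:
        path = outdir / f"{name}.csv"
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    pd.Series(manifest, name="sha256").to_csv(outdir / "manifest.csv")
    (outdir / "config.json").write_text(result.config.model_dump_json(indent=2))
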