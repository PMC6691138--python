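"""CSV readers/writers for the five study tables and configs.

All tables are plain CSV per the column dictionary below; configs load
from JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

#: Column dictionary for the CSV interchange formats.
COLUMN_DICTIONARY = {
    "foods.csv": {
        "food_code": "integer food identifier (index)",
        "description": "free-text food name",
        "archetype": "generator food archetype",
        "is_ingredient": "True for recipe-only ingredients never consumed directly",
        "popularity": "relative selection weight used by the recall generator",
        "energy_kcal..folic_acid_mcg": "nutrients per 100 g edible portion",
        "fruit_cup..seafood_plant_oz": "food-pattern equivalents per 100 g",
    },
    "recipes.csv": {
        "parent_code": "food the ingredient belongs to",
        "ingredient_code": "ingredient food code",
        "grams_per_100g_parent": "ingredient grams per 100 g of parent",
        "is_dairy": "True when the ingredient is a dairy-fat leaf",
    },
    "participants.csv": {
        "participant_id": "integer person identifier (index)",
        "age": "years (>= 4)",
        "sex": "female/male",
        "ethnicity": "population subgroup label",
        "survey_weight": "positive survey weight",
        "stratum": "sampling stratum label",
        "psu": "primary sampling unit label within stratum",
    },
    "intake.csv": {
        "participant_id": "consumer",
        "food_code": "consumed food",
        "grams": "grams consumed (> 0)",
        "occasion": "meal occasion label",
    },
    "dairy_fat.csv": {
        "food_code": "food identifier (index)",
        "dairy_fat_g": "derived dairy fat g per 100 g from recipe expansion",
    },
}


def write_tables(outdir: Path, **tables) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        if table is None:
            continue
        table.to_csv(outdir / f"{name}.csv")


def read_foods(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="food_code")


def read_recipes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


def read_intake(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def load_config_mapping(path) -> dict:
    """Load a JSON or YAML config file into a plain mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
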