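import numpy as np
import pandas as pd
import pytest

import fatswap as fs
from fatswap.composition import COMPONENT_COLUMNS


def food_row(**overrides) -> pd.Series:
    """Per-100 g component vector, zero except the given columns."""
    row = pd.Series(0.0, index=COMPONENT_COLUMNS)
    for key, value in overrides.items():
        row[key] = float(value)
    return row


def toy_foods(rows: dict) -> pd.DataFrame:
    """Composition table (index food_code) from {code: {col: value}}."""
    foods = pd.DataFrame({code: food_row(**cols) for code, cols in rows.items()}).T
    foods.index.name = "food_code"
    return foods


def toy_participants(people: dict) -> pd.DataFrame:
    """Participants table from {pid: (age, weight)} with a valid two-PSU
    single-stratum design."""
    pids = list(people)
    return pd.DataFrame(
        {
            "age": [people[p][0] for p in pids],
            "survey_weight": [people[p][1] for p in pids],
            "stratum": 1,
            "psu": [1 + i % 2 for i in range(len(pids))],
        },
        index=pd.Index(pids, name="participant_id"),
    )


@pytest.fixture(scope="session")
def small_config():
    return fs.SyntheticConfig(n_foods=150, n_participants=250, seed=11)


@pytest.fixture(scope="session")
def small_db(small_config):
    return fs.generate_food_database(small_config)


@pytest.fixture(scope="session")
def small_population(small_config):
    return fs.generate_population(small_config)


@pytest.fixture(scope="session")
def small_intake(small_config, small_db, small_population):
    return fs.generate_recalls(small_population, small_db, small_config)


@pytest.fixture(scope="session")
def small_study():
    cfg = fs.StudyConfig(
        synthetic=fs.SyntheticConfig(n_foods=200, n_participants=400), seed=5
    )
    return fs.run_substitution_study(cfg)
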