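"""Cohort table schema shared by the generator, models and pipeline.

A cohort is a plain pandas DataFrame with one row per participant:
behavior minutes (``sleep``, ``sb``, ``lpa``, ``mvpa``), covariates,
outcome scores at wave 0 and — for prospective data — wave-1 scores and
change scores.  This module pins the column names, the categorical level
orders (the first level is the regression reference), and CSV round-trip
helpers, so every stage agrees on the schema.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .composition import DEFAULT_LABELS

__all__ = [
    "BEHAVIOR_COLUMNS",
    "CATEGORICAL_LEVELS",
    "CONTINUOUS_COVARIATES",
    "MODEL_COVARIATES",
    "OUTCOMES",
    "read_cohort_csv",
    "write_cohort_csv",
    "behavior_matrix",
]

#: behavior minute columns, in the canonical part order
BEHAVIOR_COLUMNS: dict[str, str] = {
    "Sleep": "sleep",
    "SB": "sb",
    "LPA": "lpa",
    "MVPA": "mvpa",
}

#: categorical covariates with level order; the first level is the
#: reference category in regression designs
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["men", "women"],
    "education": ["no_studies", "primary", "secondary", "university"],
    "marital_status": ["single", "married", "separated", "widowed"],
    "household_economy": ["difficult", "easy"],
    "smoking": ["current", "former", "never"],
    "alcohol": ["heavy", "moderate", "former", "never"],
    "gait_speed": ["score_0", "score_1", "score_2", "score_3", "score_4"],
    "chronic_diseases": ["none", "one", "two_plus"],
}

CONTINUOUS_COVARIATES: list[str] = ["age", "energy_intake", "bmi", "mmse"]

#: cumulative adjustment sets: model 1 (sex, age), model 2 adds
#: socioeconomic covariates, model 3 adds lifestyle and health covariates
MODEL_COVARIATES: dict[int, list[str]] = {
    1: ["sex", "age"],
    2: ["sex", "age", "education", "marital_status", "household_economy"],
    3: [
        "sex",
        "age",
        "education",
        "marital_status",
        "household_economy",
        "smoking",
        "alcohol",
        "energy_intake",
        "bmi",
        "mmse",
        "gait_speed",
        "chronic_diseases",
    ],
}

OUTCOMES: list[str] = ["depression", "loneliness", "happiness", "mcs"]


def apply_categorical_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    """Cast the known categorical columns to ordered-level Categoricals."""
    out = df.copy()
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in out.columns:
            out[col] = pd.Categorical(out[col], categories=levels)
    return out


def behavior_matrix(cohort: pd.DataFrame, labels: Sequence[str] = DEFAULT_LABELS):
    """The (n, 4) behavior-minute matrix in canonical part order."""
    cols = [BEHAVIOR_COLUMNS[lab] for lab in labels]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing behavior columns {missing}")
    return cohort[cols].to_numpy(dtype=float)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a participant table and restore categorical level orders."""
    return apply_categorical_dtypes(pd.read_csv(path))


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
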