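"""Synthetic cohorts with the structure the analysis assumes.

Time-use compositions are logistic-normal: a multivariate normal on the
ilr scale, centred at the ilr image of a chosen mean composition, mapped
back to the simplex.  Covariates are drawn from configurable marginals
(defaults emulate a community-dwelling cohort of adults aged >= 65),
outcomes are linear in the ilr coordinates plus covariates plus Gaussian
noise and then mapped onto each instrument's score range, a second wave
is produced with drift and completely-at-random attrition, and per-day
wear records support the valid-day / valid-participant filters.

All randomness flows from ``config.seed`` through fixed, documented
stream ids (one per operation), so each stage is individually
reproducible and adding participants to one stage does not disturb
another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import BEHAVIOR_COLUMNS, CATEGORICAL_LEVELS, OUTCOMES
from .composition import (
    DEFAULT_LABELS,
    MINUTES_PER_DAY,
    Composition,
    canonical_basis,
    close,
    ilr_inverse,
    ilr_transform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeEffect",
    "WearModel",
    "GeneratorConfig",
    "default_outcome_effects",
    "default_covariate_marginals",
    "generate_cohort",
    "generate_wave1",
    "generate_day_records",
    "apply_validity_filter",
]

# stream ids for per-operation RNG splitting
_STREAM_COMPOSITION = 1
_STREAM_COVARIATES = 2
_STREAM_OUTCOMES = 3
_STREAM_WAVE1 = 4
_STREAM_DAYS = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class OutcomeEffect:
    """Generative model for one outcome.

    The noiseless mean on the model scale is

        intercept + ilr_beta . z + sum(covariate effects)

    with z the canonical-basis ilr coordinates of the participant's
    composition.  ``transform`` maps the noisy draw onto the instrument's
    scale: ``"round_clip"`` rounds to integers and clips to ``bounds``
    (ordinal scales), ``"clip"`` clips only (the 0-100 MCS), ``"none"``
    leaves the draw untouched (useful for estimator checks, where
    rounding would attenuate coefficients).
    """

    intercept: float
    ilr_beta: tuple[float, float, float]
    noise_sd: float
    covariate_beta: Mapping[str, object] = field(default_factory=dict)
    transform: str = "round_clip"
    bounds: tuple[float, float] | None = None

    def linear_predictor(self, z: np.ndarray, cohort: pd.DataFrame) -> np.ndarray:
        lp = self.intercept + z @ np.asarray(self.ilr_beta, dtype=float)
        for col, beta in self.covariate_beta.items():
            if isinstance(beta, Mapping):  # categorical: level -> effect
                lp = lp + cohort[col].map(lambda v: beta.get(v, 0.0)).to_numpy(float)
            else:
                lp = lp + float(beta) * cohort[col].to_numpy(float)
        return lp

    def apply_transform(self, values: np.ndarray, name: str = "") -> np.ndarray:
        if self.transform == "none":
            return values
        if self.bounds is None:
            raise ValueError(f"outcome {name!r}: transform {self.transform} needs bounds")
        lo, hi = self.bounds
        if self.transform == "round_clip":
            out = np.clip(np.rint(values), lo, hi)
        elif self.transform == "clip":
            out = np.clip(values, lo, hi)
        else:
            raise ValueError(f"unknown transform {self.transform!r}")
        rate = float(np.mean((values < lo) | (values > hi)))
        if rate > 0:
            logger.info("outcome %s: %.1f%% of draws truncated to [%s, %s]",
                        name, 100 * rate, lo, hi)
        return out


def default_outcome_effects() -> dict[str, OutcomeEffect]:
    """Default generative effects for the four outcomes.

    Directions follow the pattern the analysis is meant to detect: time
    in MVPA relative to the rest is beneficial (lower depression and
    loneliness, higher happiness and MCS).  Intercepts are set so that,
    at the default mean composition and covariate marginals, outcome
    means land near 0.93 (depression), 3.69 (loneliness), 7.49
    (happiness) and 50.4 (MCS) with SDs near the instruments' observed
    spread.
    """
    return {
        "depression": OutcomeEffect(
            intercept=0.19,
            ilr_beta=(0.25, 0.05, 0.35),
            noise_sd=1.6,
            covariate_beta={"sex": {"women": 0.3}},
            transform="round_clip",
            bounds=(0, 10),
        ),
        "loneliness": OutcomeEffect(
            intercept=3.55,
            ilr_beta=(0.05, 0.0, 0.12),
            noise_sd=1.33,
            transform="round_clip",
            bounds=(3, 9),
        ),
        "happiness": OutcomeEffect(
            intercept=7.98,
            ilr_beta=(-0.05, -0.15, -0.22),
            noise_sd=1.70,
            transform="round_clip",
            bounds=(0, 10),
        ),
        "mcs": OutcomeEffect(
            intercept=54.92,
            ilr_beta=(-0.8, 0.5, -1.5),
            noise_sd=9.4,
            covariate_beta={"age": -0.05},
            transform="clip",
            bounds=(0, 100),
        ),
    }


def default_covariate_marginals() -> dict[str, object]:
    """Covariate marginals for the default cohort.

    Categorical frequencies and continuous mean/SD pairs describe a
    community-dwelling sample of adults aged 65+ (majority women, married,
    never smokers, moderate drinkers, primary education, easy household
    economy).  Continuous entries are (mean, sd) with hard ranges applied
    after the draw.
    """
    return {
        "sex": {"men": 0.4693, "women": 0.5307},
        "education": {"no_studies": 0.1543, "primary": 0.4821,
                      "secondary": 0.1808, "university": 0.1828},
        "marital_status": {"single": 0.0659, "married": 0.6605,
                           "separated": 0.0695, "widowed": 0.2041},
        "household_economy": {"difficult": 0.1426, "easy": 0.8574},
        "smoking": {"current": 0.0936, "former": 0.3813, "never": 0.5251},
        "alcohol": {"heavy": 0.0466, "moderate": 0.6979,
                    "former": 0.0671, "never": 0.1884},
        "gait_speed": {"score_0": 0.0028, "score_1": 0.0362, "score_2": 0.0900,
                       "score_3": 0.1756, "score_4": 0.6955},
        "chronic_diseases": {"none": 0.1965, "one": 0.3857, "two_plus": 0.4178},
        "age": (71.68, 4.33),
        "energy_intake": (1944.99, 345.03),
        "bmi": (27.76, 4.42),
        "mmse": (27.99, 2.00),
    }


_CONTINUOUS_RANGES = {
    "age": (65.0, 105.0),
    "energy_intake": (500.0, 6000.0),
    "bmi": (14.0, 60.0),
    "mmse": (0.0, 30.0),
}


@dataclass(frozen=True)
class WearModel:
    """Per-day accelerometer wear-time model (hours, truncated to [0, 24])."""

    mean_hours: float = 23.8
    sd_hours: float = 1.5
    day_ilr_sd: float = 0.25  # day-to-day spread around the participant mean


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything :func:`generate_cohort` and friends need.

    Defaults emulate the study conditions of a two-wave accelerometer
    cohort of older adults: the mean composition is the published
    geometric mean of the four behaviors, ilr variability is diagonal
    with MVPA the most variable in relative terms, follow-up averages
    2.31 +/- 0.31 years, and about a third of participants are lost
    before wave 1 (1679 of 2489 retained).
    """

    n: int = 2489
    seed: int = 0
    mean_composition: Composition = field(
        default_factory=lambda: close((470.59, 778.61, 143.28, 47.52))
    )
    ilr_cov: np.ndarray = field(
        default_factory=lambda: np.diag([0.04, 0.04, 0.09])
    )
    covariate_marginals: Mapping[str, object] = field(
        default_factory=default_covariate_marginals
    )
    outcome_effects: Mapping[str, OutcomeEffect] = field(
        default_factory=default_outcome_effects
    )
    followup_years_mean: float = 2.31
    followup_years_sd: float = 0.31
    attrition_rate: float = 1.0 - 1679.0 / 2489.0
    wave1_drift: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "depression": (0.06, 1.2),
            "loneliness": (0.08, 1.0),
            "happiness": (-0.14, 1.3),
            "mcs": (-0.59, 7.0),
        }
    )
    #: optional baseline-composition effect on the wave-1 change (canonical
    #: ilr scale); zero by default (no prospective effect)
    change_ilr_beta: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    wear_model: WearModel = field(default_factory=WearModel)

    def __post_init__(self) -> None:
        cov = np.asarray(self.ilr_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("ilr_cov must be a symmetric 3x3 matrix")
        eig = np.linalg.eigvalsh(cov)
        if np.any(eig < -1e-12):
            raise ValueError(f"ilr_cov is not positive semi-definite (eigs {eig})")
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition_rate must be in [0, 1)")
        for col, marg in self.covariate_marginals.items():
            if isinstance(marg, Mapping):
                s = float(sum(marg.values()))
                if abs(s - 1.0) > 5e-3:
                    raise ValueError(
                        f"marginal frequencies for {col!r} sum to {s}, not 1"
                    )
        object.__setattr__(self, "ilr_cov", cov)

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _draw_compositions(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    mu = ilr_transform(config.mean_composition, canonical_basis())
    z = rng.multivariate_normal(mu, config.ilr_cov, size=config.n,
                                method="svd")
    return ilr_inverse(z, canonical_basis(), total=MINUTES_PER_DAY,
                       labels=DEFAULT_LABELS)


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    out: dict[str, object] = {}
    for col, marg in config.covariate_marginals.items():
        if isinstance(marg, Mapping):
            levels = list(marg.keys())
            p = np.asarray(list(marg.values()), dtype=float)
            p = p / p.sum()
            draws = rng.choice(len(levels), size=config.n, p=p)
            cats = CATEGORICAL_LEVELS.get(col, levels)
            out[col] = pd.Categorical([levels[i] for i in draws], categories=cats)
        else:
            mean, sd = marg
            vals = rng.normal(mean, sd, size=config.n)
            lo, hi = _CONTINUOUS_RANGES.get(col, (-np.inf, np.inf))
            vals = np.clip(vals, lo, hi)
            if col == "mmse":
                vals = np.rint(vals)
            out[col] = vals
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a wave-0 cohort table: compositions, covariates, outcomes.

    Deterministic under ``config.seed``.  Compositions are strictly
    positive (logistic-normal support) and closed to 1440 min/day.
    """
    x = _draw_compositions(config, _rng(config.seed, _STREAM_COMPOSITION))
    cov = _draw_covariates(config, _rng(config.seed, _STREAM_COVARIATES))

    df = pd.DataFrame(
        x, columns=[BEHAVIOR_COLUMNS[lab] for lab in DEFAULT_LABELS]
    )
    df.insert(0, "participant_id", np.arange(1, config.n + 1))
    df = pd.concat([df, cov], axis=1)

    z = ilr_transform(x, canonical_basis(), labels=DEFAULT_LABELS)
    rng = _rng(config.seed, _STREAM_OUTCOMES)
    truncation: dict[str, float] = {}
    for name, eff in config.outcome_effects.items():
        raw = eff.linear_predictor(z, df) + rng.normal(0.0, eff.noise_sd,
                                                       size=config.n)
        df[name] = eff.apply_transform(raw, name=name)
        if eff.transform != "none" and eff.bounds is not None:
            lo, hi = eff.bounds
            truncation[name] = float(np.mean((raw < lo) | (raw > hi)))
    df.attrs["truncation_rates"] = truncation
    df.attrs["wave"] = 0
    return df


def generate_wave1(
    cohort_w0: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Second-wave outcomes with drift and completely-at-random attrition.

    Returns the wave-1 table for retained participants (columns
    ``<outcome>_w1`` and ``<outcome>_change`` merged onto the wave-0
    rows) and a boolean retention flag aligned to ``cohort_w0``.
    Wave-1 scores are wave-0 scores plus a configured mean drift, an
    optional baseline-composition effect, and noise, re-mapped onto the
    instrument ranges.
    """
    rng = _rng(config.seed, _STREAM_WAVE1)
    n = len(cohort_w0)
    retained = pd.Series(rng.random(n) >= config.attrition_rate,
                         index=cohort_w0.index, name="retained")
    sub = cohort_w0.loc[retained].copy()
    from .cohort import behavior_matrix

    z = ilr_transform(behavior_matrix(sub), canonical_basis(),
                      labels=DEFAULT_LABELS)
    sub["followup_years"] = np.clip(
        rng.normal(config.followup_years_mean, config.followup_years_sd,
                   size=len(sub)),
        0.1, None,
    )
    for name in config.outcome_effects:
        drift, noise_sd = config.wave1_drift.get(name, (0.0, 0.0))
        delta = np.full(len(sub), float(drift))
        beta = config.change_ilr_beta.get(name)
        if beta is not None:
            delta = delta + z @ np.asarray(beta, dtype=float)
        if noise_sd > 0:
            delta = delta + rng.normal(0.0, noise_sd, size=len(sub))
        eff = config.outcome_effects[name]
        w1 = eff.apply_transform(sub[name].to_numpy(float) + delta,
                                 name=f"{name}_w1")
        sub[f"{name}_w1"] = w1
        sub[f"{name}_change"] = w1 - sub[name].to_numpy(float)
    sub.attrs["wave"] = 1
    return sub, retained


def generate_day_records(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Seven per-participant accelerometer days (days 6-7 flagged weekend).

    Each day draws wear hours from the wear model (truncated to [0, 24])
    and a day-level composition around the participant's mean (ilr noise),
    closed to the worn minutes, so behavior minutes never exceed
    wear_hours * 60.
    """
    rng = _rng(config.seed, _STREAM_DAYS)
    wm = config.wear_model
    from .cohort import behavior_matrix

    x = behavior_matrix(cohort)
    z = ilr_transform(x, canonical_basis(), labels=DEFAULT_LABELS)
    rows = []
    for (pid, zi) in zip(cohort["participant_id"], z):
        wear = np.clip(rng.normal(wm.mean_hours, wm.sd_hours, size=7), 0.0, 24.0)
        zd = zi + rng.normal(0.0, wm.day_ilr_sd, size=(7, 3))
        comps = ilr_inverse(zd, canonical_basis(), total=1.0,
                            labels=DEFAULT_LABELS)
        for day in range(1, 8):
            minutes = comps[day - 1] * wear[day - 1] * 60.0
            rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "weekend": day >= 6,
                    "wear_hours": wear[day - 1],
                    "sleep": minutes[0],
                    "sb": minutes[1],
                    "lpa": minutes[2],
                    "mvpa": minutes[3],
                }
            )
    return pd.DataFrame(rows)


def apply_validity_filter(
    day_records: pd.DataFrame,
    min_wear_hours: float = 16.0,
    min_valid_days: int = 4,
    min_weekend_days: int = 1,
) -> tuple[list, pd.DataFrame]:
    """Valid-day / valid-participant filter and per-participant compositions.

    A day is valid iff it recorded at least ``min_wear_hours`` hours; a
    participant is retained iff they have at least ``min_valid_days``
    valid days including at least ``min_weekend_days`` valid weekend
    days.  Retained participants get the arithmetic mean of their valid
    days' behavior minutes, closed to 1440 min/day.  Returns the retained
    ids and a table (participant_id, sleep, sb, lpa, mvpa).  Counts in
    and out are logged.
    """
    if day_records.empty:
        raise ValueError("no day records to filter")
    valid = day_records[day_records["wear_hours"] >= min_wear_hours]
    stats = valid.groupby("participant_id").agg(
        n_valid=("day", "size"), n_weekend=("weekend", "sum")
    )
    keep = stats[
        (stats["n_valid"] >= min_valid_days)
        & (stats["n_weekend"] >= min_weekend_days)
    ].index
    n_total = day_records["participant_id"].nunique()
    logger.info(
        "validity filter: %d of %d participants retained (>=%d valid days"
        " of >=%.0f h incl. >=%d weekend)",
        len(keep), n_total, min_valid_days, min_wear_hours, min_weekend_days,
    )
    means = (
        valid[valid["participant_id"].isin(keep)]
        .groupby("participant_id")[["sleep", "sb", "lpa", "mvpa"]]
        .mean()
    )
    closed = means.to_numpy() * (MINUTES_PER_DAY
                                 / means.sum(axis=1).to_numpy()[:, None])
    out = pd.DataFrame(closed, columns=["sleep", "sb", "lpa", "mvpa"],
                       index=means.index).reset_index()
    return list(keep), out
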