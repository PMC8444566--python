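import numpy as np
import pandas as pd
import pytest

from timecoda import (
    GeneratorConfig,
    OutcomeEffect,
    close,
    generate_cohort,
)

#: published geometric-mean composition of the cross-sectional sample,
#: as percent of the day and as minutes/day
TABLE1_PCT = (32.68, 54.07, 9.95, 3.30)
TABLE1_MIN = (470.59, 778.61, 143.28, 47.52)


@pytest.fixture(scope="session")
def table1_mean():
    return close(TABLE1_PCT, total=1440.0)


def slim_config(n, seed, ilr_beta=(0.0, 0.0, 0.0), noise_sd=1.0,
                transform="none", **kwargs):
    """A minimal generator setup: one continuous outcome ("mcs" column),
    sex and age as the only covariates.  Used for estimator checks where
    the full covariate panel and ordinal rounding would only add noise."""
    return GeneratorConfig(
        n=n,
        seed=seed,
        covariate_marginals={
            "sex": {"men": 0.4693, "women": 0.5307},
            "age": (71.68, 4.33),
        },
        outcome_effects={
            "mcs": OutcomeEffect(
                intercept=50.0,
                ilr_beta=tuple(ilr_beta),
                noise_sd=noise_sd,
                transform=transform,
                bounds=(0, 100) if transform != "none" else None,
            )
        },
        **kwargs,
    )


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-condition wave-0 cohort, shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n=800, seed=42))


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a known continuous linear-in-ilr outcome (no rounding)."""
    cfg = slim_config(n=2000, seed=7, ilr_beta=(0.5, -0.3, 0.8), noise_sd=2.0)
    return generate_cohort(cfg), cfg
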