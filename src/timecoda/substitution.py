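"""Compositional isotemporal substitution.

Given a fitted composition model, predict the change in the outcome when
a fixed duration (30 min by default) is reallocated from one behavior to
another while the remaining behaviors are held constant.  Both the
reference day and the reallocated day are evaluated on the ilr scale, so
the predicted difference is

    ES = (ilr(reference +/- delta) - ilr(reference)) . beta_comp

with beta_comp the fitted composition coefficients.  Covariate terms are
shared between the two predictions and cancel exactly, so the ES does not
depend on where the covariates are set.  The 95% CI is the exact
normal-theory interval for a linear contrast of OLS coefficients:
ES +/- t(0.975, residual df) * sqrt(c' Sigma c).  A seeded parametric
bootstrap over the coefficient distribution is available as an
alternative interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import behavior_matrix
from .composition import (
    Composition,
    MINUTES_PER_DAY,
    close,
    compositional_mean,
    ilr_transform,
)
from .regression import FitResult

__all__ = [
    "SubstitutionEstimate",
    "SubstitutionGrid",
    "substitute",
    "substitution_grid",
    "default_reference",
]


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Predicted outcome change for one delta-minute reallocation."""

    from_part: str
    to_part: str
    delta: float
    es: float
    ci_low: float
    ci_high: float
    se: float
    reference: Composition

    def __post_init__(self) -> None:
        if self.from_part == self.to_part:
            raise ValueError("from_part and to_part must differ")
        if not self.ci_low <= self.es <= self.ci_high:
            raise ValueError("inconsistent confidence bounds")

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _reallocated(reference: Composition, from_part: str, to_part: str,
                 delta: float) -> Composition:
    if from_part == to_part:
        raise ValueError("from_part and to_part must differ")
    for part in (from_part, to_part):
        if part not in reference.labels:
            raise ValueError(f"unknown behavior {part!r};"
                             f" parts are {reference.labels}")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta >= reference[from_part]:
        raise ValueError(
            f"cannot move {delta} min out of {from_part!r}: the reference"
            f" day only spends {reference[from_part]:.2f} min there"
        )
    parts = reference.parts.copy()
    i, j = reference.labels.index(from_part), reference.labels.index(to_part)
    parts[i] -= delta
    parts[j] += delta
    return Composition(parts, reference.labels, reference.total)


def substitute(
    fit: FitResult,
    from_part: str,
    to_part: str,
    delta: float = 30.0,
    reference: Composition | None = None,
    level: float = 0.95,
    bootstrap: int | None = None,
    seed: int = 0,
) -> SubstitutionEstimate:
    """ES and CI for reallocating ``delta`` minutes between two behaviors.

    ``reference`` defaults to the model's mean-composition day and must be
    closed to the same total (minutes/day); the donor part must keep a
    positive duration after the move.  ``bootstrap`` (number of draws)
    switches the CI to a seeded parametric bootstrap over the coefficient
    sampling distribution; the default is the exact t interval.
    """
    if reference is None:
        raise ValueError("pass a reference composition"
                         " (e.g. default_reference(cohort))")
    new = _reallocated(reference, from_part, to_part, delta)
    z_ref = ilr_transform(reference, fit.basis)
    z_new = ilr_transform(new, fit.basis)
    c = z_new - z_ref
    beta = fit.composition_beta
    cov = fit.composition_cov
    es = float(c @ beta)
    se = float(np.sqrt(c @ cov @ c))
    if delta == 0:
        es, se = 0.0, 0.0
    if bootstrap:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(beta, cov, size=int(bootstrap)) @ c
        alpha = (1 - level) / 2
        lo, hi = np.quantile(draws, [alpha, 1 - alpha])
    else:
        tcrit = stats.t.ppf(0.5 + level / 2, fit.residual_df)
        lo, hi = es - tcrit * se, es + tcrit * se
    return SubstitutionEstimate(
        from_part=from_part, to_part=to_part, delta=float(delta),
        es=es, ci_low=float(min(lo, es)), ci_high=float(max(hi, es)),
        se=se, reference=reference,
    )


@dataclass(frozen=True)
class SubstitutionGrid:
    """All ordered reallocation pairs for one fit and delta (12 for 4 parts)."""

    estimates: tuple[SubstitutionEstimate, ...]
    delta: float
    outcome: str

    def __post_init__(self) -> None:
        labels = self.estimates[0].reference.labels
        expected = len(labels) * (len(labels) - 1)
        if len(self.estimates) != expected:
            raise ValueError(
                f"{len(self.estimates)} estimates for {len(labels)} parts;"
                f" expected {expected}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped export: blocks of "increase part" rows."""
        rows = [
            {
                "outcome": self.outcome,
                "increase": e.to_part,
                "decrease": e.from_part,
                "delta_min": e.delta,
                "es": e.es,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "significant": e.significant,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)

    def lookup(self, from_part: str, to_part: str) -> SubstitutionEstimate:
        for e in self.estimates:
            if e.from_part == from_part and e.to_part == to_part:
                return e
        raise KeyError((from_part, to_part))


def substitution_grid(
    fit: FitResult,
    delta: float = 30.0,
    reference: Composition | None = None,
    **kwargs,
) -> SubstitutionGrid:
    """Every ordered (from, to) pair at one delta, grouped by gaining part.

    Rows come out in blocks by the behavior that gains time, matching the
    usual "up part / down part" table layout.
    """
    if reference is None:
        raise ValueError("pass a reference composition")
    estimates = []
    for to_part in reference.labels:  # block: the behavior gaining time
        for from_part in reference.labels:
            if from_part == to_part:
                continue
            estimates.append(
                substitute(fit, from_part, to_part, delta, reference, **kwargs)
            )
    return SubstitutionGrid(tuple(estimates), float(delta),
                            fit.spec.outcome)


def default_reference(cohort: pd.DataFrame) -> Composition:
    """Reference day: the sample's compositional mean closed to 1440 min."""
    x = behavior_matrix(cohort)
    if x.shape[0] == 0:
        raise ValueError("empty cohort")
    return compositional_mean(x, total=MINUTES_PER_DAY)
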