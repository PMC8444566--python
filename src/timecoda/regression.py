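"""Linear models of mental-health outcomes on ilr time-use coordinates.

An outcome (or its wave-to-wave change) is regressed by ordinary least
squares on the three ilr coordinates of the 24-h composition plus a
cumulative covariate set: model 1 adjusts for sex and age; model 2 adds
education, marital status and household economy; model 3 adds smoking,
alcohol, energy intake, BMI, cognitive function (MMSE), gait-speed
category and chronic-disease count.  Prospective designs use the change
score as the response and always adjust for the baseline value of the
outcome.

Two summaries come out of each fit:

* a per-behavior coefficient ("gamma"): the coefficient of the *first*
  pivot coordinate under the basis that puts that behavior first, i.e.
  time in one behavior relative to all the others.  Because the pivot
  bases are orthogonal rotations of one another, fitted values, residuals
  and R^2 are identical whichever basis is used; only the labelling of
  the composition coefficients changes.
* a joint "composition model" p-value: a nested F-test (3 numerator df)
  of the model against the same model with all three ilr coordinates
  dropped; invariant to the basis choice.  A likelihood-ratio variant is
  available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import (
    BEHAVIOR_COLUMNS,
    CATEGORICAL_LEVELS,
    MODEL_COVARIATES,
    behavior_matrix,
)
from .composition import (
    DEFAULT_LABELS,
    IlrBasis,
    canonical_basis,
    ilr_transform,
    pivot_bases,
)

__all__ = ["ModelSpec", "GammaEstimate", "FitResult", "build_design",
           "fit_composition_model", "joint_composition_test"]

_ILR_NAMES = ["z1", "z2", "z3"]


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model, under which design and adjustment level.

    ``design="cross_sectional"`` regresses the wave-0 score on the wave-0
    composition.  ``design="prospective"`` regresses the change score
    (``<outcome>_change`` column) on the wave-0 composition and forces
    ``baseline_adjust`` on, adding the wave-0 score as a covariate.
    """

    outcome: str
    design: str = "cross_sectional"
    adjustment: int = 3
    baseline_adjust: bool | None = None

    def __post_init__(self) -> None:
        if self.design not in ("cross_sectional", "prospective"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.adjustment not in MODEL_COVARIATES:
            raise ValueError(
                f"adjustment must be one of {sorted(MODEL_COVARIATES)},"
                f" got {self.adjustment!r}"
            )
        if self.design == "prospective":
            if self.baseline_adjust is False:
                raise ValueError(
                    "prospective models always adjust for the baseline outcome"
                )
            object.__setattr__(self, "baseline_adjust", True)
        elif self.baseline_adjust is None:
            object.__setattr__(self, "baseline_adjust", False)

    @property
    def response_column(self) -> str:
        if self.design == "prospective":
            return f"{self.outcome}_change"
        return self.outcome

    @property
    def covariates(self) -> list[str]:
        cols = list(MODEL_COVARIATES[self.adjustment])
        if self.baseline_adjust:
            cols.append(self.outcome)  # baseline value of the outcome
        return cols


def _expand_covariates(df: pd.DataFrame, covariates: Iterable[str]) -> pd.DataFrame:
    """Reference-level (treatment) coding for categoricals, passthrough else."""
    pieces = []
    for col in covariates:
        if col in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[col]
            cat = pd.Categorical(df[col], categories=levels)
            if pd.isna(cat).any() and not df[col].isna().any():
                bad = sorted(set(df[col].dropna()) - set(levels))
                raise ValueError(f"unknown {col} categories {bad}")
            # unobserved levels would produce all-zero dummies (or, for an
            # empty reference level, dummies summing to the intercept); the
            # reference becomes the first *observed* level
            observed = [lv for lv in levels if (cat == lv).any()]
            cat = cat.remove_categories(
                [lv for lv in levels if lv not in observed])
            dummies = pd.get_dummies(
                pd.Series(cat, index=df.index, name=col),
                prefix=col, drop_first=True, dtype=float,
            )
            pieces.append(dummies)
        else:
            pieces.append(df[col].astype(float))
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


def build_design(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    basis: IlrBasis | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (with intercept) and response for a model spec.

    Rows are listwise-complete for the response and the spec's covariates;
    compositions must be strictly positive (the error names the first
    offending row).  The three ilr coordinates are computed under
    ``basis`` (canonical by default) and enter as columns z1, z2, z3.
    """
    if basis is None:
        basis = canonical_basis()
    needed = [spec.response_column] + spec.covariates
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {missing_cols}")

    mask = cohort[needed].notna().all(axis=1)
    data = cohort.loc[mask]
    if len(data) == 0:
        raise ValueError(
            f"no usable rows for outcome {spec.response_column!r}:"
            " all rows have missing response or covariates"
        )
    x = behavior_matrix(data)
    bad = ~(x > 0).all(axis=1)
    if bad.any():
        row = data.index[np.nonzero(bad)[0][0]]
        raise ValueError(
            f"row {row}: non-positive behavior minutes; compositions must"
            " be strictly positive"
        )
    z = ilr_transform(x, basis, labels=DEFAULT_LABELS)
    X = pd.DataFrame(z, columns=_ILR_NAMES, index=data.index)
    X = pd.concat([X, _expand_covariates(data, spec.covariates)], axis=1)
    X = sm.add_constant(X, prepend=True)
    y = data[spec.response_column].astype(float)
    return X, y


@dataclass(frozen=True)
class GammaEstimate:
    """Per-behavior coefficient: the behavior relative to all others."""

    behavior: str
    estimate: float
    se: float
    p_value: float


@dataclass(frozen=True)
class FitResult:
    """A fitted composition model plus everything downstream needs."""

    spec: ModelSpec
    basis: IlrBasis
    beta: pd.Series
    beta_cov: pd.DataFrame
    gamma: dict[str, GammaEstimate]
    joint_p: float
    n_used: int
    residual_df: int
    r_squared: float
    fitted: pd.Series = field(repr=False)
    sigma2: float = 0.0

    @property
    def composition_beta(self) -> np.ndarray:
        """Coefficients of z1..z3 under :attr:`basis`."""
        return self.beta[_ILR_NAMES].to_numpy()

    @property
    def composition_cov(self) -> np.ndarray:
        """3x3 covariance of the composition coefficients."""
        return self.beta_cov.loc[_ILR_NAMES, _ILR_NAMES].to_numpy()

    def gamma_frame(self) -> pd.DataFrame:
        rows = [
            {"behavior": g.behavior, "gamma": g.estimate, "se": g.se,
             "p": g.p_value}
            for g in self.gamma.values()
        ]
        return pd.DataFrame(rows)

    def coefficient_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.beta_cov.to_numpy()))
        t = self.beta.to_numpy() / se
        p = 2 * stats.t.sf(np.abs(t), self.residual_df)
        return pd.DataFrame(
            {"term": self.beta.index, "estimate": self.beta.to_numpy(),
             "se": se, "t": t, "p": p}
        )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns involved in the collinearity for the error message
        bad = []
        cols = list(X.columns)
        kept: list[int] = []
        for j in range(arr.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
                bad.append(cols[j])
            else:
                kept.append(j)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} of"
            f" {arr.shape[1]}); collinear columns: {bad}"
        )


def _ols(X: pd.DataFrame, y: pd.Series):
    return sm.OLS(y, X.astype(float)).fit()


def joint_composition_test(
    X: pd.DataFrame, y: pd.Series, method: str = "f"
) -> float:
    """p-value for the composition as a whole.

    Compares the full model against the nested model dropping all three
    ilr coordinates: an F-test with 3 numerator df (default) or a
    likelihood-ratio chi-square test (``method="lr"``).  Invariant to the
    pivot basis, since all bases span the same column space.
    """
    full = _ols(X, y)
    reduced = _ols(X.drop(columns=_ILR_NAMES), y)
    if method == "f":
        f, p, _ = full.compare_f_test(reduced)
        return float(p)
    if method == "lr":
        lr, p, _ = full.compare_lr_test(reduced)
        return float(p)
    raise ValueError(f"unknown joint-test method {method!r}")


def fit_composition_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    basis: IlrBasis | None = None,
    joint_method: str = "f",
    gamma_method: str = "refit",
) -> FitResult:
    """OLS fit of an outcome on ilr coordinates plus the spec's covariates.

    ``gamma`` holds one entry per behavior: the first-pivot coefficient
    under the basis placing that behavior first, with its classical
    two-sided t-test p-value.  ``gamma_method="refit"`` refits under each
    pivot basis; ``"rotate"`` rotates the canonical-basis coefficients and
    covariance instead (numerically identical, no refit).
    """
    if basis is None:
        basis = canonical_basis()
    X, y = build_design(cohort, spec, basis)
    _check_rank(X)
    res = _ols(X, y)

    beta = pd.Series(res.params, index=X.columns)
    beta_cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    joint_p = joint_composition_test(X, y, method=joint_method)

    gamma: dict[str, GammaEstimate] = {}
    V_ref = basis.contrast_matrix()
    perm_ref = basis.permutation(DEFAULT_LABELS)
    b_comp = beta[_ILR_NAMES].to_numpy()
    S_comp = beta_cov.loc[_ILR_NAMES, _ILR_NAMES].to_numpy()
    for pb in pivot_bases(DEFAULT_LABELS):
        if gamma_method == "refit":
            Xb, yb = build_design(cohort, spec, pb)
            rb = _ols(Xb, yb)
            est = float(rb.params["z1"])
            se = float(rb.bse["z1"])
        elif gamma_method == "rotate":
            # coordinates relate by Z_b = Z_ref @ R with R = V_ref_p^T V_b_p
            # (both contrast matrices expressed on the same column order),
            # so beta_b = R^T beta_ref and Sigma_b = R^T Sigma_ref R
            V_b = pb.contrast_matrix()
            perm_b = pb.permutation(DEFAULT_LABELS)
            A = np.zeros_like(V_ref)
            A[perm_ref, :] = V_ref  # rows in canonical label order
            B = np.zeros_like(V_b)
            B[perm_b, :] = V_b
            R = A.T @ B
            est = float((R.T @ b_comp)[0])
            se = float(np.sqrt((R.T @ S_comp @ R)[0, 0]))
        else:
            raise ValueError(f"unknown gamma_method {gamma_method!r}")
        p = float(2 * stats.t.sf(abs(est / se), res.df_resid))
        gamma[pb.pivot] = GammaEstimate(pb.pivot, est, se, p)

    return FitResult(
        spec=spec,
        basis=basis,
        beta=beta,
        beta_cov=beta_cov,
        gamma=gamma,
        joint_p=joint_p,
        n_used=int(res.nobs),
        residual_df=int(res.df_resid),
        r_squared=float(res.rsquared),
        fitted=pd.Series(res.fittedvalues, index=X.index),
        sigma2=float(res.scale),
    )
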