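"""End-to-end analysis pipeline.

Orchestrates the stages: generate or load a cohort, apply the wear-time
validity filter, score the instruments, produce descriptive tables,
fit the cross-sectional and prospective composition models under the
three adjustment levels, build isotemporal-substitution grids, and run
the sensitivity analyses (random 10% case removal, MMSE >= 24 subset,
cross-sectional models on the prospective subsample).  Every step is a
plain function over DataFrames; :func:`run_all` wires them together from
a :class:`RunConfig` and writes CSV outputs plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import (
    CATEGORICAL_LEVELS,
    CONTINUOUS_COVARIATES,
    OUTCOMES,
    behavior_matrix,
    read_cohort_csv,
)
from .composition import DEFAULT_LABELS, MINUTES_PER_DAY, compositional_mean
from .regression import FitResult, ModelSpec, fit_composition_model
from .simulate import GeneratorConfig, generate_cohort, generate_wave1
from .substitution import default_reference, substitution_grid

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_descriptives",
    "run_main_analysis",
    "run_sensitivity",
    "run_all",
    "fits_to_frame",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``participant_csv`` (plus optional ``day_records_csv``) points
    at input tables, or ``generator`` describes a synthetic cohort.  The
    significance flags in the outputs use alpha = 0.05, with a borderline
    band up to 0.10 flagged separately.
    """

    participant_csv: str | None = None
    day_records_csv: str | None = None
    generator: GeneratorConfig | None = None
    designs: tuple[str, ...] = ("cross_sectional", "prospective")
    models: tuple[int, ...] = (1, 2, 3)
    outcomes: tuple[str, ...] = tuple(OUTCOMES)
    deltas: tuple[float, ...] = (30.0,)
    seed: int = 0
    output_dir: str = "timecoda_output"
    sensitivity_drop10: bool = True
    sensitivity_mmse: bool = True
    sensitivity_cross_on_prospective: bool = True

    def __post_init__(self) -> None:
        if not self.designs or not self.models:
            raise ValueError("select at least one design and one model")
        bad = [d for d in self.designs
               if d not in ("cross_sectional", "prospective")]
        if bad:
            raise ValueError(f"unknown designs {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _flag(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "borderline"
    return "ns"


def load_or_generate(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Wave-0 cohort plus (for synthetic runs) the prospective subset."""
    if config.participant_csv:
        cohort = read_cohort_csv(config.participant_csv)
        prospective = None
        if {f"{o}_change" for o in config.outcomes} & set(cohort.columns):
            prospective = cohort[
                cohort[[f"{o}_change" for o in config.outcomes
                        if f"{o}_change" in cohort.columns]].notna().any(axis=1)
            ]
        return cohort, prospective
    gen = config.generator or GeneratorConfig(seed=config.seed)
    cohort = generate_cohort(gen)
    prospective, _ = generate_wave1(cohort, gen)
    return cohort, prospective


def _describe_continuous(a: pd.Series, b: pd.Series | None) -> dict:
    row = {"mean_cs": a.mean(), "sd_cs": a.std()}
    if b is not None:
        row.update(mean_prosp=b.mean(), sd_prosp=b.std())
        if a.std() > 0 or b.std() > 0:
            row["p"] = float(stats.ttest_ind(a.dropna(), b.dropna(),
                                             equal_var=False).pvalue)
    return row


def run_descriptives(
    cohort: pd.DataFrame, prospective: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptive table: mean +/- SD, n (%), compositional geometric mean.

    Continuous variables are compared between the cross-sectional and
    prospective samples by Welch t-test, categoricals by chi-square, and
    — when wave-1 scores are present — wave-0 vs wave-1 outcomes in the
    prospective sample by paired t-test.  The compositional mean row
    reports both percent of the day (sums to 100) and min/day (sums to
    1440).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for col in CONTINUOUS_COVARIATES + list(OUTCOMES):
        if col not in cohort.columns:
            continue
        b = prospective[col] if prospective is not None else None
        rows.append({"variable": col, "kind": "continuous",
                     **_describe_continuous(cohort[col], b)})
        if (prospective is not None and f"{col}_w1" in prospective.columns
                and col in OUTCOMES):
            paired = prospective[[col, f"{col}_w1"]].dropna()
            res = stats.ttest_rel(paired[f"{col}_w1"], paired[col])
            rows.append({
                "variable": f"{col}_wave1", "kind": "continuous",
                "mean_prosp": paired[f"{col}_w1"].mean(),
                "sd_prosp": paired[f"{col}_w1"].std(),
                "p": float(res.pvalue) if len(paired) > 1 else np.nan,
            })
    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in cohort.columns:
            continue
        counts = cohort[col].value_counts()
        p_chi = np.nan
        if prospective is not None:
            counts_p = prospective[col].value_counts()
            table = np.array([
                [counts.get(lv, 0) for lv in levels],
                [counts_p.get(lv, 0) for lv in levels],
            ])
            keep = table.sum(axis=0) > 0
            if keep.sum() > 1:
                p_chi = float(stats.chi2_contingency(table[:, keep])[1])
        for lv in levels:
            n = int(counts.get(lv, 0))
            row = {"variable": f"{col}:{lv}", "kind": "categorical",
                   "n_cs": n, "pct_cs": 100.0 * n / len(cohort), "p": p_chi}
            if prospective is not None:
                np_ = int(prospective[col].value_counts().get(lv, 0))
                row.update(n_prosp=np_,
                           pct_prosp=100.0 * np_ / len(prospective))
            rows.append(row)
    for sample, df in (("cross_sectional", cohort), ("prospective", prospective)):
        if df is None:
            continue
        cm_pct = compositional_mean(behavior_matrix(df), total=100.0)
        cm_min = cm_pct.reclose(MINUTES_PER_DAY)
        for lab, pct, mins in zip(DEFAULT_LABELS, cm_pct.parts, cm_min.parts):
            rows.append({"variable": f"composition:{lab}", "kind": sample,
                         "pct_cs": pct, "mean_cs": mins})
    return pd.DataFrame(rows)


def fits_to_frame(fits: dict[tuple[str, str, int], FitResult]) -> pd.DataFrame:
    """Flatten fits into the published-table shape: one row per
    outcome x design x model, columns for the joint composition p and the
    four per-behavior gammas with p-values and significance flags."""
    rows = []
    for (design, outcome, model), fit in fits.items():
        row = {"design": design, "outcome": outcome, "model": model,
               "n": fit.n_used, "composition_p": fit.joint_p,
               "composition_flag": _flag(fit.joint_p)}
        for behavior, g in fit.gamma.items():
            row[f"gamma_{behavior}"] = g.estimate
            row[f"p_{behavior}"] = g.p_value
            row[f"flag_{behavior}"] = _flag(g.p_value)
        rows.append(row)
    return pd.DataFrame(rows)


def run_main_analysis(
    config: RunConfig,
    cohort: pd.DataFrame,
    prospective: pd.DataFrame | None = None,
) -> dict[str, object]:
    """Fit every outcome x design x model and build substitution grids.

    Returns ``fits`` (dict keyed by (design, outcome, model)),
    ``model_table`` (gamma/joint-p table), and ``substitution_table``
    (all deltas, fully adjusted model per design).
    """
    fits: dict[tuple[str, str, int], FitResult] = {}
    grids = []
    for design in config.designs:
        data = cohort if design == "cross_sectional" else prospective
        if data is None:
            raise ValueError(f"no data for the {design} design")
        reference = default_reference(data)
        for outcome in config.outcomes:
            for model in config.models:
                spec = ModelSpec(outcome=outcome, design=design,
                                 adjustment=model)
                fit = fit_composition_model(data, spec)
                fits[(design, outcome, model)] = fit
            top = fits[(design, outcome, max(config.models))]
            for delta in config.deltas:
                g = substitution_grid(top, delta=delta, reference=reference)
                gf = g.to_frame()
                gf.insert(0, "design", design)
                grids.append(gf)
    return {
        "fits": fits,
        "model_table": fits_to_frame(fits),
        "substitution_table": pd.concat(grids, ignore_index=True),
    }


def _gamma_shift_frame(base: FitResult, alt: FitResult) -> pd.DataFrame:
    rows = []
    for behavior, g0 in base.gamma.items():
        g1 = alt.gamma[behavior]
        rows.append({
            "behavior": behavior,
            "gamma_main": g0.estimate,
            "gamma_sensitivity": g1.estimate,
            "shift": g1.estimate - g0.estimate,
            "sign_change": np.sign(g0.estimate) != np.sign(g1.estimate),
            "significance_change": (g0.p_value < 0.05) != (g1.p_value < 0.05),
        })
    return pd.DataFrame(rows)


def run_sensitivity(
    config: RunConfig,
    cohort: pd.DataFrame,
    prospective: pd.DataFrame | None,
    fits: dict[tuple[str, str, int], FitResult],
    n_drop10: int = 5,
) -> pd.DataFrame:
    """Sensitivity reruns of the fully adjusted models.

    (a) ``drop10``: refit after removing a seeded random 10% of rows —
    repeated ``n_drop10`` times with distinct sub-seeds so the report is a
    shift *distribution*, not a single verdict; a "significant shift" is
    flagged descriptively as any gamma changing sign or crossing
    alpha = 0.05.  (b) ``mmse``: refit on the MMSE >= 24 subset.
    (c) ``cross_on_prospective``: cross-sectional models refit on the
    prospective subsample.
    """
    model = max(config.models)
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    for design in config.designs:
        data = cohort if design == "cross_sectional" else prospective
        if data is None:
            continue
        for outcome in config.outcomes:
            base = fits[(design, outcome, model)]
            spec = ModelSpec(outcome=outcome, design=design, adjustment=model)
            if config.sensitivity_drop10:
                for rep in range(n_drop10):
                    keep = rng.random(len(data)) >= 0.10
                    alt = fit_composition_model(data.loc[keep], spec)
                    sf = _gamma_shift_frame(base, alt)
                    sf.insert(0, "analysis", f"drop10_rep{rep + 1}")
                    sf.insert(1, "design", design)
                    sf.insert(2, "outcome", outcome)
                    rows.append(sf)
            if config.sensitivity_mmse and "mmse" in data.columns:
                subset = data[data["mmse"] >= 24]
                alt = fit_composition_model(subset, spec)
                sf = _gamma_shift_frame(base, alt)
                sf.insert(0, "analysis", "mmse_ge_24")
                sf.insert(1, "design", design)
                sf.insert(2, "outcome", outcome)
                rows.append(sf)
    if (config.sensitivity_cross_on_prospective and prospective is not None
            and "cross_sectional" in config.designs):
        for outcome in config.outcomes:
            base = fits[("cross_sectional", outcome, model)]
            spec = ModelSpec(outcome=outcome, design="cross_sectional",
                             adjustment=model)
            alt = fit_composition_model(prospective, spec)
            sf = _gamma_shift_frame(base, alt)
            sf.insert(0, "analysis", "cross_sectional_on_prospective")
            sf.insert(1, "design", "cross_sectional")
            sf.insert(2, "outcome", outcome)
            rows.append(sf)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def run_all(config: RunConfig) -> dict[str, object]:
    """The full pipeline; writes CSVs and a JSON manifest to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, prospective = load_or_generate(config)
    logger.info("cohort: %d participants; prospective subset: %s",
                len(cohort), "none" if prospective is None else len(prospective))

    descriptives = run_descriptives(cohort, prospective)
    main = run_main_analysis(config, cohort, prospective)
    sensitivity = run_sensitivity(config, cohort, prospective, main["fits"])

    descriptives.to_csv(out / "descriptives.csv", index=False)
    main["model_table"].to_csv(out / "model_table.csv", index=False)
    main["substitution_table"].to_csv(out / "substitution_table.csv",
                                      index=False)
    if len(sensitivity):
        sensitivity.to_csv(out / "sensitivity.csv", index=False)
    coef_rows = []
    for (design, outcome, model), fit in main["fits"].items():
        cf = fit.coefficient_frame()
        cf.insert(0, "design", design)
        cf.insert(1, "outcome", outcome)
        cf.insert(2, "model", model)
        coef_rows.append(cf)
    pd.concat(coef_rows, ignore_index=True).to_csv(
        out / "coefficients.csv", index=False)

    manifest = {
        "package": "timecoda",
        "version": __version__,
        "seed": config.seed,
        "n_cross_sectional": int(len(cohort)),
        "n_prospective": None if prospective is None else int(len(prospective)),
        "designs": list(config.designs),
        "models": [int(m) for m in config.models],
        "outcomes": list(config.outcomes),
        "deltas": [float(d) for d in config.deltas],
        "outputs": ["descriptives.csv", "model_table.csv",
                    "substitution_table.csv", "coefficients.csv",
                    "sensitivity.csv", "manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"descriptives": descriptives, "sensitivity": sensitivity,
            "manifest": manifest, **main}
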