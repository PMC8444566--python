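import numpy as np
import pandas as pd
import pytest

from timecoda import (
    GeneratorConfig,
    WearModel,
    apply_validity_filter,
    canonical_basis,
    compositional_mean,
    generate_cohort,
    generate_day_records,
    generate_wave1,
    ilr_transform,
)
from timecoda.cohort import behavior_matrix

from conftest import TABLE1_MIN


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n=100, seed=5)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n=100, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n=50, seed=1))
        b = generate_cohort(GeneratorConfig(n=50, seed=2))
        assert not np.allclose(a["sleep"], b["sleep"])

    def test_zero_covariance_is_degenerate_at_the_mean(self):
        cfg = GeneratorConfig(n=20, seed=3, ilr_cov=np.zeros((3, 3)))
        cohort = generate_cohort(cfg)
        x = behavior_matrix(cohort)
        assert np.allclose(x, cfg.mean_composition.parts, rtol=1e-9)

    def test_sample_center_near_generator_mean(self):
        cohort = generate_cohort(GeneratorConfig(n=10_000, seed=11))
        m = compositional_mean(behavior_matrix(cohort))
        # ilr-scale SEs are sqrt(diag/n) ~ 0.002-0.003; compare there
        z_err = ilr_transform(m) - ilr_transform(
            compositional_mean(np.array([TABLE1_MIN])))
        assert np.all(np.abs(z_err) < 4 * np.sqrt(np.array([0.04, 0.04, 0.09])
                                                  / 10_000))

    def test_strict_positivity_and_closure(self, synthetic_cohort):
        x = behavior_matrix(synthetic_cohort)
        assert (x > 0).all()
        assert np.allclose(x.sum(axis=1), 1440.0, rtol=1e-9)

    def test_outcomes_within_instrument_ranges(self, synthetic_cohort):
        assert synthetic_cohort["depression"].between(0, 10).all()
        assert synthetic_cohort["loneliness"].between(3, 9).all()
        assert synthetic_cohort["happiness"].between(0, 10).all()
        assert synthetic_cohort["mcs"].between(0, 100).all()
        assert "truncation_rates" in synthetic_cohort.attrs

    def test_covariate_marginals_respected(self):
        cohort = generate_cohort(GeneratorConfig(n=20_000, seed=13))
        women = (cohort["sex"] == "women").mean()
        assert women == pytest.approx(0.5307, abs=0.015)
        assert cohort["age"].mean() == pytest.approx(71.7, abs=0.2)
        assert cohort["mmse"].le(30).all()

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 0, 0], [0, -0.5, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(n=10, seed=0, ilr_cov=bad)

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(n=10, seed=0,
                            covariate_marginals={"sex": {"men": 0.7,
                                                         "women": 0.7}})

    def test_ilr_covariance_converges(self):
        """Sample ilr covariance approaches the generating covariance as n
        grows (shrinking Frobenius distance)."""
        target = np.diag([0.04, 0.04, 0.09])
        dists = []
        for n in (500, 5000, 50_000):
            cohort = generate_cohort(GeneratorConfig(n=n, seed=17))
            z = ilr_transform(behavior_matrix(cohort), canonical_basis())
            S = np.cov(z, rowvar=False)
            dists.append(np.linalg.norm(S - target, "fro"))
        assert dists[2] < dists[0]
        assert dists[2] < 0.01


class TestWave1:
    def test_no_attrition_retains_everyone(self):
        cfg = GeneratorConfig(n=200, seed=19, attrition_rate=0.0)
        cohort = generate_cohort(cfg)
        w1, retained = generate_wave1(cohort, cfg)
        assert retained.all() and len(w1) == 200

    def test_attrition_rate_matches_binomial_expectation(self):
        """At the default loss rate, a 2489-person cohort retains about
        1679 participants on average (2489 * 0.675 ~ 1680)."""
        retained_counts = []
        for seed in range(30):
            cfg = GeneratorConfig(n=2489, seed=seed)
            cohort = generate_cohort(cfg.with_(n=2489))
            _, retained = generate_wave1(cohort, cfg)
            retained_counts.append(int(retained.sum()))
        mean_kept = np.mean(retained_counts)
        se = np.std(retained_counts, ddof=1) / np.sqrt(len(retained_counts))
        assert abs(mean_kept - 1679) < 4 * se + 5

    def test_zero_drift_zero_noise_gives_zero_change(self):
        cfg = GeneratorConfig(
            n=150, seed=23, attrition_rate=0.0,
            wave1_drift={k: (0.0, 0.0) for k in
                         ("depression", "loneliness", "happiness", "mcs")},
        )
        cohort = generate_cohort(cfg)
        w1, _ = generate_wave1(cohort, cfg)
        for out in ("depression", "loneliness", "happiness", "mcs"):
            assert np.allclose(w1[f"{out}_change"], 0.0)

    def test_default_drift_directions(self):
        """Depression and loneliness worsen on average; happiness and
        global mental health decline."""
        cfg = GeneratorConfig(n=4000, seed=29)
        cohort = generate_cohort(cfg)
        w1, _ = generate_wave1(cohort, cfg)
        assert w1["loneliness_change"].mean() > 0
        assert w1["happiness_change"].mean() < 0
        assert w1["mcs_change"].mean() < 0

    def test_followup_years_near_configured_mean(self):
        cfg = GeneratorConfig(n=3000, seed=31, attrition_rate=0.0)
        cohort = generate_cohort(cfg)
        w1, _ = generate_wave1(cohort, cfg)
        assert w1["followup_years"].mean() == pytest.approx(2.31, abs=0.05)

    def test_change_effect_flows_from_baseline_composition(self):
        cfg = GeneratorConfig(
            n=2000, seed=37, attrition_rate=0.0,
            wave1_drift={k: (0.0, 0.0) for k in
                         ("depression", "loneliness", "happiness", "mcs")},
            change_ilr_beta={"mcs": (0.0, 0.0, 2.0)},
        )
        cohort = generate_cohort(cfg)
        w1, _ = generate_wave1(cohort, cfg)
        z3 = ilr_transform(behavior_matrix(w1), canonical_basis())[:, 2]
        mask = w1["mcs_change"].notna()
        corr = np.corrcoef(z3[mask], w1.loc[mask, "mcs_change"])[0, 1]
        assert corr > 0.5


class TestDayRecords:
    def test_seven_days_two_weekend(self, synthetic_cohort):
        cfg = GeneratorConfig(n=len(synthetic_cohort), seed=42)
        records = generate_day_records(synthetic_cohort.head(20), cfg)
        per = records.groupby("participant_id")
        assert (per.size() == 7).all()
        assert (per["weekend"].sum() == 2).all()

    def test_minutes_bounded_by_wear_time(self, synthetic_cohort):
        cfg = GeneratorConfig(n=20, seed=43)
        records = generate_day_records(synthetic_cohort.head(20), cfg)
        total = records[["sleep", "sb", "lpa", "mvpa"]].sum(axis=1)
        assert (total <= records["wear_hours"] * 60 + 1e-6).all()
        assert (records["wear_hours"] <= 24).all()

    def test_degenerate_full_wear_all_days_valid(self, synthetic_cohort):
        cfg = GeneratorConfig(n=10, seed=44,
                              wear_model=WearModel(mean_hours=24.0,
                                                   sd_hours=0.0))
        records = generate_day_records(synthetic_cohort.head(10), cfg)
        kept, comps = apply_validity_filter(records)
        assert len(kept) == 10
        assert np.allclose(comps[["sleep", "sb", "lpa", "mvpa"]].sum(axis=1),
                           1440.0)


def _days(pid, wear_by_day):
    """Constructed day records: {day: wear_hours}; behavior minutes split
    40/45/10/5 percent of worn time."""
    rows = []
    for day, wear in wear_by_day.items():
        w = wear * 60
        rows.append({"participant_id": pid, "day": day, "weekend": day >= 6,
                     "wear_hours": wear, "sleep": 0.40 * w, "sb": 0.45 * w,
                     "lpa": 0.10 * w, "mvpa": 0.05 * w})
    return rows


class TestValidityFilter:
    def test_full_week_retained(self):
        records = pd.DataFrame(_days(1, {d: 20.0 for d in range(1, 8)}))
        kept, comps = apply_validity_filter(records)
        assert kept == [1]
        assert comps[["sleep", "sb", "lpa", "mvpa"]].iloc[0].sum() == \
            pytest.approx(1440.0)

    def test_four_valid_days_without_weekend_excluded(self):
        records = pd.DataFrame(_days(1, {1: 20, 2: 20, 3: 20, 4: 20,
                                         6: 10, 7: 10}))
        kept, _ = apply_validity_filter(records)
        assert kept == []

    def test_three_valid_days_with_weekend_excluded(self):
        records = pd.DataFrame(_days(1, {1: 20, 2: 20, 6: 20,
                                         3: 10, 4: 10, 5: 10, 7: 10}))
        kept, _ = apply_validity_filter(records)
        assert kept == []

    def test_four_valid_days_with_weekend_retained(self):
        records = pd.DataFrame(_days(1, {1: 20, 2: 20, 3: 20, 6: 20,
                                         4: 10, 5: 10, 7: 10}))
        kept, comps = apply_validity_filter(records)
        assert kept == [1]

    def test_sixteen_hour_boundary_is_valid(self):
        records = pd.DataFrame(_days(1, {1: 16.0, 2: 16.0, 3: 16.0,
                                         6: 16.0}))
        kept, _ = apply_validity_filter(records)
        assert kept == [1]

    def test_mean_over_valid_days_only(self):
        # one invalid day with a wildly different mix must not leak in
        rows = _days(1, {1: 20, 2: 20, 3: 20, 6: 20})
        rows += [{"participant_id": 1, "day": 4, "weekend": False,
                  "wear_hours": 5.0, "sleep": 300.0, "sb": 0.1, "lpa": 0.1,
                  "mvpa": 0.1}]
        kept, comps = apply_validity_filter(pd.DataFrame(rows))
        row = comps.iloc[0]
        assert row["sleep"] == pytest.approx(0.40 * 1440, rel=1e-9)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            apply_validity_filter(pd.DataFrame(columns=["participant_id",
                                                        "wear_hours"]))
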