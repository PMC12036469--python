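"""Cohort filtering, Cox model variants, propensity weights and KM/log-rank."""

import numpy as np
import pandas as pd
import pytest

from sleepstrat import (
    CohortSpec,
    build_outcome_cohort,
    estimate_propensity_weights,
    fit_cox_model,
    generate_cohort,
    km_disease_free_survival,
    logrank_two_groups,
    standardized_mean_differences,
)
from sleepstrat.outcomes import trim_weights


def _cohort_with_groups(spec_kwargs, label_map=None):
    df = generate_cohort(CohortSpec(**spec_kwargs))
    labels = label_map or {i: f"RG{i + 1}"
                           for i in range(len(spec_kwargs["group_proportions"]))}
    df["risk_group"] = df["group"].map(labels)
    return df


class TestBuildOutcomeCohort:
    def _toy(self):
        # 10 subjects: 3 short-history only, 2 prevalent only, 1 both -> 6 kept
        # (one of the "short history" subjects is also prevalent)
        rows = []
        for i, (hist, prev) in enumerate([
            (10, 0), (12, 0), (8, 0), (6, 0), (9, 0), (20, 0),  # 6 eligible
            (2, 0), (4, 0), (4, 1),                             # short history
            (15, 1),                                            # prevalent
        ]):
            rows.append({"id": i, "history_years": hist, "stroke_event": 0,
                         "stroke_time": 5.0, "prevalent_stroke": prev})
        return pd.DataFrame(rows)

    def test_history_and_prevalence_filters(self):
        kept = build_outcome_cohort(self._toy(), "stroke")
        assert len(kept) == 6
        assert (kept["history_years"] >= 5).all()
        assert (kept["prevalent_stroke"] == 0).all()

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            build_outcome_cohort(self._toy(), "gout")

    def test_death_outcome_uses_plain_columns(self):
        df = generate_cohort(CohortSpec(n_subjects=100, seed=0))
        kept = build_outcome_cohort(df, "death")
        assert (kept["history_years"] >= 5).all()


class TestCoxModels:
    def test_two_group_hr_recovery_model1(self):
        df = _cohort_with_groups(dict(
            n_subjects=5000, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, np.log(2.0)), baseline_hazard=0.03,
            censoring_rate=0.01, followup_horizon=15.0, seed=3,
        ))
        fit = fit_cox_model(df, 1)
        assert 1.8 <= fit.hr("RG2") <= 2.2
        lo, hi = fit.ci("RG2")
        assert lo <= 2.0 <= hi

    def test_null_covariate_ci_covers_one(self):
        """A zero-effect binary covariate: CI covers HR=1 in ~95% of seeds."""
        from lifelines import CoxPHFitter

        covered = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = generate_cohort(CohortSpec(
                n_subjects=800, group_proportions=(1.0,),
                group_log_hazard_ratios=(0.0,), baseline_hazard=0.05,
                censoring_rate=0.02, followup_horizon=12.0, seed=seed,
            ))
            cph = CoxPHFitter().fit(
                df[["time_years", "event", "sex"]], "time_years", "event"
            )
            s = cph.summary.loc["sex"]
            covered += s["coef lower 95%"] <= 0.0 <= s["coef upper 95%"]
        assert covered >= 0.88 * n_seeds  # binomial slack around 0.95

    def test_model5_excludes_pap(self):
        df = _cohort_with_groups(dict(
            n_subjects=2000, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.5), baseline_hazard=0.05,
            censoring_rate=0.01, seed=5,
        ))
        fit = fit_cox_model(df, 5)
        assert fit.n_samples == int((df["pap_prescribed"] == 0).sum())

    def test_model6_excludes_under_55(self):
        df = _cohort_with_groups(dict(
            n_subjects=2000, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.5), baseline_hazard=0.05,
            censoring_rate=0.01, seed=6,
        ))
        fit = fit_cox_model(df, 6)
        assert fit.n_samples == int((df["age"] >= 55).sum())

    def test_ahi_severity_exposure(self):
        df = _cohort_with_groups(dict(
            n_subjects=3000, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.0), baseline_hazard=0.05,
            censoring_rate=0.01, seed=7,
        ))
        fit = fit_cox_model(df, 1, exposure="ahi_severity")
        assert fit.reference == "normal"
        # null effect: all severity bands' CIs should mostly cover 1
        assert set(fit.summary.index) <= {"mild", "moderate", "severe"}

    def test_invalid_model_id(self):
        df = _cohort_with_groups(dict(
            n_subjects=100, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.0), seed=1,
        ))
        with pytest.raises(ValueError, match="model_id"):
            fit_cox_model(df, 7)

    def test_zero_event_group_flagged_unbounded(self):
        df = _cohort_with_groups(dict(
            n_subjects=400, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.0), baseline_hazard=0.05,
            censoring_rate=0.01, seed=2,
        ))
        df.loc[df["risk_group"] == "RG2", "event"] = 0
        fit = fit_cox_model(df, 1)
        assert fit.zero_event_levels == ["RG2"]
        lo, hi = fit.ci("RG2")
        assert lo == 0.0 and np.isinf(hi)


class TestPropensityWeights:
    def test_stabilized_ratio_recovered_from_known_assignment(self):
        """With P(G=1|x=1)=0.8, P(G=1|x=0)=0.2 and marginal 0.5, the
        stabilized weight is marginal/conditional: 0.625 or 2.5 per cell."""
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.integers(0, 2, n)
        g = rng.random(n) < np.where(x == 1, 0.8, 0.2)
        df = pd.DataFrame({"x": x.astype(float),
                           "risk_group": np.where(g, "RG2", "RG1")})
        wv = estimate_propensity_weights(df, covariates=["x"])
        w = wv.weights.to_numpy()
        assert abs(w[(g == 1) & (x == 1)].mean() - 0.625) < 0.08
        assert abs(w[(g == 1) & (x == 0)].mean() - 2.5) < 0.3

    def test_clipping_bounds_match_percentiles(self):
        raw = pd.Series([0.1, 1, 1, 1, 1, 1, 1, 1, 1, 10.0])
        wv = trim_weights(raw, mode="clip")
        assert wv.weights.max() == pytest.approx(np.percentile(raw, 95))
        assert wv.weights.min() == pytest.approx(np.percentile(raw, 5))
        assert len(wv.weights) == len(raw)

    def test_exclude_mode_drops_out_of_bounds(self):
        raw = pd.Series([0.1, 1, 1, 1, 1, 1, 1, 1, 1, 10.0])
        wv = trim_weights(raw, mode="exclude")
        assert len(wv.weights) == 8

    def test_randomized_groups_balanced_after_weighting(self):
        df = _cohort_with_groups(dict(
            n_subjects=4000, group_proportions=(0.4, 0.35, 0.25),
            group_log_hazard_ratios=(0.0, 0.0, 0.0), seed=11,
        ))
        wv = estimate_propensity_weights(df)
        covs = ["age", "bmi", "sex", "hypertension", "history_years"]
        smd = standardized_mean_differences(df, covs, weights=wv)
        assert np.abs(smd.to_numpy()).max() < 0.1

    def test_weight_means_near_one_per_group(self):
        df = _cohort_with_groups(dict(
            n_subjects=4000, group_proportions=(0.5, 0.5),
            group_log_hazard_ratios=(0.0, 0.0), seed=12,
        ))
        wv = estimate_propensity_weights(df)
        for g, sub in df.groupby("risk_group"):
            assert abs(wv.weights.loc[sub.index].mean() - 1.0) < 0.05

    def test_single_group_rejected(self):
        df = _cohort_with_groups(
            dict(n_subjects=100, group_proportions=(1.0,),
                 group_log_hazard_ratios=(0.0,), seed=1),
        )
        with pytest.raises(ValueError, match="2 groups"):
            estimate_propensity_weights(df)


class TestKaplanMeierLogrank:
    def test_hand_product_limit(self):
        """times {1,2,3}, events {1,1,0}: S(2) = (1 - 1/3)(1 - 1/2) = 1/3."""
        df = pd.DataFrame({
            "time_years": [1.0, 2.0, 3.0], "event": [1, 1, 0],
            "risk_group": ["RG1"] * 3,
        })
        table = km_disease_free_survival(df, horizons=(2.0,))
        assert table.loc["RG1", "S(2y)"] == pytest.approx(1 / 3)

    def test_no_events_survival_one_p_one(self):
        df = pd.DataFrame({
            "time_years": [3.0] * 40, "event": [0] * 40,
            "risk_group": ["RG1"] * 20 + ["RG2"] * 20,
        })
        table = km_disease_free_survival(df)
        assert (table[["S(2y)", "S(4y)", "S(6y)"]].to_numpy() == 1.0).all()
        assert table.loc["RG2", "logrank_p"] == 1.0

    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(5.0, 500)
        df = pd.DataFrame({"time_years": times, "event": 1,
                           "risk_group": "RG1"})
        table = km_disease_free_survival(df, horizons=(2.0, 4.0))
        for h in (2.0, 4.0):
            assert table.loc["RG1", f"S({h:g}y)"] == pytest.approx(
                (times > h).mean(), abs=1e-9
            )

    def test_logrank_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(5, 200), rng.exponential(3, 150)
        ea, eb = rng.integers(0, 2, 200), rng.integers(0, 2, 150)
        stat, p = logrank_two_groups(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, ea, eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_logrank_p_uniform(self):
        """Identically distributed groups: p-values are uniform on [0, 1]."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(200):
            df = generate_cohort(CohortSpec(
                n_subjects=300, group_proportions=(0.5, 0.5),
                group_log_hazard_ratios=(0.0, 0.0), baseline_hazard=0.05,
                censoring_rate=0.02, followup_horizon=10.0, seed=seed + 1000,
            ))
            a, b = df[df.group == 0], df[df.group == 1]
            pvals.append(logrank_two_groups(
                a.time_years, a.event, b.time_years, b.event)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_km_non_increasing(self):
        df = generate_cohort(CohortSpec(
            n_subjects=500, group_proportions=(1.0,),
            group_log_hazard_ratios=(0.0,), baseline_hazard=0.1,
            censoring_rate=0.05, seed=8,
        ))
        df["risk_group"] = "RG1"
        table = km_disease_free_survival(df, horizons=(1.0, 3.0, 6.0, 10.0))
        vals = table.loc["RG1", ["S(1y)", "S(3y)", "S(6y)", "S(10y)"]].to_numpy()
        assert (np.diff(vals.astype(float)) <= 1e-12).all()

    def test_weighted_km_upweights_subjects(self):
        df = pd.DataFrame({
            "time_years": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 0],
            "risk_group": ["RG1"] * 4,
        })
        from sleepstrat import WeightVector

        wv = WeightVector(
            weights=pd.Series([5.0, 1.0, 1.0, 1.0], index=df.index),
            trim_lower=1.0, trim_upper=5.0, mode="clip",
        )
        weighted = km_disease_free_survival(df, horizons=(1.5,), weights=wv)
        plain = km_disease_free_survival(df, horizons=(1.5,))
        # the early death carries 5x weight -> lower weighted survival
        assert weighted.loc["RG1", "S(1.5y)"] < plain.loc["RG1", "S(1.5y)"]
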