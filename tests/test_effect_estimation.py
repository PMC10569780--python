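"""Screening, propensity stratification, CMH, and Cox estimation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.contingency_tables import StratifiedTable

from causalbn.effect_estimation import (
    SurvivalRecord,
    association_screen,
    cmh_test,
    cox_log_partial_likelihood,
    cox_score_test,
    dichotomize,
    fit_cox,
    fit_propensity,
    hr_comparison_table,
    significant_covariates,
)
from causalbn.synthetic_cohort import (
    ScenarioConfig,
    apply_exclusions,
    make_ground_truth,
    sample_cohort,
)


@pytest.fixture(scope="module")
def confounded_cohort():
    gt = make_ground_truth(ScenarioConfig("confounded", 5000, 0))
    cohort, _ = apply_exclusions(sample_cohort(gt, 5000, 0))
    return gt, cohort


class TestAssociationScreen:
    def test_generator_treatment_ancestors_flagged(self, confounded_cohort):
        # exactly the causal ancestors of treatment (direct parents plus the
        # upstream drivers of physical status and nodal stage) are significant
        gt, cohort = confounded_cohort
        screen = association_screen(
            cohort, "treatment",
            ["sex", "age3", "comorbidities", "ASA", "pT", "pN", "subsite", "grade"],
        )
        ancestors = {
            v for v in ("sex", "age3", "comorbidities", "ASA", "pT", "pN", "subsite", "grade")
            if v in gt.graph.ancestors("treatment")
        }
        assert ancestors == {"age3", "ASA", "pN", "comorbidities", "grade"}
        assert set(significant_covariates(screen)) == ancestors

    def test_identical_column_extreme(self, confounded_cohort):
        _, cohort = confounded_cohort
        df = cohort.assign(copy=cohort["treatment"].astype(str))
        screen = association_screen(df, "treatment", ["copy"])
        assert screen["copy"].p_value < 1e-10

    def test_type_one_error_rate(self):
        # coin-flip treatment independent of all covariates: each variable
        # should be flagged in about 5% of replicates
        rng = np.random.default_rng(3)
        flags = 0
        total = 0
        for _ in range(400):
            df = pd.DataFrame(
                {
                    "a": rng.integers(0, 3, 400).astype(str),
                    "b": rng.integers(0, 2, 400).astype(str),
                    "treatment": rng.integers(0, 2, 400).astype(str),
                }
            )
            screen = association_screen(df, "treatment", ["a", "b"])
            flags += len(significant_covariates(screen))
            total += 2
        assert 0.03 < flags / total < 0.07

    def test_constant_treatment_rejected(self):
        df = pd.DataFrame({"a": ["x", "y"], "treatment": ["t", "t"]})
        with pytest.raises(ValueError):
            association_screen(df, "treatment")


class TestPropensity:
    def test_logistic_closed_form(self):
        # P(T=1|X=1)=0.8, P(T=1|X=0)=0.2: intercept ln(0.25), slope ln(16)
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.integers(0, 2, n)
        t = (rng.random(n) < np.where(x == 1, 0.8, 0.2)).astype(int)
        df = pd.DataFrame({"x": x.astype(str), "treatment": t.astype(str)})
        res = fit_propensity(df, ["x"], "treatment", treated_level="1")
        se_b0 = se_b1 = 0.08  # conservative binomial SEs at this n
        assert res.coefficients["intercept"] == pytest.approx(np.log(0.25), abs=3 * se_b0)
        assert res.coefficients["x[1]"] == pytest.approx(np.log(16), abs=3 * se_b1)

    def test_independent_covariate_slope_ci_covers_zero(self):
        rng = np.random.default_rng(1)
        n = 4000
        df = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n).astype(str),
                "treatment": rng.integers(0, 2, n).astype(str),
            }
        )
        res = fit_propensity(df, ["x"], "treatment")
        slope = res.coefficients["x[1]"]
        assert abs(slope) < 3 * 2 / np.sqrt(n)  # |slope| within 3 crude SEs of 0

    def test_quintile_occupancy(self):
        rng = np.random.default_rng(2)
        n = 1000
        df = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n).astype(str),
                "y": rng.integers(0, 3, n).astype(str),
                "treatment": rng.integers(0, 2, n).astype(str),
            }
        )
        res = fit_propensity(df, ["x", "y"], "treatment")
        counts = np.bincount(res.strata)[1:]
        assert counts.tolist() == [200] * 5
        assert len(res.bin_edges) == 4

    def test_empty_covariates_refused(self):
        df = pd.DataFrame({"treatment": ["a", "b"] * 10})
        with pytest.warns(UserWarning):
            res = fit_propensity(df, [], "treatment")
        assert res.strata is None
        assert np.allclose(res.scores, 0.5)


class TestCMH:
    def test_single_stratum_hand_value(self):
        # table [[30,20],[20,30]]: E[a]=25, Var=50^4/(100^2*99), stat ~ 3.960
        t = np.array([1] * 50 + [0] * 50)
        f = np.array([1] * 30 + [0] * 20 + [1] * 20 + [0] * 30)
        res = cmh_test(t, f, np.zeros(100))
        var = 50 * 50 * 50 * 50 / (100**2 * 99)
        assert res.statistic == pytest.approx(25 / var, abs=1e-3)
        assert res.statistic == pytest.approx(3.960, abs=1e-3)
        assert res.df == 1

    def test_two_identical_strata_linearity(self):
        t1 = np.array([1] * 25 + [0] * 25)
        f1 = np.array([1] * 15 + [0] * 10 + [1] * 10 + [0] * 15)
        t = np.concatenate([t1, t1])
        f = np.concatenate([f1, f1])
        strata = np.repeat([0, 1], 50)
        res = cmh_test(t, f, strata)
        # per-stratum sums double, matching the formula applied to the sums
        num = 2 * (15 - 25 * 25 / 50)
        var = 2 * (25 * 25 * 25 * 25 / (50**2 * 49))
        assert res.statistic == pytest.approx(num**2 / var, abs=1e-9)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        t = rng.integers(0, 2, 600)
        f = (rng.random(600) < 0.3 + 0.2 * t).astype(int)
        s = rng.integers(0, 5, 600)
        ours = cmh_test(t, f, s)
        tables = [
            pd.crosstab(t[s == k], f[s == k]).to_numpy() for k in range(5)
        ]
        ref = StratifiedTable(tables).test_null_odds(correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-8)

    def test_simpson_construction(self):
        # within strata independent; marginally associated through the stratum
        rng = np.random.default_rng(11)
        n = 4000
        s = rng.integers(0, 2, n)
        p_t = np.where(s == 1, 0.8, 0.2)
        p_f = np.where(s == 1, 0.7, 0.3)
        t = (rng.random(n) < p_t).astype(int)
        f = (rng.random(n) < p_f).astype(int)
        marginal = cmh_test(t, f, np.zeros(n))
        stratified = cmh_test(t, f, s)
        assert marginal.p_value < 0.001
        assert stratified.p_value > 0.05

    def test_zero_margin_stratum_skipped(self):
        t = np.array([1, 1, 0, 0, 1, 1])
        f = np.array([1, 0, 1, 0, 1, 1])
        s = np.array([0, 0, 0, 0, 1, 1])  # stratum 1 has no controls
        res = cmh_test(t, f, s)
        assert res.skipped_strata == [1]

    def test_multilevel_factor_requires_dichotomize(self):
        t = np.array([0, 1] * 10)
        f = np.array([0, 1, 2, 1] * 5)
        with pytest.raises(ValueError):
            cmh_test(t, f, np.zeros(20))
        with pytest.warns(UserWarning):
            fb = dichotomize(pd.Series(f), "2")
        assert set(np.unique(fb)) <= {0, 1}


def exponential_two_group(n_per_arm=2000, hr=0.5, censor_frac=0.2, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n_per_arm)
    lam = 0.5 * np.exp(np.log(hr) * g)
    t = rng.exponential(1 / lam)
    c = rng.uniform(0, t.max() * 2, len(t))
    cens = rng.random(len(t)) < censor_frac
    time = np.where(cens, np.minimum(t, c), t)
    event = ~cens | (t <= c)
    return pd.DataFrame(
        {"time": time + 1e-9, "event": event, "treatment": g.astype(str)}
    )


class TestCox:
    def test_exponential_hazard_ratio_recovered(self):
        df = exponential_two_group()
        fit = fit_cox(df, ["treatment"])
        beta = fit.coefficients["treatment[1]"]
        se = fit.standard_errors["treatment[1]"]
        assert beta == pytest.approx(np.log(0.5), abs=3 * se)
        assert fit.hr["treatment[1]"] == pytest.approx(np.exp(beta))
        lo, hi = fit.ci95["treatment[1]"]
        assert (lo, hi) == pytest.approx(
            (np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se))
        )

    def test_permuted_treatment_ci_covers_one(self):
        rng = np.random.default_rng(5)
        df = exponential_two_group(seed=2)
        df["treatment"] = rng.permutation(df["treatment"].to_numpy())
        fit = fit_cox(df, ["treatment"])
        lo, hi = fit.ci95["treatment[1]"]
        assert lo < 1.0 < hi

    def test_log_partial_likelihood_at_zero_untied(self):
        # six subjects, untied event times, all events: -ln(6!)
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [True] * 6,
                "x": ["0", "1", "0", "1", "0", "1"],
            }
        )
        ll = cox_log_partial_likelihood(df, ["x"], beta=0.0)
        assert ll == pytest.approx(-np.log(720), abs=1e-9)

    def test_score_test_equals_logrank_untied(self):
        df = exponential_two_group(n_per_arm=60, censor_frac=0.0, seed=4)
        stat = cox_score_test(df, ["treatment"])
        ref = logrank_test(
            df.loc[df.treatment == "0", "time"],
            df.loc[df.treatment == "1", "time"],
            event_observed_A=df.loc[df.treatment == "0", "event"],
            event_observed_B=df.loc[df.treatment == "1", "event"],
        )
        assert stat == pytest.approx(ref.test_statistic, abs=1e-6)

    def test_time_scaling_invariance(self):
        df = exponential_two_group(n_per_arm=300, seed=6)
        f1 = fit_cox(df, ["treatment"])
        df2 = df.assign(time=df["time"] * 365.25)
        f2 = fit_cox(df2, ["treatment"])
        assert f1.coefficients["treatment[1]"] == pytest.approx(
            f2.coefficients["treatment[1]"], abs=1e-6
        )

    def test_matches_lifelines(self):
        df = exponential_two_group(n_per_arm=400, seed=8)
        fit = fit_cox(df, ["treatment"])
        cph = CoxPHFitter()
        dd = df.assign(treatment=(df["treatment"] == "1").astype(float))
        cph.fit(dd, duration_col="time", event_col="event")
        assert fit.coefficients["treatment[1]"] == pytest.approx(
            float(cph.params_["treatment"]), abs=1e-4
        )

    @pytest.mark.parametrize("ties", ["Efron", "Breslow"])
    def test_matches_statsmodels_phreg_with_heavy_ties(self, ties, confounded_cohort):
        # day-granular registry-style times: many tied event days
        _, cohort = confounded_cohort
        from statsmodels.duration.hazard_regression import PHReg

        from causalbn.effect_estimation import _dummy_design

        fit = fit_cox(cohort, ["treatment", "pN", "ASA"], tie_method=ties)
        X, names = _dummy_design(cohort, ["treatment", "pN", "ASA"])
        ref = PHReg(
            cohort["time"].to_numpy(float),
            X,
            status=cohort["event"].to_numpy(int),
            ties=ties.lower(),
        ).fit()
        assert np.allclose(list(fit.coefficients.values()), ref.params, atol=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(
            ref.model.loglike(ref.params), abs=1e-6
        )

    def test_efron_breslow_agree_without_ties(self):
        df = exponential_two_group(n_per_arm=100, censor_frac=0.0, seed=9)
        fe = fit_cox(df, ["treatment"], tie_method="Efron")
        fb = fit_cox(df, ["treatment"], tie_method="Breslow")
        assert fe.coefficients["treatment[1]"] == pytest.approx(
            fb.coefficients["treatment[1]"], abs=1e-6
        )

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [False, False], "x": ["0", "1"]}
        )
        with pytest.raises(ValueError):
            fit_cox(df, ["x"])

    def test_survival_record_validation(self):
        with pytest.raises(ValueError):
            SurvivalRecord(time=0.0, event=True, covariates={}, treatment="yes")


class TestHrTable:
    def test_single_fit_single_row(self):
        df = exponential_two_group(n_per_arm=200, seed=10)
        fit = fit_cox(df, ["treatment"])
        table = hr_comparison_table({"crude": fit}, "treatment[1]")
        assert len(table) == 1
        assert bool(table["ci_overlaps_all"].iloc[0])

    def test_identical_fits_identical_rows(self):
        df = exponential_two_group(n_per_arm=200, seed=10)
        fit = fit_cox(df, ["treatment"])
        table = hr_comparison_table({"a": fit, "b": fit}, "treatment[1]")
        assert table.iloc[0]["hr"] == table.iloc[1]["hr"]
        assert table["ci_overlaps_all"].all()

    def test_crude_vs_adjusted_in_designed_direction(self, confounded_cohort):
        # confounding by indication pushes the crude HR below the truth
        gt, cohort = confounded_cohort
        crude = fit_cox(cohort, ["treatment"])
        adjusted = fit_cox(cohort, ["treatment", "pN", "ASA"])
        table = hr_comparison_table(
            {"crude": crude, "adjusted": adjusted}, "treatment[yes]"
        )
        hr_crude = table.set_index("model").loc["crude", "hr"]
        hr_adj = table.set_index("model").loc["adjusted", "hr"]
        assert hr_crude < hr_adj
        assert abs(np.log(hr_adj) - gt.true_log_hr) < abs(np.log(hr_crude) - gt.true_log_hr)

    def test_missing_treatment_term_raises(self):
        df = exponential_two_group(n_per_arm=100, seed=3)
        fit = fit_cox(df, ["treatment"])
        with pytest.raises(KeyError):
            hr_comparison_table({"crude": fit}, "nope")
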