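"""Tests for prevalence tables, bivariate tests, crude ORs and GEE models."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from alcodoc import analysis, classify
from alcodoc.analysis import (crude_odds_ratio, bivariate_compare,
                              fit_documentation_model, fit_risk_model,
                              prevalence_from_counts, prevalence_table,
                              round_half_up)
from alcodoc.errors import DataError, ModelError

TABLE1_COUNTS = {"NONE": 57_712, "LIGHT": 117_779, "MODERATE": 82_178,
                 "HEAVY": 8_088, "PAST": 4_519}


class TestRounding:
    @pytest.mark.parametrize("x, nd, expected", [
        (43.577, 1, 43.6),
        (43.55, 1, 43.6),     # half goes up
        (2.345, 2, 2.35),
        (40.649, 1, 40.6),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected


class TestPrevalence:
    def test_reference_counts(self):
        t = prevalence_from_counts(TABLE1_COUNTS, unclassified=13_992,
                                   cohort_total=700_620)
        assert t.percents == {"NONE": 21.4, "LIGHT": 43.6, "MODERATE": 30.4,
                              "HEAVY": 3.0, "PAST": 1.7}
        assert t.classified_total == 270_276
        assert t.documented_total == 284_268
        assert t.heightened_risk_pct == 4.7
        assert t.documentation_rate_pct == 40.6

    def test_single_light_patient(self):
        t = prevalence_from_counts({"NONE": 0, "LIGHT": 1, "MODERATE": 0,
                                    "HEAVY": 0, "PAST": 0}, 0)
        assert t.percents["LIGHT"] == 100.0
        assert all(t.percents[c] == 0.0 for c in t.percents if c != "LIGHT")

    def test_percents_sum_near_100(self, small_cohort):
        t = prevalence_table(small_cohort)
        assert abs(sum(t.percents.values()) - 100.0) <= 0.3

    def test_permutation_invariance(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=3)
        assert prevalence_table(small_cohort).percents == \
            prevalence_table(shuffled).percents

    def test_empty_raises(self, small_cohort):
        undocumented = small_cohort[~small_cohort["documented"]]
        with pytest.raises(DataError):
            prevalence_table(undocumented)

    def test_accounting_matches_cohort(self, small_cohort):
        t = prevalence_table(small_cohort)
        assert t.documented_total == int(small_cohort["documented"].sum())
        assert t.classified_total + t.unclassified_count == t.documented_total


class TestBivariate:
    def test_null_two_by_two(self):
        df = pd.DataFrame({
            "documented": [True] * 40 + [False] * 40,
            "male": ([True] * 20 + [False] * 20) * 2,
        })
        res = bivariate_compare(df, "male")
        assert res.kind == "chi2"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_male_proportions(self):
        """Documented-male 43.7% vs undocumented-male 42.4%."""
        doc = np.zeros(284_268, bool)
        doc[:124_243] = True
        undoc = np.zeros(416_352, bool)
        undoc[:176_457] = True
        df = pd.DataFrame({
            "documented": np.r_[np.ones(284_268, bool),
                                np.zeros(416_352, bool)],
            "male": np.r_[doc, undoc]})
        res = bivariate_compare(df, "male")
        s = res.summary.set_index("group")
        assert round_half_up(100 * s.loc["documented", "estimate"], 1) == 43.7
        assert round_half_up(100 * s.loc["undocumented", "estimate"], 1) == 42.4
        assert res.p_value < 1e-4

    def test_numeric_uses_t(self, small_cohort):
        res = bivariate_compare(small_cohort, "age_years")
        assert res.kind == "t"
        assert 0 <= res.p_value <= 1

    def test_zero_cell_switches_to_exact(self):
        df = pd.DataFrame({"documented": [True] * 5 + [False] * 5,
                           "male": [True] * 5 + [False] * 5})
        res = bivariate_compare(df, "male")
        assert res.kind == "fisher"

    def test_type_one_error_near_alpha(self):
        """On null data the chi-square test rejects ~5% of the time."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame({"documented": rng.random(400) < 0.4,
                               "male": rng.random(400) < 0.5})
            if bivariate_compare(df, "male").p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)


class TestCrudeOddsRatio:
    @pytest.mark.parametrize("cells, expected", [
        ((1, 1, 1, 1), 1.0),
        ((10, 5, 2, 4), 4.0),
    ])
    def test_examples(self, cells, expected):
        assert crude_odds_ratio(*cells).value == pytest.approx(expected)

    def test_reference_sex_by_documentation(self):
        """Cross-product from the descriptive counts is ~1.056 (the printed
        unadjusted model value 1.07 comes from a clustered fit)."""
        res = crude_odds_ratio(124_243, 160_025, 176_457, 239_895)
        assert res.value == pytest.approx(1.0556, abs=5e-4)
        assert res.ci_low < res.value < res.ci_high

    def test_zero_cell_correction(self):
        res = crude_odds_ratio(5, 0, 3, 4)
        assert res.corrected
        assert np.isfinite(res.value)

    def test_negative_raises(self):
        with pytest.raises(DataError):
            crude_odds_ratio(-1, 2, 3, 4)

    def test_brute_force_oracle(self):
        """Matches exhaustive cross-product arithmetic with Woolf CI."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 21, 4)
            res = crude_odds_ratio(a, b, c, d)
            assert res.value == pytest.approx((a * d) / (b * c))
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert res.ci_low == pytest.approx(
                res.value * math.exp(-analysis.Z95 * se))
            assert res.ci_high == pytest.approx(
                res.value * math.exp(analysis.Z95 * se))


class TestModels:
    def test_documentation_model_shape(self, small_cohort):
        m = fit_documentation_model(small_cohort,
                                    compute_unadjusted=False)
        assert set(m.terms.index) == set(analysis.DOC_MODEL_TERMS)
        assert m.n_used == len(small_cohort)
        assert m.n_clusters == small_cohort["provider_id"].nunique()
        t = m.terms
        assert ((t["adj_ci_low"] <= t["adj_or"])
                & (t["adj_or"] <= t["adj_ci_high"])).all()
        assert (t["adj_or"] > 0).all()

    def test_risk_model_excludes_unknown(self, small_cohort):
        m = fit_risk_model(small_cohort, compute_unadjusted=False)
        n_classified = int((small_cohort["category"].notna()
                            & small_cohort["category"].ne("UNKNOWN")).sum())
        assert m.n_used == n_classified
        assert "age_years" in m.terms.index
        assert "provider_male" not in m.terms.index

    def test_singleton_clusters_equal_plain_logit(self):
        """With every patient their own provider and independence working
        correlation, GEE coefficients equal an ordinary logistic fit."""
        rng = np.random.default_rng(8)
        n = 400
        x = rng.random(n) < 0.5
        p = 1 / (1 + np.exp(-(-0.3 + 0.4 * x)))
        df = pd.DataFrame({
            "documented": rng.random(n) < p,
            "male": x,
            "age_over_mean": rng.random(n) < 0.5,
            "urban": rng.random(n) < 0.8,
            "high_visits": rng.random(n) < 0.5,
            "depression": rng.random(n) < 0.2,
            "diabetes": rng.random(n) < 0.1,
            "hypertension": rng.random(n) < 0.25,
            "osteoarthritis": rng.random(n) < 0.15,
            "provider_male": rng.random(n) < 0.5,
            "provider_age_over_mean": rng.random(n) < 0.5,
            "provider_id": [f"d{i}" for i in range(n)],
        })
        m = fit_documentation_model(df, working_correlation="independence",
                                    compute_unadjusted=False)
        design = df.assign(rural=~df["urban"])
        X = sm.add_constant(
            design[list(analysis.DOC_MODEL_TERMS)].astype(float))
        glm = sm.GLM(df["documented"].astype(float), X,
                     family=sm.families.Binomial()).fit()
        for term in analysis.DOC_MODEL_TERMS:
            assert math.log(m.terms.loc[term, "adj_or"]) == pytest.approx(
                glm.params[term], abs=1e-6)

    def test_single_cluster_refused(self, small_cohort):
        one = small_cohort.copy()
        one["provider_id"] = "d0"
        with pytest.raises(ModelError):
            fit_documentation_model(one, compute_unadjusted=False)

    def test_constant_outcome_refused(self, small_cohort):
        c = small_cohort.copy()
        c["heightened_risk"] = c["heightened_risk"].where(
            c["heightened_risk"].isna(), False)
        with pytest.raises(ModelError):
            fit_risk_model(c, compute_unadjusted=False)

    def test_exchangeable_near_independence_when_no_icc(self, small_cohort):
        """Zero true intra-cluster correlation: both working correlations
        give nearly identical coefficients."""
        m1 = fit_documentation_model(small_cohort,
                                     working_correlation="exchangeable",
                                     compute_unadjusted=False)
        m2 = fit_documentation_model(small_cohort,
                                     working_correlation="independence",
                                     compute_unadjusted=False)
        diff = np.log(m1.terms["adj_or"]) - np.log(m2.terms["adj_or"])
        assert np.abs(diff).max() < 1e-2


class TestReport:
    def test_structure(self, small_cohort, tmp_path):
        prev = prevalence_table(small_cohort)
        bivs = [bivariate_compare(small_cohort, v) for v in ("male",
                                                             "age_years")]
        models = [fit_documentation_model(small_cohort,
                                          compute_unadjusted=False)]
        paths = analysis.report(prev, bivs, models, tmp_path)
        res = pd.read_csv(paths["results.csv"])
        assert set(res["section"]) == {"prevalence", "bivariate",
                                       "model:documented"}
        assert (res["section"] == "bivariate").sum() == 2
        assert (res["section"] == "model:documented").sum() == len(
            analysis.DOC_MODEL_TERMS)
        assert "multiple-testing" in (tmp_path / "report.txt").read_text()

    def test_prevalence_only(self, small_cohort, tmp_path):
        prev = prevalence_table(small_cohort)
        paths = analysis.report(prev, [], [], tmp_path)
        res = pd.read_csv(paths["results.csv"])
        assert set(res["section"]) == {"prevalence"}
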