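"""Case--control, multinomial, LRT, contrast and survey models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from complement_pqtl.association import (
    case_control_linear,
    case_control_logistic,
    group_linear_model,
    lrt,
    multinomial_subgroups,
    null_multinomial,
    pairwise_contrasts,
    survey_association,
)
from complement_pqtl.datatypes import Cohort, DataError

from conftest import make_cohort, make_panel


class TestCaseControlLinear:
    def test_noise_free_shift_reported_as_nf_minus_case(self):
        """Cases exactly 0.215 higher -> group coefficient -0.215."""
        coh = make_cohort(30, 40)
        y = np.where(coh.is_case, 1.215, 1.0)
        panel = make_panel({"C3": y}, index=coh.ids)
        fit = case_control_linear(panel, coh, "C3")
        assert fit.coef("group") == pytest.approx(-0.215, abs=1e-12)
        assert fit.pvalue("group") < 1e-20

    def test_identical_groups_zero_effect(self):
        coh = make_cohort(10, 10)
        panel = make_panel({"C3": np.tile([1.0, 2.0], 10)}, index=coh.ids)
        fit = case_control_linear(panel, coh, "C3")
        assert fit.coef("group") == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_toy(self):
        rng = np.random.default_rng(0)
        coh = make_cohort(6, 6, rng)
        y = rng.normal(size=12)
        panel = make_panel({"Bb": y}, index=coh.ids)
        fit = case_control_linear(panel, coh, "Bb", covariates=("bmi",))
        X = np.column_stack(
            [np.ones(12), (~coh.is_case).astype(float), coh.subjects["bmi"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef("group") == pytest.approx(beta[1], abs=1e-10)
        assert fit.coef("bmi") == pytest.approx(beta[2], abs=1e-10)

    def test_collinear_covariates_rejected(self):
        coh = make_cohort(10, 10)
        coh.subjects["age"] = coh.subjects["bmi"]  # force exact collinearity
        panel = make_panel({"C3": np.arange(20.0)}, index=coh.ids)
        with pytest.raises(DataError, match="collinear"):
            case_control_linear(panel, coh, "C3", covariates=("age", "bmi"))


class TestCaseControlLogistic:
    def test_null_predictor_small_coefficient(self):
        rng = np.random.default_rng(1)
        coh = make_cohort(50, 121, rng)
        panel = make_panel({"C3": rng.normal(size=171)}, index=coh.ids)
        fit = case_control_logistic(panel, coh, "C3")
        se = float(fit.terms.loc["protein", "se"])
        assert abs(fit.coef("protein")) < 4 * se

    def test_complete_separation_flagged(self):
        coh = make_cohort(10, 10)
        y = np.where(coh.is_case, 5.0, -5.0)
        panel = make_panel({"C3": y}, index=coh.ids)
        fit = case_control_logistic(panel, coh, "C3")
        assert not fit.converged

    def test_matches_direct_likelihood_optimum(self):
        """Newton solution agrees with an independent optimizer of the
        hand-written log-likelihood on a 20-row toy."""
        rng = np.random.default_rng(2)
        coh = make_cohort(10, 10, rng)
        x = rng.normal(size=20)
        panel = make_panel({"C3": x}, index=coh.ids)
        fit = case_control_logistic(panel, coh, "C3")
        yv = coh.is_case.to_numpy(dtype=float)

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(yv * eta - np.log1p(np.exp(eta)))

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.coef("protein") == pytest.approx(opt.x[1], abs=1e-3)


class TestMultinomial:
    @staticmethod
    def _labels(coh, rng):
        labs = np.where(
            coh.is_case,
            rng.choice(["CFShet", "CFSrem"], size=len(coh.ids)),
            rng.choice(["NFhet", "NFrem"], size=len(coh.ids)),
        )
        return pd.Series(labs, index=coh.ids)

    def test_two_level_reduces_to_binary_logistic(self):
        rng = np.random.default_rng(3)
        coh = make_cohort(40, 40, rng)
        x = rng.normal(size=80) + 0.8 * coh.is_case.to_numpy()
        panel = make_panel({"C3": x}, index=coh.ids)
        labels = pd.Series(
            np.where(coh.is_case, "CFShet", "NFhet"), index=coh.ids
        )
        mn = multinomial_subgroups(panel, labels, "C3", coh, reference="NFhet")
        bin_fit = case_control_logistic(panel, coh, "C3")
        mn_beta = float(mn.level_terms["CFShet"].loc["protein", "beta"])
        assert mn_beta == pytest.approx(bin_fit.coef("protein"), abs=1e-6)

    def test_reference_block_identically_zero(self, study_sim):
        rng = np.random.default_rng(4)
        coh = study_sim.cohort
        labels = self._labels(coh, rng)
        mn = multinomial_subgroups(study_sim.panel, labels, "C3", coh)
        ref = mn.level_terms["NFhet"]
        assert (ref["beta"] == 0).all()

    def test_relabeling_permutes_blocks(self):
        rng = np.random.default_rng(5)
        coh = make_cohort(60, 60, rng)
        x = rng.normal(size=120)
        panel = make_panel({"C3": x}, index=coh.ids)
        labels = self._labels(coh, rng)
        mn1 = multinomial_subgroups(panel, labels, "C3", coh)
        swapped = labels.replace({"CFShet": "CFSrem", "CFSrem": "CFShet"})
        mn2 = multinomial_subgroups(panel, swapped, "C3", coh)
        b1 = mn1.level_terms["CFShet"]["beta"].to_numpy()
        b2 = mn2.level_terms["CFSrem"]["beta"].to_numpy()
        assert np.allclose(b1, b2, atol=1e-6)


class TestLrt:
    def test_full_vs_itself_is_zero(self):
        rng = np.random.default_rng(6)
        coh = make_cohort(20, 20, rng)
        panel = make_panel({"C3": rng.normal(size=40)}, index=coh.ids)
        fit = case_control_logistic(panel, coh, "C3")
        res = lrt(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        coh = make_cohort(20, 20, rng)
        panel = make_panel({"C3": rng.normal(size=40)}, index=coh.ids)
        full = case_control_logistic(panel, coh, "C3")
        sub = Cohort(coh.subjects.iloc[:30])
        panel30 = make_panel(
            {"C3": panel.values["C3"].iloc[:30].to_numpy()}, index=sub.ids
        )
        reduced = case_control_logistic(panel30, sub, "C3")
        with pytest.raises(DataError, match="rows"):
            lrt(full, reduced)

    def test_planted_subgroup_effect_detected(self):
        """A strong protein difference across 4 subgroups yields a tiny
        LRT p-value."""
        rng = np.random.default_rng(8)
        coh = make_cohort(60, 60, rng)
        labels = TestMultinomial._labels(coh, rng)
        shift = labels.map(
            {"CFShet": 1.0, "CFSrem": 0.0, "NFhet": -1.0, "NFrem": 0.0}
        )
        panel = make_panel(
            {"C3": rng.normal(size=120) + shift.to_numpy()}, index=coh.ids
        )
        full = multinomial_subgroups(panel, labels, "C3", coh)
        reduced = null_multinomial(labels, coh, rows=full.rows)
        res = lrt(full, reduced)
        assert res.df == 3
        assert res.p_value < 1e-4


class TestContrasts:
    def test_no_covariates_equals_raw_mean_difference(self):
        rng = np.random.default_rng(9)
        coh = make_cohort(30, 30, rng)
        labels = pd.Series(
            np.repeat(["A", "B", "C"], 20), index=coh.ids
        )
        y = rng.normal(size=60) + labels.map({"A": 0.0, "B": 1.0, "C": 2.0}).to_numpy()
        panel = make_panel({"C3": y}, index=coh.ids)
        fit = group_linear_model(panel, labels, "C3", coh, reference="A")
        table = pairwise_contrasts(fit)
        ab = table[(table["group_a"] == "A") & (table["group_b"] == "B")].iloc[0]
        raw_diff = y[:20].mean() - y[20:40].mean()
        assert ab["estimate"] == pytest.approx(raw_diff, abs=1e-10)

    def test_contrast_equals_prediction_difference_oracle(self):
        """Three-group toy with a covariate: each contrast equals the
        difference of model predictions at the covariate mean."""
        rng = np.random.default_rng(10)
        coh = make_cohort(30, 30, rng)
        labels = pd.Series(np.repeat(["A", "B", "C"], 20), index=coh.ids)
        y = (
            rng.normal(size=60)
            + labels.map({"A": 0, "B": 1, "C": 2}).to_numpy()
            + 0.05 * coh.subjects["bmi"].to_numpy()
        )
        panel = make_panel({"C3": y}, index=coh.ids)
        fit = group_linear_model(
            panel, labels, "C3", coh, covariates=("bmi",), reference="A"
        )
        table = pairwise_contrasts(fit)
        beta = fit.terms["beta"]
        bmi_mean = coh.subjects["bmi"].mean()

        def predict(level):
            val = beta["const"] + beta["bmi"] * bmi_mean
            if f"group[{level}]" in beta.index:
                val += beta[f"group[{level}]"]
            return val

        for row in table.itertuples():
            assert row.estimate == pytest.approx(
                predict(row.group_a) - predict(row.group_b), abs=1e-10
            )

    def test_single_group_empty_table(self):
        rng = np.random.default_rng(11)
        coh = make_cohort(10, 10, rng)
        labels = pd.Series(["A"] * 20, index=coh.ids)
        panel = make_panel({"C3": rng.normal(size=20)}, index=coh.ids)
        fit = group_linear_model(panel, labels, "C3", coh)
        assert len(pairwise_contrasts(fit)) == 0


class TestSurveyAssociation:
    def test_noise_free_slope_and_r2(self):
        rng = np.random.default_rng(12)
        coh = make_cohort(20, 20, rng)
        score = rng.uniform(0, 50, 40)
        surveys = pd.DataFrame({"cdc_si": score}, index=coh.ids)
        panel = make_panel({"CRP": 0.1 * score + 1.0}, index=coh.ids)
        fit = survey_association(panel, surveys, coh, "CRP", "cdc_si")
        assert fit.coef("score") == pytest.approx(0.1, abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_negative_direction_preserved(self):
        rng = np.random.default_rng(13)
        coh = make_cohort(20, 20, rng)
        score = rng.uniform(20, 80, 40)
        surveys = pd.DataFrame({"sf36_GH": score}, index=coh.ids)
        panel = make_panel(
            {"C3": -0.02 * score + rng.normal(scale=0.01, size=40)}, index=coh.ids
        )
        fit = survey_association(panel, surveys, coh, "C3", "sf36_GH")
        assert fit.coef("score") < 0

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(14)
        coh = make_cohort(10, 10, rng)
        surveys = pd.DataFrame({"cdc_si": np.ones(20)}, index=coh.ids)
        panel = make_panel({"C3": rng.normal(size=20)}, index=coh.ids)
        with pytest.raises(DataError, match="constant"):
            survey_association(panel, surveys, coh, "C3", "cdc_si")


class TestNestingMonotonicity:
    def test_r2_never_decreases_with_added_predictor(self, study_sim):
        import statsmodels.api as sm

        panel = study_sim.panel
        coh = study_sim.cohort
        y = panel.values["C3"].to_numpy()
        covs = coh.covariate_frame()
        X1 = sm.add_constant(covs[["bmi"]])
        X2 = sm.add_constant(covs[["bmi", "age"]])
        r2_1 = sm.OLS(y, X1).fit().rsquared
        r2_2 = sm.OLS(y, X2).fit().rsquared
        assert r2_2 >= r2_1 - 1e-12
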