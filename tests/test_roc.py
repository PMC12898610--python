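"""Stratified ROC, AUC identities and two-marker subgroup assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from complement_pqtl.datatypes import Cohort, DataError
from complement_pqtl.roc import (
    RocFilters,
    assign_subgroups,
    hanley_mcneil_se,
    mann_whitney_auc,
    screen_strata,
    stratum_roc,
)

from conftest import make_cohort, make_panel
from test_pqtl import make_genotypes


def brute_force_auc(scores, labels):
    """Pairwise concordance count with ties worth 1/2 (independent oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, controls = scores[labels], scores[~labels]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_toy_probabilities_three_quarters(self):
        """Cases {0.9, 0.4} vs controls {0.3, 0.5}: 3 of 4 pairs concordant."""
        scores = [0.9, 0.4, 0.3, 0.5]
        labels = [1, 1, 0, 0]
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.75)

    def test_equals_brute_force_concordance_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            if labels.all():
                labels[-1] = False
            # ties made likely by rounding
            scores = np.round(rng.normal(size=n), 1)
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=0
            )

    def test_perfect_and_constant_predictors(self):
        assert mann_whitney_auc([1, 2, 3, -1, -2, -3], [1, 1, 1, 0, 0, 0]) == 1.0
        assert mann_whitney_auc([1.0] * 6, [1, 1, 1, 0, 0, 0]) == 0.5


class TestStratumRoc:
    def test_constant_covariate_dropped_equals_raw_auc(self):
        """All-female stratum: sex is dropped and with no covariates left
        the AUC equals the AUC of the raw analyte values exactly."""
        rng = np.random.default_rng(1)
        n = 40
        coh = make_cohort(20, 20, rng)
        coh.subjects["sex"] = "female"
        vals = rng.normal(size=n) + coh.is_case.to_numpy()
        panel = make_panel({"C3": vals}, index=coh.ids)
        gm = make_genotypes({"rs1": np.ones(n)}, coh.ids)
        rec = stratum_roc(gm, panel, coh, [("rs1", 1)], "C3", covariates=("sex",))
        assert rec.covariates == ""
        assert rec.auc == pytest.approx(
            mann_whitney_auc(vals, coh.is_case.to_numpy()), abs=0
        )

    def test_stratum_filtering(self):
        rng = np.random.default_rng(2)
        coh = make_cohort(10, 10, rng)
        dose = np.tile([0.0, 1.0], 10)  # both groups present in each stratum
        gm = make_genotypes({"rs1": dose}, coh.ids)
        panel = make_panel({"C3": rng.normal(size=20)}, index=coh.ids)
        rec = stratum_roc(gm, panel, coh, [("rs1", 0)], "C3")
        assert rec.n_case + rec.n_control == 10
        assert rec.stratum == "rs1=0"

    def test_single_class_stratum_rejected(self):
        coh = make_cohort(5, 5)
        dose = np.array([0] * 5 + [1] * 5, dtype=float)
        gm = make_genotypes({"rs1": dose}, coh.ids)
        panel = make_panel({"C3": np.arange(10.0)}, index=coh.ids)
        with pytest.raises(DataError, match="single outcome class"):
            stratum_roc(gm, panel, coh, [("rs1", 0)], "C3")

    def test_hanley_mcneil_reference_value(self):
        """Spot check of the SE formula by direct arithmetic."""
        auc, n1, n0 = 0.8, 20, 40
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        expected = np.sqrt(
            (auc * (1 - auc) + 19 * (q1 - auc**2) + 39 * (q2 - auc**2)) / 800
        )
        assert hanley_mcneil_se(auc, n1, n0) == pytest.approx(expected, abs=1e-15)


class TestFilters:
    @pytest.mark.parametrize(
        "auc,p,n,expected",
        [
            (0.80, 0.01, 20, True),
            (0.80, 0.01, 10, False),  # too small
            (0.70, 0.001, 30, False),  # AUC too low
            (0.80, 0.10, 30, False),  # not significant
            (0.75, 0.01, 30, False),  # strict inequality at the boundary
        ],
    )
    def test_filter_rule(self, auc, p, n, expected):
        assert RocFilters().passes(auc, p, n) is expected

    def test_tightening_filters_is_monotone(self, study_sim):
        cmap = {"C3": ["bmi"]}
        loose = RocFilters(auc_min=0.6, p_max=0.2, n_min=5)
        tight = RocFilters(auc_min=0.8, p_max=0.01, n_min=30)
        snps = ["rs800292", "rs1061170"]
        t_loose = screen_strata(
            study_sim.genotypes, study_sim.panel, study_sim.cohort,
            snps, cmap, loose, analytes=("C3",),
        )
        t_tight = screen_strata(
            study_sim.genotypes, study_sim.panel, study_sim.cohort,
            snps, cmap, tight, analytes=("C3",),
        )
        passed_loose = set(
            t_loose.loc[t_loose["passes_filters"], ["stratum", "analyte"]]
            .apply(tuple, axis=1)
        )
        passed_tight = set(
            t_tight.loc[t_tight["passes_filters"], ["stratum", "analyte"]]
            .apply(tuple, axis=1)
        )
        assert passed_tight <= passed_loose


class TestSubgroupAssignment:
    def test_exhaustive_nine_genotype_combinations(self):
        """All (dosage_a, dosage_b) pairs in {0,1,2}^2 for one case and one
        control each: het iff either dosage is exactly 1; homozygous-risk
        (2) without a het call is rem."""
        combos = list(itertools.product([0, 1, 2], repeat=2))
        n = len(combos) * 2
        coh = make_cohort(len(combos), len(combos))
        da = np.array([c[0] for c in combos] * 2, dtype=float)
        db = np.array([c[1] for c in combos] * 2, dtype=float)
        gm = make_genotypes({"rsA": da, "rsB": db}, coh.ids)
        labels = assign_subgroups(gm, coh, "rsA", "rsB")
        for i, (a, b) in enumerate(combos):
            case_label = labels.iloc[i]
            control_label = labels.iloc[i + len(combos)]
            expect_het = (a == 1) or (b == 1)
            assert case_label == ("CFShet" if expect_het else "CFSrem")
            assert control_label == ("NFhet" if expect_het else "NFrem")
        # the double-risk edge case: (0, 2) and (2, 0) are rem, not het
        assert labels.iloc[combos.index((0, 2))] == "CFSrem"
        assert labels.iloc[combos.index((2, 0)) + len(combos)] == "NFrem"
        # partition: every subject labeled exactly once
        assert labels.notna().all()
        assert labels.value_counts().sum() == n

    def test_case_control_prefix_respected(self, study_sim):
        labels = assign_subgroups(
            study_sim.genotypes, study_sim.cohort, "rs9332739", "rs800292"
        )
        is_case = study_sim.cohort.is_case
        assert labels[is_case].dropna().str.startswith("CFS").all()
        assert labels[~is_case].dropna().str.startswith("NF").all()
        assert labels.value_counts().sum() == len(study_sim.cohort.ids)

    def test_missing_genotype_handling(self):
        coh = make_cohort(2, 2)
        da = np.array([np.nan, 1, 0, np.nan])
        db = np.array([0, np.nan, 0, 2])
        gm = make_genotypes({"rsA": da, "rsB": db}, coh.ids)
        excl = assign_subgroups(gm, coh, "rsA", "rsB", missing="exclude")
        assert pd.isna(excl.iloc[0])  # unknown and not observed-het
        assert excl.iloc[1] == "CFShet"  # observed het call is decisive
        rem = assign_subgroups(gm, coh, "rsA", "rsB", missing="rem")
        assert rem.iloc[0] == "CFSrem"
        assert rem.iloc[3] == "NFrem"

    def test_absent_marker_rejected(self, study_sim):
        with pytest.raises(DataError, match="absent"):
            assign_subgroups(
                study_sim.genotypes, study_sim.cohort, "rsNOPE", "rs800292"
            )
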