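"""Top-hit selection, enrichment scores, overlap, cis/trans, directionality."""

import numpy as np
import pandas as pd
import pytest

from complement_pqtl.datatypes import FUNCTIONAL_GROUPS, DataError
from complement_pqtl.enrichment import (
    classify_cis_trans,
    directionality,
    directionality_points,
    enrichment_scores,
    external_overlap,
    overlap_disease_snps,
    top_hits,
)


def make_scan(rows):
    return pd.DataFrame(rows, columns=["rsid", "analyte", "beta", "se", "p_fvr"])


def make_annotation(rsids, groups=None, genes=None):
    n = len(rsids)
    return pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "pos": np.arange(n) + 1000,
            "gene": genes or [f"G{i}" for i in range(n)],
            "functional_group": groups or ["complement"] * n,
            "consequence": ["intronic"] * n,
            "minor_allele": ["A"] * n,
            "major_allele": ["G"] * n,
        },
        index=pd.Index(rsids, name="rsid"),
    )


class TestTopHits:
    def test_strict_threshold(self):
        scan = make_scan(
            [("rs1", "C3", 0.1, 0.05, 0.005), ("rs2", "C3", 0.1, 0.05, 0.02)]
        )
        ann = make_annotation(["rs1", "rs2"])
        hits = top_hits(scan, ann, 0.01)
        assert list(hits.snps_by_analyte["C3"]["rsid"]) == ["rs1"]

    def test_gene_counted_once(self):
        scan = make_scan(
            [("rs1", "C3", 0.1, 0.05, 0.001), ("rs2", "C3", 0.1, 0.05, 0.001)]
        )
        ann = make_annotation(["rs1", "rs2"], genes=["GENEX", "GENEX"])
        hits = top_hits(scan, ann, 0.01)
        assert list(hits.pooled_genes) == ["GENEX"]
        assert len(hits.pooled_snps) == 2

    def test_empty_scan_no_error(self):
        hits = top_hits(make_scan([]), make_annotation([]), 0.01)
        assert hits.snps_by_analyte == {}
        assert len(hits.pooled_snps) == 0


class TestEnrichmentScores:
    def test_score_arithmetic(self):
        """Analyte with 4/8 hits in a group whose pooled share is 10/100
        scores 0.5/0.1 = 5."""
        g_target, g_other = FUNCTIONAL_GROUPS[0], FUNCTIONAL_GROUPS[1]
        rows = []
        # analyte A: 4 of 8 in target group
        for i in range(8):
            rows.append((f"a{i}", "C3", 0.1, 0.05, 0.001))
        # analyte B: 6 of 92 in target group (pooled: 10/100)
        for i in range(92):
            rows.append((f"b{i}", "Bb", 0.1, 0.05, 0.001))
        rsids = [r[0] for r in rows]
        groups = [g_target] * 4 + [g_other] * 4 + [g_target] * 6 + [g_other] * 86
        ann = make_annotation(rsids, groups=groups)
        hits = top_hits(make_scan(rows), ann, 0.01)
        scores = enrichment_scores(hits)
        row = scores[
            (scores["analyte"] == "C3")
            & (scores["functional_group"] == g_target)
            & (scores["level"] == "snp")
        ].iloc[0]
        assert row["enrichment_score"] == pytest.approx(5.0)

    def test_uniform_composition_gives_unit_scores(self):
        rows, groups = [], []
        for analyte in ("C3", "Bb"):
            for i, g in enumerate(FUNCTIONAL_GROUPS):
                rows.append((f"{analyte}{i}", analyte, 0.1, 0.05, 0.001))
                groups.append(g)
        rsids = [r[0] for r in rows]
        ann = make_annotation(rsids, groups=groups)
        hits = top_hits(make_scan(rows), ann, 0.01)
        scores = enrichment_scores(hits)
        assert np.allclose(scores["enrichment_score"], 1.0)

    def test_expected_weighted_scores_sum_to_one(self, study_sim):
        """Sum over groups of expected_proportion * score = 1 per analyte
        and level (algebraic identity of the ratio definition)."""
        from complement_pqtl.pqtl import scan

        table, _ = scan(
            study_sim.genotypes, study_sim.panel, study_sim.cohort,
            analytes=("C3", "Bb", "FactorB"),
        )
        hits = top_hits(table, study_sim.genotypes.snps, 0.05)
        scores = enrichment_scores(hits)
        for (analyte, level), grp in scores.groupby(["analyte", "level"]):
            total = (grp["expected_proportion"] * grp["enrichment_score"]).sum()
            assert total == pytest.approx(1.0, abs=1e-12), (analyte, level)


class TestOverlap:
    def test_disjoint_sets_empty(self):
        scan = make_scan([("rs1", "C3", 0.1, 0.05, 0.001)])
        disease = pd.DataFrame(
            {"rsid": ["rsX"], "risk_allele": ["minor"], "risk_nt": ["A"],
             "odds_ratio": [2.0]}
        )
        assert len(overlap_disease_snps(scan, disease)) == 0

    def test_one_snp_two_analytes_fans_out(self):
        scan = make_scan(
            [("rs1", "C3", 0.1, 0.05, 0.001), ("rs1", "Bb", -0.2, 0.05, 0.002)]
        )
        disease = pd.DataFrame(
            {"rsid": ["rs1"], "risk_allele": ["minor"], "risk_nt": ["A"],
             "odds_ratio": [2.0]}
        )
        out = overlap_disease_snps(scan, disease)
        assert len(out) == 2
        assert set(out["analyte"]) == {"C3", "Bb"}

    def test_duplicate_disease_rows_rejected(self):
        scan = make_scan([("rs1", "C3", 0.1, 0.05, 0.001)])
        disease = pd.DataFrame(
            {"rsid": ["rs1", "rs1"], "risk_allele": ["minor"] * 2,
             "risk_nt": ["A"] * 2, "odds_ratio": [2.0, 2.0]}
        )
        with pytest.raises(DataError, match="duplicate"):
            overlap_disease_snps(scan, disease)


class TestCisTrans:
    @pytest.fixture
    def tables(self):
        ann = make_annotation(["rs1"])
        tss = pd.DataFrame(
            {"gene": ["C3"], "chrom": ["1"], "tss": [1_000_000]},
            index=pd.Index(["C3"], name="analyte"),
        )
        return ann, tss

    @pytest.mark.parametrize(
        "pos,chrom,expected",
        [
            (1_500_000, "1", "cis"),
            (2_000_000, "1", "cis"),  # exactly 1 Mb away: inclusive boundary
            (2_000_001, "1", "trans"),
            (1, "1", "cis"),  # symmetric on the other side (999,999 bp)
            (1_500_000, "2", "trans"),
        ],
    )
    def test_window_rules(self, tables, pos, chrom, expected):
        ann, tss = tables
        ann.loc["rs1", "pos"] = pos
        ann.loc["rs1", "chrom"] = chrom
        assert classify_cis_trans("rs1", "C3", ann, tss) == expected

    def test_unmapped_analyte_unknown(self, tables):
        ann, tss = tables
        assert classify_cis_trans("rs1", "SC5b9", ann, tss) == "unknown"


class TestDirectionality:
    def test_collinear_points_r2_one(self):
        pts = pd.DataFrame(
            {"rsid": list("abc"), "odds_ratio": [1.0, 2.0, 3.0],
             "beta": [0.1, 0.3, 0.5]}
        )
        assert directionality(pts)["r_squared"] == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            pts = pd.DataFrame(
                {"rsid": [f"r{i}" for i in range(n)],
                 "odds_ratio": rng.uniform(0.3, 3.0, n),
                 "beta": rng.normal(size=n)}
            )
            res = directionality(pts)
            r = np.corrcoef(pts["odds_ratio"], pts["beta"])[0, 1]
            assert res["r_squared"] == pytest.approx(r**2, abs=1e-12)

    def test_r2_invariant_under_affine_or_rescaling(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(
            {"rsid": [f"r{i}" for i in range(12)],
             "odds_ratio": rng.uniform(0.5, 2.5, 12),
             "beta": rng.normal(size=12)}
        )
        base = directionality(pts)["r_squared"]
        scaled = pts.assign(odds_ratio=3.0 * pts["odds_ratio"] + 1.0)
        assert directionality(scaled)["r_squared"] == pytest.approx(base, abs=1e-12)

    def test_allele_flip_matches_direct_refit(self):
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(
            {"rsid": [f"r{i}" for i in range(10)],
             "odds_ratio": rng.uniform(0.5, 2.5, 10),
             "beta": rng.normal(size=10)}
        )
        flipped = pts.assign(odds_ratio=1.0 / pts["odds_ratio"], beta=-pts["beta"])
        res_flip = directionality(flipped)
        refit = directionality(
            pd.DataFrame(
                {"rsid": pts["rsid"], "odds_ratio": 1.0 / pts["odds_ratio"],
                 "beta": -pts["beta"]}
            )
        )
        assert res_flip == refit

    def test_major_allele_rows_are_expressed_minor_respect(self):
        """A row whose risk allele is the major allele enters the point set
        with its OR inverted."""
        scan = make_scan(
            [("rs1", "C3", 0.2, 0.05, 0.001), ("rs2", "C3", -0.1, 0.05, 0.001),
             ("rs3", "C3", 0.05, 0.02, 0.001)]
        )
        ann = make_annotation(["rs1", "rs2", "rs3"])
        disease = pd.DataFrame(
            {"rsid": ["rs1", "rs2", "rs3"],
             "risk_allele": ["minor", "major", "minor"],
             "risk_nt": ["A", "G", "A"],  # annotation minor allele is A
             "odds_ratio": [2.0, 2.0, 1.5]}
        )
        pts = directionality_points(scan, disease, "C3", ann)
        by = pts.set_index("rsid")["odds_ratio"]
        assert by["rs1"] == pytest.approx(2.0)
        assert by["rs2"] == pytest.approx(0.5)

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame(
            {"rsid": ["a", "b"], "odds_ratio": [1.0, 2.0], "beta": [0.1, 0.2]}
        )
        with pytest.raises(DataError, match="3 points"):
            directionality(pts)


class TestExternalOverlap:
    def test_join_and_fan_out(self):
        scan = make_scan(
            [("rs800292", "C3", 0.1, 0.05, 0.001),
             ("rs800292", "Bb", -0.2, 0.05, 0.002),
             ("rsZ", "C3", 0.0, 0.05, 0.004)]
        )
        ann = make_annotation(["rs800292", "rsZ"])
        hits = top_hits(scan, ann, 0.01)
        external = pd.DataFrame(
            {"phenotype": ["fatigue"], "rsid": ["rs800292"],
             "odds_ratio": [0.75], "ci": ["0.61-0.94"], "p": [0.01]}
        )
        out = external_overlap(hits, external, ann)
        assert len(out) == 2
        assert set(out["analyte"]) == {"C3", "Bb"}

    def test_empty_external_table(self):
        scan = make_scan([("rs1", "C3", 0.1, 0.05, 0.001)])
        ann = make_annotation(["rs1"])
        hits = top_hits(scan, ann, 0.01)
        external = pd.DataFrame(
            columns=["phenotype", "rsid", "odds_ratio", "ci", "p"]
        )
        assert len(external_overlap(hits, external, ann)) == 0
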