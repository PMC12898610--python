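"""Functional-group enrichment, disease overlap, cis/trans calls and
OR--beta directionality for pQTL scan output.

The enrichment score for analyte *a* and functional group *g* is

    score(a, g) = observed proportion of a's top hits in g
                  / expected proportion of g in the pooled top-hit lists

computed separately at the SNP level and at the gene level (genes counted
once per analyte list).  Scores above 1 indicate overrepresentation, and
for every analyte the identity sum_g expected_g * score_g = 1 holds by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import FUNCTIONAL_GROUPS, DataError

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # bp, inclusive


@dataclass
class TopHits:
    """Per-analyte significant SNP lists plus pooled unique sets."""

    snps_by_analyte: dict  # analyte -> DataFrame (rsid, gene, functional_group, p_fvr)
    pooled_snps: pd.Index
    pooled_genes: pd.Index
    threshold: float


def top_hits(
    scan_records: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    p_threshold: float = 0.01,
) -> TopHits:
    """Significant records per analyte at strict p < threshold.

    SNPs missing gene annotation stay in the SNP-level lists but are
    excluded from gene-level counts (with a warning).
    """
    ann = snp_annotation
    sig = scan_records[scan_records["p_fvr"] < p_threshold].copy()
    sig["gene"] = sig["rsid"].map(ann["gene"]) if "gene" in ann.columns else ""
    sig["functional_group"] = sig["rsid"].map(ann["functional_group"])
    n_missing = int((sig["gene"].fillna("") == "").sum())
    if n_missing:
        log.warning("%d top hits lack gene annotation; excluded at gene level", n_missing)
    by_analyte = {
        analyte: grp[["rsid", "gene", "functional_group", "p_fvr"]].reset_index(drop=True)
        for analyte, grp in sig.groupby("analyte")
    }
    pooled_snps = pd.Index(sig["rsid"].unique())
    pooled_genes = pd.Index(sig.loc[sig["gene"].fillna("") != "", "gene"].unique())
    return TopHits(
        snps_by_analyte=by_analyte,
        pooled_snps=pooled_snps,
        pooled_genes=pooled_genes,
        threshold=p_threshold,
    )


def _group_counts(frame: pd.DataFrame, level: str) -> pd.Series:
    if level == "snp":
        items = frame[["rsid", "functional_group"]]
    else:
        items = (
            frame.loc[frame["gene"].fillna("") != "", ["gene", "functional_group"]]
            .drop_duplicates("gene")
        )
    return items["functional_group"].value_counts().reindex(
        FUNCTIONAL_GROUPS, fill_value=0
    )


def enrichment_scores(
    hits: TopHits, deduplicate_pooled: bool = False
) -> pd.DataFrame:
    """Observed/expected functional-group proportions per analyte.

    Expected proportions come from pooling every analyte's top-hit list;
    by default a SNP shared by several lists counts once per list
    (``deduplicate_pooled=True`` counts each SNP/gene once overall).
    Returns one row per (analyte, group, level).
    """
    levels = ("snp", "gene")
    pooled = {lev: pd.Series(0, index=list(FUNCTIONAL_GROUPS)) for lev in levels}
    observed = {}
    for analyte, frame in hits.snps_by_analyte.items():
        observed[analyte] = {lev: _group_counts(frame, lev) for lev in levels}
        for lev in levels:
            pooled[lev] = pooled[lev] + observed[analyte][lev]
    if deduplicate_pooled:
        all_frames = pd.concat(hits.snps_by_analyte.values(), ignore_index=True) \
            if hits.snps_by_analyte else pd.DataFrame(
                columns=["rsid", "gene", "functional_group"])
        pooled["snp"] = _group_counts(all_frames.drop_duplicates("rsid"), "snp")
        pooled["gene"] = _group_counts(all_frames, "gene")
    rows = []
    for analyte, obs in observed.items():
        for lev in levels:
            total_obs = obs[lev].sum()
            total_exp = pooled[lev].sum()
            for group in FUNCTIONAL_GROUPS:
                if total_obs == 0 or total_exp == 0:
                    continue
                obs_prop = obs[lev][group] / total_obs
                exp_prop = pooled[lev][group] / total_exp
                if exp_prop == 0:
                    if obs_prop > 0:
                        log.warning(
                            "group %s has zero expected proportion but observed hits", group
                        )
                        score = float("inf")
                    else:
                        continue
                else:
                    score = obs_prop / exp_prop
                rows.append(
                    {
                        "analyte": analyte,
                        "functional_group": group,
                        "level": lev,
                        "observed_count": int(obs[lev][group]),
                        "observed_proportion": float(obs_prop),
                        "expected_proportion": float(exp_prop),
                        "enrichment_score": float(score),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["analyte", "functional_group", "level", "observed_count",
                 "observed_proportion", "expected_proportion", "enrichment_score"],
    )


def overlap_disease_snps(
    scan_records: pd.DataFrame,
    disease_table: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """SNPs significant in the pQTL scan that also carry a disease
    association; one output row per (rsid, analyte) pair."""
    if disease_table["rsid"].duplicated().any():
        raise DataError("disease table has duplicate rsid rows")
    sig = scan_records[scan_records["p_fvr"] < p_threshold]
    merged = sig.merge(disease_table, on="rsid", how="inner")
    cols = ["rsid", "analyte", "beta", "se", "p_fvr", "cis_trans",
            "risk_allele", "risk_nt", "odds_ratio"]
    return merged[[c for c in cols if c in merged.columns]].reset_index(drop=True)


def classify_cis_trans(
    rsid: str,
    analyte: str,
    snp_annotation: pd.DataFrame,
    tss_table: pd.DataFrame,
) -> str:
    """cis iff the SNP lies within 1 Mb (inclusive) of the TSS of the gene
    encoding the analyte, on the same chromosome; unknown if unmapped."""
    if analyte not in tss_table.index or rsid not in snp_annotation.index:
        return "unknown"
    snp = snp_annotation.loc[rsid]
    tss = tss_table.loc[analyte]
    if str(snp["chrom"]) != str(tss["chrom"]):
        return "trans"
    return "cis" if abs(int(snp["pos"]) - int(tss["tss"])) <= CIS_WINDOW else "trans"


def annotate_cis_trans(
    scan_records: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    tss_table: pd.DataFrame,
) -> pd.DataFrame:
    out = scan_records.copy()
    out["cis_trans"] = [
        classify_cis_trans(r, a, snp_annotation, tss_table)
        for r, a in zip(out["rsid"], out["analyte"])
    ]
    return out


def directionality_points(
    scan_records: pd.DataFrame,
    disease_table: pd.DataFrame,
    analyte: str,
    snp_annotation: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """(OR, beta) pairs for one analyte, all with respect to the minor
    allele: rows whose risk allele is the major allele get OR inverted
    (beta is already per minor-allele copy)."""
    overlap = overlap_disease_snps(scan_records, disease_table, p_threshold)
    pts = overlap[overlap["analyte"] == analyte].copy()
    if snp_annotation is not None and "risk_nt" in pts.columns:
        minor = pts["rsid"].map(snp_annotation["minor_allele"])
        is_minor = pts["risk_nt"].astype(str).eq(minor.astype(str))
    else:
        is_minor = pts["risk_allele"].eq("minor")
    pts["odds_ratio"] = np.where(
        is_minor, pts["odds_ratio"], 1.0 / pts["odds_ratio"]
    )
    return pts[["rsid", "odds_ratio", "beta"]].reset_index(drop=True)


def directionality(points: pd.DataFrame) -> dict:
    """OLS of protein beta on disease OR; returns slope, intercept, R^2."""
    if len(points) < 3:
        raise DataError("directionality regression needs at least 3 points")
    x = points["odds_ratio"].to_numpy(dtype=float)
    y = points["beta"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError("odds ratios have zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "n": int(fit.nobs),
    }


def external_overlap(
    hits: TopHits,
    external: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    top_n: int = 50,
) -> pd.DataFrame:
    """Join each analyte's top-N (lowest p) SNPs against an external
    summary-statistics table keyed by rsid.

    The external table needs columns phenotype, rsid, odds_ratio, ci, p;
    unmatched rows are dropped.  A SNP in two analytes' lists that matches
    one external phenotype yields two rows.
    """
    required = {"phenotype", "rsid", "odds_ratio", "ci", "p"}
    missing = required - set(external.columns)
    if missing:
        raise DataError(f"external table missing columns: {sorted(missing)}")
    rows = []
    for analyte, frame in hits.snps_by_analyte.items():
        top = frame.nsmallest(top_n, "p_fvr")
        merged = top.merge(external, on="rsid", how="inner")
        for r in merged.itertuples():
            cons = (
                snp_annotation.at[r.rsid, "consequence"]
                if r.rsid in snp_annotation.index
                else ""
            )
            rows.append(
                {
                    "phenotype": r.phenotype,
                    "rsid": r.rsid,
                    "gene": r.gene,
                    "consequence": cons,
                    "external_odds_ratio": r.odds_ratio,
                    "external_ci": r.ci,
                    "external_p": r.p,
                    "analyte": analyte,
                    "pqtl_p": r.p_fvr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["phenotype", "rsid", "gene", "consequence", "external_odds_ratio",
                 "external_ci", "external_p", "analyte", "pqtl_p"],
    )
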