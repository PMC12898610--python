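"""SNP x protein QTL scan: covariate-adjusted full-vs-reduced F-tests.

For each SNP--protein pair the full model regresses the log2 protein level
on the additive minor-allele dosage plus the analyte's covariates; the
reduced model omits the dosage.  Both are fitted on identical rows and

    F = ((RSS_reduced - RSS_full) / 1) / (RSS_full / (n - p_full))

is referred to F(1, n - p_full).  Because the genotype term adds a single
degree of freedom, F equals the squared t statistic of the dosage
coefficient -- an identity the test suite asserts.  Bonferroni correction
uses m = the number of models actually fitted in a scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ALL_MEASURES, Cohort, DataError, GenotypeMatrix, ProteinPanel

log = logging.getLogger(__name__)

#: A pair is testable only if, among analyzed rows, the dosage takes >= 2
#: distinct values and the minority dosage class has >= MIN_MINOR_COUNT rows.
MIN_MINOR_COUNT = 3


@dataclass
class PqtlRecord:
    rsid: str
    analyte: str
    beta: float  # per minor-allele copy, log2 units
    se: float
    f_statistic: float
    p_fvr: float
    p_bonferroni: float
    n_used: int
    cis_trans: str = "unknown"


def _ols(X: np.ndarray, y: np.ndarray):
    """Plain least squares returning (beta, se, rss, df_resid)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise DataError("rank-deficient design in pQTL model")
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * rss / dof)
    return beta, se, rss, dof


def fit_pqtl(
    genotypes: GenotypeMatrix,
    panel: ProteinPanel,
    cohort: Cohort,
    rsid: str,
    analyte: str,
    covariates=(),
) -> PqtlRecord | None:
    """Fit one SNP--protein pair; returns None (with a log entry) when the
    SNP is effectively monomorphic among the analyzed rows."""
    dose = genotypes.dosage(rsid)
    y = panel.values[analyte]
    covs = cohort.covariate_frame()[list(covariates)] if covariates else None
    cols = {"y": y, "dose": dose}
    if covs is not None:
        for c in covs.columns:
            cols[c] = covs[c]
    df = pd.DataFrame(cols).dropna()
    n = len(df)
    if n <= len(covariates) + 3:
        log.info("skipping %s/%s: only %d complete rows", rsid, analyte, n)
        return None
    dose_vals = df["dose"].to_numpy()
    counts = pd.Series(dose_vals).value_counts()
    if len(counts) < 2 or counts.sort_values().iloc[:-1].sum() < MIN_MINOR_COUNT:
        log.info("skipping %s/%s: effectively monomorphic", rsid, analyte)
        return None
    yv = df["y"].to_numpy(dtype=float)
    cov_mat = df[[c for c in df.columns if c not in ("y", "dose")]].to_numpy(dtype=float)
    ones = np.ones((n, 1))
    X_full = np.column_stack([ones, dose_vals[:, None], cov_mat])
    X_red = np.column_stack([ones, cov_mat])
    beta_f, se_f, rss_full, dof_full = _ols(X_full, yv)
    _, _, rss_red, _ = _ols(X_red, yv)
    if rss_full > 0:
        f_stat = max(rss_red - rss_full, 0.0) / (rss_full / dof_full)
        p = float(stats.f.sf(f_stat, 1, dof_full))
    elif rss_red > rss_full:  # genotype explains the last residual exactly
        f_stat, p = float("inf"), 0.0
    else:  # outcome constant or perfectly fit without genotype
        f_stat, p = 0.0, 1.0
    return PqtlRecord(
        rsid=rsid,
        analyte=analyte,
        beta=float(beta_f[1]),
        se=float(se_f[1]),
        f_statistic=float(f_stat),
        p_fvr=p,
        p_bonferroni=np.nan,  # filled by scan()
        n_used=n,
    )


def scan(
    genotypes: GenotypeMatrix,
    panel: ProteinPanel,
    cohort: Cohort,
    covariate_map: dict | None = None,
    analytes=ALL_MEASURES,
) -> tuple[pd.DataFrame, dict]:
    """Fit every testable (SNP, analyte) pair and Bonferroni-correct.

    ``covariate_map`` maps analyte -> list of covariates (typically the
    screening output); missing analytes get no adjustment.  Returns the
    record table and a summary dict with the number of models fitted and
    the counts of significant pairs at the two reporting tiers (p < 0.05
    and p < 0.01).
    """
    covariate_map = covariate_map or {}
    records = []
    skipped = 0
    for rsid in genotypes.rsids:
        for analyte in analytes:
            rec = fit_pqtl(
                genotypes, panel, cohort, rsid, analyte,
                covariates=tuple(covariate_map.get(analyte, ())),
            )
            if rec is None:
                skipped += 1
            else:
                records.append(rec)
    m = len(records)
    rows = []
    for rec in records:
        rec.p_bonferroni = min(1.0, rec.p_fvr * m)
        rows.append(asdict(rec))
    table = pd.DataFrame(
        rows,
        columns=["rsid", "analyte", "beta", "se", "f_statistic", "p_fvr",
                 "p_bonferroni", "n_used", "cis_trans"],
    )
    summary = {
        "models_fitted": m,
        "pairs_skipped": skipped,
        "significant_p05": int((table["p_fvr"] < 0.05).sum()) if m else 0,
        "significant_p01": int((table["p_fvr"] < 0.01).sum()) if m else 0,
        "unique_snps_p05": int(table.loc[table["p_fvr"] < 0.05, "rsid"].nunique()) if m else 0,
        "unique_snps_p01": int(table.loc[table["p_fvr"] < 0.01, "rsid"].nunique()) if m else 0,
    }
    return table, summary


def genotype_stratified_summary(
    genotypes: GenotypeMatrix,
    panel: ProteinPanel,
    cohort: Cohort,
    rsid: str,
    analyte: str,
) -> pd.DataFrame:
    """Per-genotype five-number summary of log2 levels plus the case
    fraction in each dosage stratum (boxplot-style table)."""
    df = pd.DataFrame(
        {
            "dose": genotypes.dosage(rsid),
            "y": panel.values[analyte],
            "case": cohort.is_case,
        }
    ).dropna(subset=["dose"])
    rows = []
    for dose, grp in df.groupby("dose", sort=True):
        vals = grp["y"].dropna().to_numpy()
        q = (
            np.percentile(vals, [0, 25, 50, 75, 100])
            if vals.size
            else [np.nan] * 5
        )
        rows.append(
            {
                "rsid": rsid,
                "analyte": analyte,
                "dosage": int(dose),
                "n": len(grp),
                "n_case": int(grp["case"].sum()),
                "case_fraction": float(grp["case"].mean()),
                "min": float(q[0]),
                "q1": float(q[1]),
                "median": float(q[2]),
                "q3": float(q[3]),
                "max": float(q[4]),
                "mean": float(vals.mean()) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
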