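"""Genotype-stratified ROC screening and two-marker subgroup assignment.

Within a genotype-defined stratum, case status is modeled by logistic
regression on the log2 analyte level plus covariates; the AUC of the
predicted probabilities is computed as Mann--Whitney concordance (ties
count 1/2), with the Hanley--McNeil standard error and a normal
approximation for the test against AUC = 0.5.  Covariates that are
constant within a stratum (e.g., sex in an all-female stratum) are dropped
automatically, and with no covariates left the monotone logistic link
makes the AUC identical to the AUC of the raw analyte values.

Two-marker subgrouping: a subject is "het" iff heterozygous (dosage
exactly 1) at either marker; homozygous at both -- including
homozygous-risk carriers (dosage 2) -- is "rem".  Labels combine case
status with carriership: CFShet, CFSrem, NFhet, NFrem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import association
from .datatypes import (
    ALL_MEASURES,
    SUBGROUP_LABELS,
    Cohort,
    DataError,
    GenotypeMatrix,
    ProteinPanel,
)

log = logging.getLogger(__name__)


@dataclass
class RocFilters:
    """Screening thresholds; defaults follow the study's filter rule."""

    auc_min: float = 0.75
    auc_strict: bool = True  # True: AUC > auc_min; False: AUC >= auc_min
    p_max: float = 0.05
    n_min: int = 15

    def passes(self, auc: float, p: float, n: int) -> bool:
        auc_ok = auc > self.auc_min if self.auc_strict else auc >= self.auc_min
        return bool(auc_ok and p < self.p_max and n >= self.n_min)


@dataclass
class RocRecord:
    stratum: str  # "rsid=dosage,..." conditions
    analyte: str
    covariates: str
    n_case: int
    n_control: int
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    p_vs_half: float
    passes_filters: bool


def mann_whitney_auc(scores, labels) -> float:
    """P(score_case > score_control) + 1/2 P(tie), via mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_case - 1) * (q1 - auc**2)
        + (n_control - 1) * (q2 - auc**2)
    ) / (n_case * n_control)
    return float(np.sqrt(max(var, 0.0)))


def _auc_record(
    scores, labels, stratum: str, analyte: str, covariates, filters: RocFilters
) -> RocRecord:
    labels = np.asarray(labels, dtype=bool)
    auc = mann_whitney_auc(scores, labels)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    se = hanley_mcneil_se(auc, n1, n0)
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return RocRecord(
        stratum=stratum,
        analyte=analyte,
        covariates=",".join(covariates),
        n_case=n1,
        n_control=n0,
        auc=auc,
        se=se,
        ci_lower=float(max(auc - 1.96 * se, 0.0)),
        ci_upper=float(min(auc + 1.96 * se, 1.0)),
        p_vs_half=p,
        passes_filters=filters.passes(auc, p, n1 + n0),
    )


def stratum_roc(
    genotypes: GenotypeMatrix,
    panel: ProteinPanel,
    cohort: Cohort,
    stratum_conditions,
    analyte: str,
    covariates=(),
    filters: RocFilters | None = None,
) -> RocRecord:
    """ROC of one analyte within the subjects matching every genotype
    condition (a list of (rsid, dosage) pairs; empty list = all subjects)."""
    filters = filters or RocFilters()
    mask = pd.Series(True, index=cohort.ids)
    parts = []
    for rsid, dosage in stratum_conditions:
        mask &= genotypes.dosage(rsid).eq(dosage)
        parts.append(f"{rsid}={int(dosage)}")
    stratum_name = ",".join(parts) if parts else "all"
    ids = mask[mask].index
    if len(ids) == 0:
        raise DataError(f"stratum {stratum_name} is empty")
    df = pd.DataFrame(
        {"y": cohort.is_case.astype(float), "protein": panel.values[analyte]}
    )
    cov_frame = cohort.covariate_frame()
    for c in covariates:
        df[c] = cov_frame[c]
    df = df.loc[df.index.isin(ids)].dropna()
    if df["y"].nunique() < 2:
        raise DataError(f"stratum {stratum_name} has a single outcome class")
    kept_covs = [c for c in covariates if np.ptp(df[c].to_numpy()) > 0]
    dropped = set(covariates) - set(kept_covs)
    if dropped:
        log.info("stratum %s: constant covariates dropped: %s", stratum_name, sorted(dropped))
    if kept_covs:
        import warnings

        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import (
            ConvergenceWarning,
            PerfectSeparationWarning,
        )

        X = sm.add_constant(df[["protein"] + kept_covs].astype(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("error", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sm.Logit(df["y"].to_numpy(), X).fit(
                    method="newton", maxiter=association.MAX_ITER,
                    tol=association.TOL, disp=False,
                )
            scores = np.asarray(res.predict(X))
        except Exception as exc:  # separation: probabilities degenerate
            log.info("stratum %s logistic failed (%s); ranking on raw level", stratum_name, exc)
            scores = df["protein"].to_numpy()
    else:
        # monotone link: predicted probability ordering equals the raw values
        scores = df["protein"].to_numpy()
    return _auc_record(
        scores, df["y"].to_numpy(dtype=bool), stratum_name, analyte, kept_covs, filters
    )


def screen_strata(
    genotypes: GenotypeMatrix,
    panel: ProteinPanel,
    cohort: Cohort,
    snp_set,
    covariate_map: dict | None = None,
    filters: RocFilters | None = None,
    analytes=ALL_MEASURES,
) -> pd.DataFrame:
    """One ROC record per (SNP, observed genotype level, analyte), ranked
    by AUC; strata with a single outcome class are skipped and logged."""
    if not len(snp_set):
        raise DataError("snp_set must be nonempty")
    filters = filters or RocFilters()
    covariate_map = covariate_map or {}
    rows = []
    for rsid in snp_set:
        dose = genotypes.dosage(rsid).dropna()
        for level in sorted(dose.unique()):
            for analyte in analytes:
                try:
                    rec = stratum_roc(
                        genotypes, panel, cohort, [(rsid, level)], analyte,
                        covariates=tuple(covariate_map.get(analyte, ())),
                        filters=filters,
                    )
                except DataError as exc:
                    log.info("skipping stratum: %s", exc)
                    break  # same stratum fails for every analyte
                rows.append(asdict(rec))
    table = pd.DataFrame(
        rows,
        columns=["stratum", "analyte", "covariates", "n_case", "n_control",
                 "auc", "se", "ci_lower", "ci_upper", "p_vs_half", "passes_filters"],
    )
    return table.sort_values("auc", ascending=False).reset_index(drop=True)


def assign_subgroups(
    genotypes: GenotypeMatrix,
    cohort: Cohort,
    marker_a: str,
    marker_b: str,
    missing: str = "exclude",
) -> pd.Series:
    """Four-level subgroup labels from heterozygosity at two markers.

    ``missing`` controls subjects with a missing genotype at either marker:
    "exclude" drops them (NaN label), "rem" treats them as non-carriers.
    """
    for m in (marker_a, marker_b):
        if m not in genotypes.dosages.columns:
            raise DataError(f"marker {m} absent from genotype matrix")
    da = genotypes.dosage(marker_a)
    db = genotypes.dosage(marker_b)
    het = da.eq(1) | db.eq(1)
    any_missing = da.isna() | db.isna()
    prefix = np.where(cohort.is_case, "CFS", "NF")
    labels = pd.Series(
        np.where(het, "het", "rem"), index=cohort.ids, dtype=object
    )
    labels = pd.Series(prefix, index=cohort.ids) + labels
    if missing == "exclude":
        labels[any_missing & ~het] = np.nan  # an observed het call is decisive
    elif missing != "rem":
        raise ValueError("missing must be 'exclude' or 'rem'")
    return labels


def subgroup_reanalysis(
    panel: ProteinPanel,
    labels: pd.Series,
    cohort: Cohort,
    genotypes: GenotypeMatrix,
    surveys: pd.DataFrame | None = None,
    covariate_map: dict | None = None,
    analytes=ALL_MEASURES,
    reference: str = "NFhet",
    filters: RocFilters | None = None,
    survey_scores=(),
) -> dict:
    """Re-run the association battery on the four genotype subgroups.

    Returns a bundle with per-analyte LRT results, multinomial fits versus
    the reference level, pairwise covariate-adjusted contrasts, ROC
    restricted to the heterozygous subgroups, and (optionally) het-only
    survey associations.
    """
    covariate_map = covariate_map or {}
    filters = filters or RocFilters()
    populated = labels.dropna().value_counts()
    if (populated > 0).sum() < 3:
        raise DataError("need at least 3 populated subgroups")
    counts = {lab: int(populated.get(lab, 0)) for lab in SUBGROUP_LABELS}
    het_ids = labels[labels.isin(["CFShet", "NFhet"])].index

    lrt_rows = []
    mn_fits = {}
    contrast_frames = []
    for analyte in analytes:
        covs = tuple(covariate_map.get(analyte, ()))
        full = association.multinomial_subgroups(
            panel, labels, analyte, cohort, covariates=covs, reference=reference
        )
        reduced = association.null_multinomial(
            labels, cohort, covariates=covs, reference=reference, rows=full.rows
        )
        res = association.lrt(full, reduced)
        lrt_rows.append(
            {"analyte": analyte, "statistic": res.statistic, "df": res.df,
             "p_value": res.p_value, "n_used": full.n_used}
        )
        mn_fits[analyte] = full
        lin = association.group_linear_model(
            panel, labels, analyte, cohort, covariates=covs, reference=reference
        )
        contr = association.pairwise_contrasts(lin)
        contr.insert(0, "analyte", analyte)
        contrast_frames.append(contr)

    het_cohort = Cohort(cohort.subjects.loc[cohort.ids.isin(het_ids)])
    het_panel = ProteinPanel(panel.values.loc[panel.ids.isin(het_ids)], panel.units)
    het_genotypes = GenotypeMatrix(
        genotypes.dosages.loc[genotypes.dosages.index.isin(het_ids)].copy(),
        genotypes.snps,
    )
    het_roc = []
    for analyte in analytes:
        try:
            rec = stratum_roc(
                het_genotypes, het_panel, het_cohort, [], analyte,
                covariates=tuple(covariate_map.get(analyte, ())), filters=filters,
            )
            het_roc.append(asdict(rec))
        except DataError as exc:
            log.info("het-only ROC skipped for %s: %s", analyte, exc)
    het_roc = pd.DataFrame(het_roc)

    het_surveys = None
    if surveys is not None and len(survey_scores):
        rows = []
        het_survey_frame = surveys.loc[surveys.index.isin(het_ids)]
        for analyte in analytes:
            for score in survey_scores:
                try:
                    fit = association.survey_association(
                        het_panel, het_survey_frame, het_cohort, analyte, score,
                        covariates=tuple(covariate_map.get(analyte, ())),
                    )
                except DataError as exc:
                    log.info("het-only survey fit skipped (%s/%s): %s", analyte, score, exc)
                    continue
                rows.append(
                    {"analyte": analyte, "score": score,
                     "beta": fit.coef("score"), "se": float(fit.terms.loc["score", "se"]),
                     "p_value": fit.pvalue("score"), "n_used": fit.n_used}
                )
        het_surveys = pd.DataFrame(rows)

    return {
        "counts": counts,
        "lrt": pd.DataFrame(lrt_rows),
        "multinomial": mn_fits,
        "contrasts": pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame(),
        "het_roc": het_roc,
        "het_surveys": het_surveys,
    }
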