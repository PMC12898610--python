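"""Case--control and subgroup protein association models.

Conventions chosen to match the reporting style of the source study design:

* linear case--control models code the group term as control (NF) = 1, so
  the reported group coefficient is the adjusted control-minus-case mean
  difference (negative values mean higher levels in cases);
* logistic models take case = 1, so a positive protein coefficient means
  higher protein levels raise the odds of being a case;
* multinomial subgroup models use NFhet as the reference category;
* no multiplicity adjustment is applied across analytes (documented in the
  output metadata) -- pairwise contrasts report unadjusted p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .datatypes import Cohort, DataError, ProteinPanel

log = logging.getLogger(__name__)

MAX_ITER = 100
TOL = 1e-8


@dataclass
class ModelFit:
    """A fitted regression: coefficient table plus likelihood bookkeeping."""

    formula: str
    kind: str  # linear | logistic | multinomial
    terms: pd.DataFrame  # index = term; columns beta, se, p
    n_used: int
    log_likelihood: float
    n_params: int
    rows: tuple  # subject ids used, for LRT row-matching
    adjusted_r2: float = float("nan")
    converged: bool = True
    reference: str | None = None  # multinomial reference level
    level_terms: dict = field(default_factory=dict)  # level -> terms frame
    result: object | None = None  # underlying statsmodels results

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float


def _complete_design(columns: dict[str, pd.Series]) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    return df.dropna()


def _prepare_X(df: pd.DataFrame, predictors: list[str]) -> tuple[pd.DataFrame, list[str]]:
    kept = []
    for name in predictors:
        if np.ptp(df[name].to_numpy(dtype=float)) == 0:
            log.warning("term %s is constant in this sample; dropped", name)
            continue
        kept.append(name)
    X = sm.add_constant(df[kept].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DataError(f"collinear design: terms {list(X.columns)} have rank {rank}")
    return X, kept


def _covariate_columns(cohort: Cohort, covariates) -> dict[str, pd.Series]:
    frame = cohort.covariate_frame()
    bad = set(covariates) - set(frame.columns)
    if bad:
        raise DataError(f"unknown covariates: {sorted(bad)}")
    return {c: frame[c] for c in covariates}


def _terms_frame(params, bse, pvals, names) -> pd.DataFrame:
    return pd.DataFrame(
        {"beta": np.asarray(params, dtype=float),
         "se": np.asarray(bse, dtype=float),
         "p": np.asarray(pvals, dtype=float)},
        index=list(names),
    )


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

def case_control_linear(
    panel: ProteinPanel, cohort: Cohort, analyte: str, covariates=()
) -> ModelFit:
    """OLS of log2 level on illness group (NF=1) plus covariates."""
    cols = {"y": panel.values[analyte]}
    cols["group"] = (~cohort.is_case).astype(float)  # NF = 1 -> beta = NF - CFS
    cols.update(_covariate_columns(cohort, covariates))
    df = _complete_design(cols)
    if df["group"].nunique() < 2:
        raise DataError("both illness groups must be represented")
    X, kept = _prepare_X(df, [c for c in cols if c != "y"])
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    return ModelFit(
        formula=f"log2({analyte}) ~ group(NF=1) + {list(covariates)}",
        kind="linear",
        terms=_terms_frame(fit.params, fit.bse, fit.pvalues, X.columns),
        n_used=int(fit.nobs),
        log_likelihood=float(fit.llf),
        n_params=X.shape[1] + 1,  # coefficients + residual variance
        rows=tuple(df.index),
        adjusted_r2=float(fit.rsquared_adj),
        result=fit,
    )


def group_linear_model(
    panel: ProteinPanel,
    labels: pd.Series,
    analyte: str,
    cohort: Cohort,
    covariates=(),
    reference: str | None = None,
) -> ModelFit:
    """OLS of log2 level on a categorical group term (dummy coding)."""
    labels = labels.dropna()
    levels = sorted(labels.unique())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise DataError(f"reference level {reference!r} not present")
    cols = {"y": panel.values[analyte]}
    dummy_names = []
    for lev in levels:
        if lev == reference:
            continue
        name = f"group[{lev}]"
        cols[name] = labels.eq(lev).astype(float)
        dummy_names.append(name)
    cols.update(_covariate_columns(cohort, covariates))
    df = _complete_design(cols).loc[lambda d: d.index.isin(labels.index)]
    X, kept = _prepare_X(df, [c for c in cols if c != "y"])
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    mf = ModelFit(
        formula=f"log2({analyte}) ~ group({len(levels)} levels, ref={reference}) + {list(covariates)}",
        kind="linear",
        terms=_terms_frame(fit.params, fit.bse, fit.pvalues, X.columns),
        n_used=int(fit.nobs),
        log_likelihood=float(fit.llf),
        n_params=X.shape[1] + 1,
        rows=tuple(df.index),
        adjusted_r2=float(fit.rsquared_adj),
        reference=reference,
        result=fit,
    )
    mf.level_terms = {"__levels__": levels}
    return mf


def pairwise_contrasts(fit: ModelFit) -> pd.DataFrame:
    """All pairwise adjusted group differences from a group linear model.

    Adjusted means are evaluated at the sample means of the covariates, so
    each contrast reduces to a difference of group-dummy coefficients; p
    values are t-based with the residual degrees of freedom and carry no
    multiplicity adjustment.
    """
    if fit.kind != "linear" or fit.reference is None:
        raise DataError("pairwise_contrasts needs a fitted group linear model")
    levels = fit.level_terms.get("__levels__", [])
    if len(levels) < 2:
        return pd.DataFrame(
            columns=["group_a", "group_b", "estimate", "se", "t", "p_value"]
        )
    res = fit.result
    names = list(fit.terms.index)
    cov = np.asarray(res.cov_params())
    dfree = res.df_resid

    def coef_vector(level):
        v = np.zeros(len(names))
        name = f"group[{level}]"
        if name in names:
            v[names.index(name)] = 1.0
        return v

    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            L = coef_vector(a) - coef_vector(b)
            est = float(L @ fit.terms["beta"].to_numpy())
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), dfree) if np.isfinite(t) else np.nan
            rows.append(
                {"group_a": a, "group_b": b, "estimate": est, "se": se,
                 "t": t, "p_value": p}
            )
    return pd.DataFrame(rows)


def survey_association(
    panel: ProteinPanel,
    surveys: pd.DataFrame,
    cohort: Cohort,
    analyte: str,
    score: str,
    covariates=(),
) -> ModelFit:
    """OLS of log2 protein level on one continuous survey score + covariates."""
    if score not in surveys.columns:
        raise DataError(f"unknown survey score: {score}")
    cols = {"y": panel.values[analyte], "score": surveys[score].astype(float)}
    cols.update(_covariate_columns(cohort, covariates))
    df = _complete_design(cols)
    if len(df) < 10:
        raise DataError(f"fewer than 10 complete rows for {analyte} ~ {score}")
    if np.ptp(df["score"].to_numpy()) == 0:
        raise DataError(f"survey score {score} is constant")
    X, _ = _prepare_X(df, [c for c in cols if c != "y"])
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    return ModelFit(
        formula=f"log2({analyte}) ~ {score} + {list(covariates)}",
        kind="linear",
        terms=_terms_frame(fit.params, fit.bse, fit.pvalues, X.columns),
        n_used=int(fit.nobs),
        log_likelihood=float(fit.llf),
        n_params=X.shape[1] + 1,
        rows=tuple(df.index),
        adjusted_r2=float(fit.rsquared_adj),
        result=fit,
    )


# ---------------------------------------------------------------------------
# logistic / multinomial
# ---------------------------------------------------------------------------

def case_control_logistic(
    panel: ProteinPanel, cohort: Cohort, analyte: str, covariates=()
) -> ModelFit:
    """Maximum-likelihood logistic regression of case status on log2 level.

    Newton iterations with tolerance 1e-8, at most 100 iterations; perfect
    separation is flagged (``converged=False``, NaN coefficients) rather
    than silently reported.
    """
    cols = {"y": cohort.is_case.astype(float), "protein": panel.values[analyte]}
    cols.update(_covariate_columns(cohort, covariates))
    df = _complete_design(cols)
    if df["y"].nunique() < 2:
        raise DataError("both outcome classes must be present")
    X, kept = _prepare_X(df, [c for c in cols if c != "y"])
    formula = f"logit(case) ~ log2({analyte}) + {list(covariates)}"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            fit = sm.Logit(df["y"].to_numpy(), X).fit(
                method="newton", maxiter=MAX_ITER, tol=TOL, disp=False
            )
        converged = bool(fit.mle_retvals.get("converged", True))
    except (PerfectSeparationError, PerfectSeparationWarning, ConvergenceWarning,
            RuntimeWarning, np.linalg.LinAlgError) as exc:
        log.warning("logistic fit failed (%s); flagged non-converged", exc)
        nan_terms = _terms_frame(
            np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan),
            np.full(X.shape[1], np.nan), X.columns,
        )
        return ModelFit(
            formula=formula, kind="logistic", terms=nan_terms,
            n_used=len(df), log_likelihood=float("nan"),
            n_params=X.shape[1], rows=tuple(df.index), converged=False,
        )
    return ModelFit(
        formula=formula,
        kind="logistic",
        terms=_terms_frame(fit.params, fit.bse, fit.pvalues, X.columns),
        n_used=int(fit.nobs),
        log_likelihood=float(fit.llf),
        n_params=X.shape[1],
        rows=tuple(df.index),
        converged=converged,
        result=fit,
    )


def multinomial_subgroups(
    panel: ProteinPanel,
    labels: pd.Series,
    analyte: str,
    cohort: Cohort,
    covariates=(),
    reference: str = "NFhet",
) -> ModelFit:
    """Multinomial logit of subgroup label on log2 level + covariates.

    The reference level's coefficient block is identically zero; empty
    levels are dropped with a warning.  ``level_terms`` maps each
    non-reference level to its coefficient table.
    """
    labels = labels.dropna().astype(str)
    counts = labels.value_counts()
    empty = [lev for lev in counts.index if counts[lev] == 0]
    levels = [lev for lev in counts.index if counts[lev] > 0]
    if empty:
        log.warning("dropping empty subgroup levels: %s", empty)
    if reference not in levels:
        raise DataError(f"reference level {reference!r} absent from labels")
    if len(levels) < 2:
        raise DataError("need at least 2 populated levels")
    order = [reference] + sorted(lev for lev in levels if lev != reference)
    cols = {"protein": panel.values[analyte]}
    cols.update(_covariate_columns(cohort, covariates))
    df = _complete_design(cols)
    df = df.loc[df.index.isin(labels.index)]
    y = pd.Categorical(labels.loc[df.index], categories=order).codes
    X, kept = _prepare_X(df, list(cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X.to_numpy()).fit(
            method="newton", maxiter=MAX_ITER, tol=TOL, disp=False
        )
    converged = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(fit.llf)
    names = list(X.columns)
    level_terms = {reference: _terms_frame(np.zeros(len(names)),
                                           np.zeros(len(names)),
                                           np.ones(len(names)), names)}
    params = np.asarray(fit.params)  # (n_terms, n_levels - 1)
    bse = np.asarray(fit.bse)
    pvals = np.asarray(fit.pvalues)
    for k, lev in enumerate(order[1:]):
        level_terms[lev] = _terms_frame(params[:, k], bse[:, k], pvals[:, k], names)
    combined = pd.concat(
        {lev: t for lev, t in level_terms.items() if lev != reference},
        names=["level", "term"],
    )
    return ModelFit(
        formula=f"mnlogit(group, ref={reference}) ~ log2({analyte}) + {list(covariates)}",
        kind="multinomial",
        terms=combined,
        n_used=len(df),
        log_likelihood=float(fit.llf),
        n_params=len(names) * (len(order) - 1),
        rows=tuple(df.index),
        converged=converged,
        reference=reference,
        level_terms=level_terms,
        result=fit,
    )


def null_multinomial(
    labels: pd.Series, cohort: Cohort, covariates=(), reference: str = "NFhet",
    rows: tuple | None = None,
) -> ModelFit:
    """Covariates-only multinomial model (the reduced model for the LRT)."""
    labels = labels.dropna().astype(str)
    counts = labels.value_counts()
    levels = [lev for lev in counts.index if counts[lev] > 0]
    order = [reference] + sorted(lev for lev in levels if lev != reference)
    cols = _covariate_columns(cohort, covariates)
    cols = cols if cols else {}
    df = pd.DataFrame(cols, index=labels.index) if cols else pd.DataFrame(index=labels.index)
    df = df.dropna()
    if rows is not None:
        df = df.loc[df.index.isin(rows)]
    y = pd.Categorical(labels.loc[df.index], categories=order).codes
    X = sm.add_constant(df.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X.to_numpy()).fit(
            method="newton", maxiter=MAX_ITER, tol=TOL, disp=False
        )
    return ModelFit(
        formula=f"mnlogit(group, ref={reference}) ~ {list(covariates)}",
        kind="multinomial",
        terms=_terms_frame(np.ravel(fit.params), np.ravel(fit.bse),
                           np.ravel(fit.pvalues),
                           [f"b{i}" for i in range(np.asarray(fit.params).size)]),
        n_used=len(df),
        log_likelihood=float(fit.llf),
        n_params=X.shape[1] * (len(order) - 1),
        rows=tuple(df.index),
        reference=reference,
        result=fit,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """-2 (llf_reduced - llf_full) against chi-square(df = parameter diff).

    Requires the reduced model to be nested in the full model and fitted on
    the same rows.
    """
    if set(reduced.rows) != set(full.rows):
        raise DataError("full and reduced models were fitted on different rows")
    if full.kind != reduced.kind:
        raise DataError("models of different kinds are not nested")
    statistic = -2.0 * (reduced.log_likelihood - full.log_likelihood)
    if statistic < -1e-8:
        raise DataError(
            f"reduced model fits better than full (stat={statistic:.3g}); not nested?"
        )
    statistic = statistic if statistic > 0 else 0.0  # avoids -0.0
    df = full.n_params - reduced.n_params
    if df < 0:
        raise DataError("full model has fewer parameters than reduced model")
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return LrtResult(statistic=float(statistic), df=int(df), p_value=p)
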