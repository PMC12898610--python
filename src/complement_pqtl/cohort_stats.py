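"""Demographic comparisons, covariate screening and protein correlations.

Covariate screening fits one simple linear regression per (analyte,
covariate) pair; covariates with a screening p-value below ``alpha`` (or
forced by an override list) form the adjustment set used by every
downstream model for that analyte.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datatypes import ALL_MEASURES, COVARIATES, Cohort, DataError, ProteinPanel

log = logging.getLogger(__name__)


def compare_demographics(cohort: Cohort) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of age and BMI plus sex counts.

    Uses the exact null distribution when both groups have <= 25 subjects
    and the tie-corrected normal approximation otherwise.
    """
    df = cohort.subjects
    cases = df[df["group"] == "case"]
    controls = df[df["group"] == "control"]
    if len(cases) < 2 or len(controls) < 2:
        raise DataError("need at least 2 subjects per group")
    rows = []
    for var in ("age", "bmi"):
        x, y = cases[var].dropna(), controls[var].dropna()
        method = "exact" if (len(x) <= 25 and len(y) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "variable": var,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "method": method,
                "median_case": float(x.median()),
                "median_control": float(y.median()),
            }
        )
    sex_counts = df.groupby(["group", "sex"]).size()
    for (grp, sex), count in sex_counts.items():
        rows.append(
            {
                "variable": f"sex_{sex}_{grp}",
                "statistic": float(count),
                "p_value": np.nan,
                "method": "count",
                "median_case": np.nan,
                "median_control": np.nan,
            }
        )
    return pd.DataFrame(rows)


def screen_covariates(
    panel: ProteinPanel,
    cohort: Cohort,
    alpha: float = 0.05,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Bivariate association of each analyte with age, sex (male=1) and BMI.

    Returns one row per (analyte, covariate) with the slope, its SE,
    adjusted R^2, the model F statistic and p-value, and a ``selected``
    flag (p < alpha, or forced through ``overrides``: analyte -> list of
    covariates to include regardless of p).
    """
    overrides = overrides or {}
    covs = cohort.covariate_frame()
    rows = []
    for analyte in ALL_MEASURES:
        y_all = panel.values[analyte]
        for cov in COVARIATES:
            x_all = covs[cov]
            mask = y_all.notna() & x_all.notna()
            y, x = y_all[mask].to_numpy(), x_all[mask].to_numpy()
            if len(y) < 10:
                raise DataError(
                    f"fewer than 10 complete rows for {analyte} ~ {cov}"
                )
            if np.ptp(x) == 0:
                log.warning("covariate %s constant; skipping %s ~ %s", cov, analyte, cov)
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            p = float(fit.pvalues[1])
            forced = cov in overrides.get(analyte, ())
            rows.append(
                {
                    "analyte": analyte,
                    "covariate": cov,
                    "coefficient": float(fit.params[1]),
                    "std_error": float(fit.bse[1]),
                    "adjusted_r2": float(fit.rsquared_adj),
                    "f_statistic": float(fit.fvalue),
                    "p_value": p,
                    "selected": bool(p < alpha or forced),
                }
            )
    return pd.DataFrame(rows)


def selected_covariates(screen: pd.DataFrame) -> dict:
    """Adjustment sets per analyte from a screening table."""
    out: dict[str, list[str]] = {a: [] for a in screen["analyte"].unique()}
    for row in screen.itertuples():
        if row.selected:
            out[row.analyte].append(row.covariate)
    return out


def protein_correlations(panel: ProteinPanel, min_pairs: int = 3):
    """Pairwise Pearson correlations of log2 analyte levels.

    Returns (r, p) DataFrames; p-values come from the t transform of r.
    Cells with fewer than ``min_pairs`` complete pairs or a zero-variance
    analyte are NaN.
    """
    cols = list(ALL_MEASURES)
    vals = panel.values[cols]
    m = len(cols)
    r_mat = np.full((m, m), np.nan)
    p_mat = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            pair = vals.iloc[:, [i, j]].dropna()
            n = len(pair)
            if n < min_pairs:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                log.warning(
                    "zero variance for %s or %s; correlation undefined",
                    cols[i], cols[j],
                )
                continue
            if i == j:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(x, y)
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
    r_df = pd.DataFrame(r_mat, index=cols, columns=cols)
    p_df = pd.DataFrame(p_mat, index=cols, columns=cols)
    return r_df, p_df
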