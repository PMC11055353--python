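"""Blood-pressure regressions on sitting-pattern summaries.

Two families of multiple linear regressions are fit per outcome (SBP, DBP):
one entering the two subject-level PC scores jointly, one entering the two
POPAI summaries (average daily inactive and active sitting minutes) jointly,
both controlling for age, race, education, employment, BMI, hypertension
status, number of valid concurrent wear days and average daily non-sitting
time.  Focal predictors are also standardized and the models refit — a
linear reparameterization, so p-values are unchanged — and the eight focal
p-values are adjusted with the Benjamini–Hochberg step-up FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COVARIATES",
    "AssociationResult",
    "bh_fdr",
    "fit_mlr",
    "standardize_refit",
    "run_association",
]

DEFAULT_COVARIATES = (
    "age",
    "race_white",
    "education_college",
    "employed",
    "bmi",
    "hypertension",
    "n_valid_days",
    "nonsitting_min",
)

_COND_LIMIT = 1e10


@dataclass
class AssociationResult:
    """One focal predictor's row of the regression table."""

    outcome: str
    predictor: str
    beta: float
    se: float
    beta_standardized: float
    se_standardized: float
    p_raw: float
    p_fdr: float
    n_used: int
    covariates: tuple[str, ...]


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, bounded by 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    X = sm.add_constant(df[list(cols)].astype(float), has_constant="add")
    cond = np.linalg.cond(X.to_numpy())
    if cond > _COND_LIMIT:
        raise ValueError(
            f"collinear design (condition number {cond:.2e}); columns: {list(X.columns)}"
        )
    return X


def fit_mlr(
    data: pd.DataFrame,
    outcome: str,
    focal: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """OLS of one outcome on the focal predictors (jointly) plus covariates.

    Complete-case analysis: rows with any missing value among the used
    columns are dropped.  Returns one row per focal predictor with the raw
    and standardized coefficients, their standard errors and the two-sided
    t-based p-value (identical between the two parameterizations).
    """
    cols = [outcome, *focal, *covariates]
    cc = data[cols].dropna()
    n_dropped = len(data) - len(cc)
    X = _design(cc, [*focal, *covariates])
    fit = sm.OLS(cc[outcome], X).fit()
    std = standardize_refit(cc, outcome, focal, covariates)
    rows = []
    for name in focal:
        if not np.isclose(fit.pvalues[name], std.loc[name, "p"], atol=1e-10):
            raise AssertionError("standardization changed a p-value")
        rows.append(
            {
                "outcome": outcome,
                "predictor": name,
                "beta": fit.params[name],
                "se": fit.bse[name],
                "beta_standardized": std.loc[name, "beta"],
                "se_standardized": std.loc[name, "se"],
                "p_raw": fit.pvalues[name],
                "n_used": int(fit.nobs),
                "n_dropped_missing": n_dropped,
            }
        )
    return pd.DataFrame(rows)


def standardize_refit(
    data: pd.DataFrame,
    outcome: str,
    focal: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Refit with z-scored focal predictors (covariates untouched).

    Standardization uses the analysis sample's mean and standard deviation
    (ddof=1).  Returns a frame indexed by focal predictor with the
    standardized beta, its standard error and the (unchanged) p-value.
    """
    cc = data[[outcome, *focal, *covariates]].dropna().copy()
    for name in focal:
        sd = cc[name].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"focal predictor {name!r} has zero variance")
        cc[name] = (cc[name] - cc[name].mean()) / sd
    X = _design(cc, [*focal, *covariates])
    fit = sm.OLS(cc[outcome], X).fit()
    return pd.DataFrame(
        {"beta": fit.params[list(focal)], "se": fit.bse[list(focal)], "p": fit.pvalues[list(focal)]}
    )


def run_association(
    scores: pd.DataFrame,
    popai: pd.DataFrame,
    pheno: pd.DataFrame,
    outcomes: Sequence[str] = ("sbp", "dbp"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """The full 8-comparison regression table with BH-FDR adjustment.

    ``scores`` holds participant-level PC scores (columns ``participant``,
    ``pc1``, ``pc2``); ``popai`` the daily summaries (``inactive_min``,
    ``active_min``); ``pheno`` outcomes plus covariates.  Focal p-values from
    all outcome x predictor-set combinations form one FDR family.  For the
    POPAI per-minute coefficients a per-hour rescaling (beta x 60) is
    reported as a convenience column.
    """
    scores = scores.rename(columns={"inactive_min": "popai_inactive", "active_min": "popai_active"})
    popai = popai.rename(columns={"inactive_min": "popai_inactive", "active_min": "popai_active"})
    data = pheno.merge(scores, on="participant").merge(
        popai[["participant", "popai_inactive", "popai_active"]], on="participant"
    )
    families = {
        "mfpca": [c for c in scores.columns if c.startswith("pc")],
        "popai": ["popai_inactive", "popai_active"],
    }
    tables = []
    for outcome in outcomes:
        for focal in families.values():
            tables.append(fit_mlr(data, outcome, focal, covariates))
    table = pd.concat(tables, ignore_index=True)
    table["p_fdr"] = bh_fdr(table["p_raw"].to_numpy())
    table["beta_per_hour"] = np.where(
        table["predictor"].str.startswith("popai_"), table["beta"] * 60.0, np.nan
    )
    table["covariates"] = [tuple(covariates)] * len(table)
    return table
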