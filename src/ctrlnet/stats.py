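"""Cohort-level inference: covariate construction, two-level repeated
measures contrasts, and covariate-adjusted regressions.

The two-level within-subject contrast is realized as an ANCOVA on
per-subject difference scores, which is numerically exact for two levels
and needs no sphericity machinery. All tests are two-sided; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synth import CohortTable

log = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "build_covariates",
    "rm_anova_2level",
    "covariate_regression",
]

_COND_THRESHOLD = 1e10


@dataclass(frozen=True)
class StatResult:
    """One inferential result row.

    ``statistic`` is an F for ANOVA-style contrasts and a t for
    regressions; ``df`` is the (numerator, denominator) pair;
    ``coefficient`` is the standardized slope for regressions (the raw
    difference-model coefficient for ANOVA terms).
    """

    effect_name: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    coefficient: float
    n_used: int
    covariates_applied: tuple[str, ...]


def build_covariates(cohort: CohortTable, states: dict | None = None) -> pd.DataFrame:
    """Augment the cohort table with activity covariates.

    Adds ``mean_activity_0`` / ``mean_activity_2`` (region-wise mean of
    each state vector) and ``activity_difference`` (their absolute
    difference), recomputed from the state vectors.
    """
    states = states if states is not None else cohort.states
    table = cohort.table.copy()
    m0, m2 = [], []
    for sid in table["subject_id"]:
        if sid not in states:
            raise KeyError(f"missing states for subject {sid}")
        pair = states[sid]
        m0.append(float(np.mean(pair.state_0back)))
        m2.append(float(np.mean(pair.state_2back)))
    table["mean_activity_0"] = m0
    table["mean_activity_2"] = m2
    table["activity_difference"] = np.abs(table["mean_activity_0"] - table["mean_activity_2"])
    return table


def _complete_cases(table: pd.DataFrame, cols: list[str], context: str) -> pd.DataFrame:
    sub = table[cols]
    mask = sub.notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        log.info("%s: %d rows dropped listwise for missing data", context, dropped)
    return table.loc[mask]


def _design(table: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept plus mean-centered covariate columns."""
    X = [np.ones(len(table))]
    for c in covariates:
        col = table[c].to_numpy(dtype=float)
        X.append(col - col.mean())
    return np.column_stack(X)


def _term_f(fit, idx: int, name: str, n_used: int, covs: tuple[str, ...]) -> StatResult:
    t = float(fit.tvalues[idx])
    df2 = float(fit.df_resid)
    F = t * t
    p = float(sps.f.sf(F, 1, df2))
    return StatResult(
        effect_name=name, statistic=F, df=(1.0, df2), p_value=p,
        coefficient=float(fit.params[idx]), n_used=n_used, covariates_applied=covs,
    )


def rm_anova_2level(
    table: pd.DataFrame,
    outcome_pair: tuple[str, str],
    between: str | None = None,
    covariates: tuple[str, ...] = (),
) -> dict[str, StatResult]:
    """Two-level repeated-measures contrast via difference-score ANCOVA.

    Returns a dict with key ``"condition"`` (the within-subject effect,
    F(1, df2)). With ``between`` set, also ``"condition_by_group"`` (the
    group term of the difference model) and ``"group"`` (the group main
    effect on the per-subject means). Covariates are mean-centered so the
    intercept estimates the condition effect at average covariate values.
    """
    covariates = tuple(covariates)
    col_a, col_b = outcome_pair
    needed = [col_a, col_b, *covariates] + ([between] if between else [])
    data = _complete_cases(table, needed, "rm_anova_2level")
    n_used = len(data)
    diff = data[col_b].to_numpy(dtype=float) - data[col_a].to_numpy(dtype=float)
    mean = (data[col_b].to_numpy(dtype=float) + data[col_a].to_numpy(dtype=float)) / 2.0

    results: dict[str, StatResult] = {}
    if np.allclose(diff, 0.0, atol=1e-300, rtol=0.0):
        # identical outcome columns: exact null by convention
        results["condition"] = StatResult(
            effect_name=f"condition[{col_a} vs {col_b}]",
            statistic=0.0, df=(1.0, float(max(n_used - 1 - len(covariates), 0))),
            p_value=1.0, coefficient=0.0, n_used=n_used,
            covariates_applied=covariates,
        )
        return results

    X = _design(data, covariates)
    if between is not None:
        g = data[between]
        codes = pd.Categorical(g).codes.astype(float)
        codes = codes - codes.mean()  # centered effect coding
        X = np.column_stack([X, codes])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design in rm_anova_2level")
    if n_used <= X.shape[1]:
        raise ValueError(
            f"too few complete cases (n={n_used}) for {X.shape[1]} parameters"
        )

    fit_diff = sm.OLS(diff, X).fit()
    results["condition"] = _term_f(
        fit_diff, 0, f"condition[{col_a} vs {col_b}]", n_used, covariates
    )
    if between is not None:
        results["condition_by_group"] = _term_f(
            fit_diff, X.shape[1] - 1,
            f"condition_x_{between}[{col_a} vs {col_b}]", n_used, covariates,
        )
        fit_mean = sm.OLS(mean, X).fit()
        results["group"] = _term_f(
            fit_mean, X.shape[1] - 1,
            f"{between}[mean of {col_a},{col_b}]", n_used, covariates,
        )
    return results


def covariate_regression(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
) -> StatResult:
    """OLS of a standardized outcome on a standardized predictor + covariates.

    Returns the standardized coefficient of the predictor with its
    two-sided t test. The predictor may be a categorical/group column, in
    which case it is dummy-coded before standardization.
    """
    covariates = tuple(covariates)
    needed = [outcome, predictor, *covariates]
    data = _complete_cases(table, needed, "covariate_regression")
    n_used = len(data)
    if n_used < len(covariates) + 3:
        raise ValueError(
            f"too few complete cases ({n_used}) for {len(covariates)} covariates"
        )
    y = data[outcome].to_numpy(dtype=float)
    pred = data[predictor]
    if not pd.api.types.is_numeric_dtype(pred):
        pred = pd.Categorical(pred).codes
    x = np.asarray(pred, dtype=float)
    if y.std(ddof=0) == 0 or x.std(ddof=0) == 0:
        raise ValueError("outcome or predictor has zero variance")
    yz = (y - y.mean()) / y.std(ddof=0)
    xz = (x - x.mean()) / x.std(ddof=0)
    X = np.column_stack([_design(data, covariates), xz])
    cond = float(np.linalg.cond(X))
    if cond > _COND_THRESHOLD:
        log.warning(
            "collinear design in covariate_regression(%s ~ %s): cond=%.3e",
            outcome, predictor, cond,
        )
    fit = sm.OLS(yz, X).fit()
    idx = X.shape[1] - 1
    t = float(fit.tvalues[idx])
    p = float(fit.pvalues[idx])
    return StatResult(
        effect_name=f"{outcome}~{predictor}",
        statistic=t,
        df=(1.0, float(fit.df_resid)),
        p_value=p,
        coefficient=float(fit.params[idx]),
        n_used=n_used,
        covariates_applied=covariates,
    )
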