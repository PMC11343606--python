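"""Cohort-level statistics: multivariate OLS and survival stratification.

A marker (expression or positivity) is regressed on clinical covariates by
ordinary least squares with per-term confidence intervals, and cohorts are
dichotomized on the mean expression of a gene set (the metagene) for
Kaplan-Meier / log-rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import InputError, ZeroEventsError

__all__ = [
    "multivariate_ols",
    "km_logrank",
    "stratify_by_metagene",
    "KMResult",
    "MetageneStrata",
]

STRATUM_HIGH = "high"
STRATUM_LOW = "low"


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categoricals against the alphabetically first level."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            parts.append(s.astype(float))
        else:
            levels = sorted(map(str, s.unique()))
            dummies = pd.get_dummies(s.astype(str), prefix=col, dtype=float)
            dummies = dummies[[f"{col}_{lv}" for lv in levels]]
            parts.append(dummies.iloc[:, 1:])  # drop first level as reference
    design = pd.concat(parts, axis=1)
    return sm.add_constant(design, has_constant="add")


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols, kept = [], []
    x = design.to_numpy(dtype=float)
    rank = 0
    for j, name in enumerate(design.columns):
        cand = x[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept.append(j)
            rank = r
        else:
            cols.append(name)
    return cols


def multivariate_ols(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """OLS of ``response`` on all other columns of ``table``.

    Categorical covariates are dummy-coded against the alphabetically
    first level. Returns one row per term with ``coef``, ``ci_low``,
    ``ci_high`` (t-based 95%), and two-sided ``p``.
    """
    if response not in table.columns:
        raise InputError(f"response column '{response}' not in table")
    if table.isna().any().any():
        bad = [c for c in table.columns if table[c].isna().any()]
        raise InputError(f"missing cells in column(s): {', '.join(bad)}")
    y = table[response].astype(float)
    design = _design_matrix(table.drop(columns=[response]))
    n, p = design.shape
    if n <= p:
        raise InputError(f"need more samples ({n}) than coefficients ({p})")
    if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < p:
        raise InputError(
            "rank-deficient design; collinear column(s): "
            + ", ".join(_collinear_columns(design))
        )
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    out.index.name = "term"
    return out


@dataclass(frozen=True)
class KMResult:
    """Per-stratum product-limit curves plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]
    statistic: float
    p: float


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    # Greenwood variance for reporting only.
    with np.errstate(divide="ignore", invalid="ignore"):
        term = table["observed"] / (
            table["at_risk"] * (table["at_risk"] - table["observed"])
        )
    greenwood = surv.to_numpy() ** 2 * np.cumsum(np.nan_to_num(term))
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
            "greenwood_se": np.sqrt(greenwood),
        }
    ).reset_index(drop=True)


def km_logrank(table: pd.DataFrame) -> KMResult:
    """Kaplan-Meier curves per stratum and the two-group log-rank test.

    ``table`` needs columns ``time`` (positive), ``event`` (bool/0-1) and
    ``stratum`` with exactly two non-empty levels. With zero events the
    curves are still computed but the test is an error (raised with the
    curves attached).
    """
    for col in ("time", "event", "stratum"):
        if col not in table.columns:
            raise InputError(f"survival table missing column '{col}'")
    time = table["time"].to_numpy(dtype=float)
    if (time <= 0).any() or not np.all(np.isfinite(time)):
        raise InputError("survival times must be positive and finite")
    event = table["event"].astype(bool).to_numpy()
    strata = table["stratum"].astype(str)
    levels = sorted(strata.unique())
    if len(levels) != 2:
        raise InputError(f"expected exactly 2 strata, got {levels}")

    curves = {
        lv: _km_curve(time[strata == lv], event[(strata == lv).to_numpy()])
        for lv in levels
    }
    if event.sum() == 0:
        raise ZeroEventsError("no events observed; log-rank undefined", curves=curves)

    a, b = levels
    res = logrank_test(
        time[strata == a],
        time[strata == b],
        event_observed_A=event[(strata == a).to_numpy()],
        event_observed_B=event[(strata == b).to_numpy()],
    )
    return KMResult(
        curves=curves, statistic=float(res.test_statistic), p=float(res.p_value)
    )


@dataclass(frozen=True)
class MetageneStrata:
    """Median dichotomization of per-sample mean signature expression."""

    stratum: pd.Series
    metagene: pd.Series
    missing_genes: tuple[str, ...] = ()


def stratify_by_metagene(matrix: pd.DataFrame, signature) -> MetageneStrata:
    """High/low split on mean signature expression per sample.

    The metagene is the mean expression over the signature genes present
    in the matrix; a sample is ``high`` when its metagene exceeds the
    cohort median, otherwise ``low`` (ties go low). Missing signature
    genes are reported, never silently dropped.
    """
    signature = list(dict.fromkeys(signature))
    present = [g for g in signature if g in matrix.index]
    missing = tuple(g for g in signature if g not in matrix.index)
    if not present:
        raise InputError("no signature gene is present in the matrix")
    metagene = matrix.loc[present].mean(axis=0)
    cut = metagene.median()
    stratum = pd.Series(
        np.where(metagene > cut, STRATUM_HIGH, STRATUM_LOW),
        index=metagene.index,
        name="stratum",
    )
    return MetageneStrata(stratum=stratum, metagene=metagene, missing_genes=missing)
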