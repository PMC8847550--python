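"""Validation statistics for virtual-vs-physical rigidity comparisons.

Covers the agreement battery used to validate virtual mechanical tests:
RMSE, Pearson correlation with strong/moderate strength classification, the
absolute-agreement criterion (RMSE strictly below the standard deviation of
the datum set), descriptive statistics, and one-way repeated-measures ANOVA
with Bonferroni-adjusted pairwise post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "rmse",
    "pearson",
    "classify_strength",
    "agreement_report",
    "rm_anova_bonferroni",
    "describe",
    "SIGNIFICANCE_LIMIT",
]

SIGNIFICANCE_LIMIT = 0.05


@dataclass(frozen=True)
class AgreementReport:
    """Absolute + relative agreement between paired rigidity measures."""

    rmse: float
    datum_sd: float
    passes: bool  # rmse strictly below the datum-set SD
    r: float
    r_squared: float
    p_value: float
    strength: str  # "strong" | "moderate" | "weak"


def rmse(x, y) -> float:
    """Root-mean-square error between paired arrays."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("rmse requires equal-length, non-empty inputs")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson's r, r**2 and the two-sided p-value from the t distribution."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson requires >= 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.statistic**2), float(res.pvalue)


def classify_strength(r: float) -> str:
    """Correlation strength: strong (r >= 0.8), moderate (r >= 0.6), else weak."""
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if r >= 0.8:
        return "strong"
    if r >= 0.6:
        return "moderate"
    return "weak"


def describe(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("sample standard deviation requires n >= 2")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def agreement_report(predicted, measured) -> AgreementReport:
    """Full agreement battery; the datum SD is taken from the measured set."""
    err = rmse(predicted, measured)
    _, sd = describe(measured)
    r, r2, p = pearson(predicted, measured)
    return AgreementReport(
        rmse=err,
        datum_sd=sd,
        passes=err < sd,
        r=r,
        r_squared=r2,
        p_value=p,
        strength=classify_strength(r),
    )


def rm_anova_bonferroni(table) -> dict:
    """One-way repeated-measures ANOVA plus Bonferroni-adjusted paired t-tests.

    ``table`` is a complete subjects x conditions array or DataFrame (e.g.
    measured GJ alongside the VTR of each candidate material model). The
    within-subject decomposition SS_total = SS_conditions + SS_subjects +
    SS_error gives F = MS_conditions / MS_error with (k-1, (k-1)(n-1))
    degrees of freedom; no sphericity correction is applied. Pairwise
    paired-t p-values are multiplied by the number of comparisons and
    capped at 1.
    """
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        data = table.to_numpy(dtype=np.float64)
    else:
        data = np.asarray(table, dtype=np.float64)
        names = [f"cond{i}" for i in range(data.shape[1])]
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 3:
        raise ValueError("need a 2D table with >= 3 subjects and >= 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("table has missing cells")
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat, p = (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            t_res = sps.ttest_rel(data[:, i], data[:, j])
            pairwise.append(
                {
                    "pair": (names[i], names[j]),
                    "t": float(t_res.statistic),
                    "p_raw": float(t_res.pvalue),
                    "p_adjusted": float(min(1.0, t_res.pvalue * n_pairs)),
                }
            )
    return {
        "F": float(f_stat),
        "p": p,
        "df": (df_cond, df_err),
        "ss": {"conditions": float(ss_cond), "subjects": float(ss_subj), "error": float(ss_err)},
        "pairwise": pairwise,
    }
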