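"""Classical-statistics confirmation of forest findings.

Prime implicants flagged by the forest are re-examined one at a time with
univariate logistic regression: the conjunction is turned into a 0/1
indicator and its odds ratio (with Wald 95% CI and p-value) estimated
against the complement as reference.  For a binary indicator the logistic
MLE odds ratio equals the 2x2 cross-product ratio.  Group-comparison
helpers (Yates-corrected chi-square for 2x2 tables, two-sample t-test from
summary statistics) support cohort description tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import Dataset
from .logic_tree import PrimeImplicant

logger = logging.getLogger(__name__)


@dataclass
class ConfirmationRecord:
    effect: str
    n_cases_with: int
    n_cases_without: int
    n_controls_with: int
    n_controls_without: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "logistic-Wald"


def pi_indicator(W: Dataset, pi: PrimeImplicant) -> np.ndarray:
    """0/1 per subject: does the subject satisfy the conjunction?"""
    for j in pi.predictor_indices:
        if j >= W.p:
            raise IndexError(f"prime implicant references predictor {j} outside the dataset")
    return pi.indicator(W.X)


def fit_logistic_univariate(y: np.ndarray, indicator: np.ndarray, effect: str = "") -> ConfirmationRecord:
    """Single-predictor logistic regression of case status on a 0/1 indicator.

    Returns the exponentiated coefficient (odds ratio), Wald 95% CI and
    Wald p-value.  Errors out on separation / empty 2x2 cells, where the
    Wald machinery is meaningless and an exact or penalised method should
    be used instead.
    """
    y = np.asarray(y, dtype=int)
    x = np.asarray(indicator, dtype=int)
    if x.min() == x.max():
        raise ValueError("indicator is constant; odds ratio undefined")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    a = int(((y == 1) & (x == 1)).sum())  # cases with
    b = int(((y == 1) & (x == 0)).sum())  # cases without
    c = int(((y == 0) & (x == 1)).sum())  # controls with
    d = int(((y == 0) & (x == 0)).sum())  # controls without
    if min(a, b, c, d) == 0:
        raise ValueError(
            "a 2x2 cell is empty (separation); use an exact or penalised logistic method"
        )
    model = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=0)
    coef = model.params[1]
    lo, hi = model.conf_int()[1]
    return ConfirmationRecord(
        effect=effect,
        n_cases_with=a, n_cases_without=b,
        n_controls_with=c, n_controls_without=d,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=float(model.pvalues[1]),
    )


def odds_ratio_from_counts(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio ad/(bc) for a 2x2 table (exposed-case a, etc.)."""
    if min(a, b, c, d) < 0 or b * c == 0:
        raise ValueError("counts must be non-negative with non-zero off-diagonal product")
    return (a * d) / (b * c)


def chi_square_2x2(table, continuity_correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default; 1 df.

    Returns (statistic, p).  Errors out when a margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins of the 2x2 table must be positive")
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(stat), float(p)


def t_test_from_summaries(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    pooled: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; pooled variance by default.

    Returns (statistic, df, two-sided p).  ``pooled=False`` gives Welch.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled)
    if pooled:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def confirm_prime_implicants(
    W: Dataset,
    pis: list[PrimeImplicant],
) -> list[ConfirmationRecord]:
    """Table of univariate logistic confirmations, one model per prime implicant."""
    records = []
    for pi in pis:
        ind = pi_indicator(W, pi)
        try:
            rec = fit_logistic_univariate(W.y, ind, effect=pi.render(W.descriptors))
        except ValueError as e:
            logger.warning("skipping confirmation for %s: %s", pi.render(W.descriptors), e)
            continue
        records.append(rec)
    return records


def confirmation_frame(records: list[ConfirmationRecord]):
    import pandas as pd

    return pd.DataFrame.from_records(
        [
            dict(
                effect=r.effect,
                cases_with=r.n_cases_with,
                cases_without=r.n_cases_without,
                controls_with=r.n_controls_with,
                controls_without=r.n_controls_without,
                odds_ratio=r.odds_ratio,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                p_value=r.p_value,
                method=r.method,
            )
            for r in records
        ]
    )
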