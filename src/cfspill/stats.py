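"""Population-level statistics: condition summaries (mean ± SEM), ordinary
least-squares regressions with R², and paired/unpaired group comparisons with
Bonferroni-corrected ANOVA follow-ups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "PopulationSummary",
    "linear_regression",
    "summarize",
    "compare_conditions",
    "compare_many",
    "bonferroni",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class PopulationSummary:
    condition: str
    metric: str
    mean: float
    sem: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R² = 1 - SSres/SStot and a
    two-sided test of zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def summarize(values, condition: str = "", metric: str = "") -> PopulationSummary:
    """Mean, SEM (= SD/sqrt(n), 0 for a single value) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return PopulationSummary(condition, metric, float(np.mean(v)), sem, int(v.size))


def compare_conditions(
    a, b, paired: bool = False, equal_var: bool = True
) -> tuple[float, float, str]:
    """Two-tailed Student's t-test between two groups.

    ``paired=True`` runs a paired test (equal lengths required); otherwise an
    unpaired test, pooled-variance by default (``equal_var=False`` for Welch).
    Returns ``(statistic, p_value, test_label)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        res = sps.ttest_rel(a, b)
        label = "paired t-test"
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        label = "unpaired t-test" if equal_var else "Welch t-test"
    return float(res.statistic), float(res.pvalue), label


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p_raw)


def compare_many(groups, labels=None) -> dict:
    """One-way ANOVA over >2 groups followed by all pairwise unpaired t-tests
    with Bonferroni adjustment."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_many needs >2 groups (use compare_conditions)")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    f_stat, p_anova = sps.f_oneway(*groups)
    pairs = []
    m = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p, _ = compare_conditions(groups[i], groups[j])
            pairs.append(
                {
                    "pair": (labels[i], labels[j]),
                    "t": t,
                    "p_raw": p,
                    "p_bonferroni": bonferroni(p, m),
                }
            )
    return {
        "test": "one-way ANOVA + Bonferroni pairwise",
        "F": float(f_stat),
        "p": float(p_anova),
        "pairwise": pairs,
    }
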