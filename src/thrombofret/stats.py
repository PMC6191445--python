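"""Group comparisons used in platelet thrombosis experiments.

Two-sample comparisons use Student's t-test, switching to Welch's t-test
when an F-test of variance equality rejects at alpha = 0.05 (``mode="auto"``,
the criterion is recorded in the result).  Bleeding times, censored at the
assay's stopping cap, are compared with the Mann-Whitney U test treating
capped observations as ties at the cap (midranks) — exact enumeration for
small samples without ties, tie-corrected normal approximation otherwise.
Multi-group comparisons run one-way ANOVA followed by Tukey's HSD.
An inclusion filter implements the normal platelet-count range
(800-1300 x 10^6 / mL, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatResult",
    "two_sample_test",
    "mann_whitney",
    "anova_tukey",
    "inclusion_filter",
    "p_to_stars",
]

PLATELET_RANGE = (800.0, 1300.0)  # x10^6 per mL, inclusive


@dataclass
class StatResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    n: dict[str, int]
    notes: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def stars(self) -> str:
        return p_to_stars(self.p_value)


def p_to_stars(p: float) -> str:
    """Significance stars: * <0.05, ** <0.01, *** <0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    cdf = sps.f.cdf(f, len(a) - 1, len(b) - 1)
    return 2.0 * min(cdf, 1.0 - cdf)


def two_sample_test(a, b, mode: str = "auto") -> StatResult:
    """Student or Welch two-sample t-test (two-sided).

    ``mode="auto"`` selects Welch when the F-test of equal variances
    rejects at alpha = 0.05; the selection and its criterion are recorded
    in the result notes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if mode not in ("student", "welch", "auto"):
        raise ValueError("mode must be 'student', 'welch' or 'auto'")
    notes = []
    if mode == "auto":
        p_var = _variance_f_test(a, b)
        equal_var = p_var >= 0.05
        notes.append(
            f"auto mode: F-test of equal variances p={p_var:.4g} -> "
            f"{'Student' if equal_var else 'Welch'}"
        )
    else:
        equal_var = mode == "student"
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        notes.append("zero variance in both groups with equal means; p set to 1")
        return StatResult(
            test_name="student_t" if equal_var else "welch_t",
            statistic=0.0, p_value=1.0, n={"a": len(a), "b": len(b)}, notes=notes,
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(
        test_name="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n={"a": len(a), "b": len(b)},
        notes=notes,
    )


def mann_whitney(a, b, cap: float | None = None) -> StatResult:
    """Mann-Whitney U test (two-sided) with optional censoring cap.

    Observations stopped at ``cap`` (e.g. a bleeding assay terminated at
    15 min) stay in the sample as ties at the cap, handled by midranks.
    The p-value is exact by enumeration when n_a + n_b <= 12 and there are
    no ties, otherwise a tie-corrected normal approximation (method noted).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    notes = []
    if cap is not None:
        if cap < max(a.max(), b.max()):
            raise ValueError("cap below the largest observed value")
        n_cap = int((a == cap).sum() + (b == cap).sum())
        if n_cap:
            notes.append(f"{n_cap} censored observation(s) kept as ties at cap {cap:g}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) + len(b) <= 12
    if small and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    notes.append(f"p-value method: {method}" + (", tie-corrected" if has_ties else ""))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n={"a": len(a), "b": len(b)},
        notes=notes,
        details={"U": float(res.statistic)},
    )


def anova_tukey(groups, labels: list[str] | None = None) -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons (>= 3 groups).

    Returns the F statistic and p-value plus a pairwise table (group pair,
    mean difference, adjusted p, significance stars) in ``details``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use two_sample_test instead")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    f_res = sps.f_oneway(*groups)
    values = np.concatenate(groups)
    group_ids = np.concatenate(
        [np.full(len(g), lab, dtype=object) for g, lab in zip(groups, labels)]
    )
    tukey = pairwise_tukeyhsd(values, group_ids, alpha=0.05)
    pairs = list(combinations(tukey.groupsunique, 2))
    table = pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "mean_diff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "stars": [p_to_stars(p) for p in tukey.pvalues],
        }
    )
    return StatResult(
        test_name="anova_oneway",
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        n={lab: len(g) for lab, g in zip(labels, groups)},
        notes=["post hoc: Tukey HSD at alpha=0.05"],
        details={"tukey": table},
    )


def inclusion_filter(platelet_counts, low: float = PLATELET_RANGE[0],
                     high: float = PLATELET_RANGE[1]) -> np.ndarray:
    """Keep animals with platelet counts in the normal range (inclusive)."""
    counts = np.asarray(platelet_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("platelet counts must be >= 0")
    return (counts >= low) & (counts <= high)
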