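"""Group-comparison statistics used in the study reports.

Two-group means by independent t-test (pooled or Welch, with Levene's
test deciding in auto mode), multi-group means by one-way ANOVA, ordinal
toxicity grades by Kruskal–Wallis, survival by log-rank (in
:mod:`alphachain.efficacy`).  α is fixed at 0.05, two-sided, and no
multiple-testing correction is applied by default (Holm is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "two_group_test",
    "two_group_test_from_stats",
    "multi_group_test",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one statistical comparison."""

    endpoint: str
    groups: tuple[str, ...]
    test: str                     # t-pooled / t-welch / anova / kruskal-wallis / logrank
    statistic: float
    p: float
    levene_p: float = math.nan
    alpha: float = ALPHA
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _degenerate(a: np.ndarray, b: np.ndarray) -> GroupComparison | None:
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        equal = a.mean() == b.mean()
        return GroupComparison(
            "", ("A", "B"), "t-pooled",
            0.0 if equal else math.inf, 1.0 if equal else 0.0,
            notes="degenerate: zero variance in both groups",
        )
    return None


def two_group_test(values_a, values_b, mode: str = "auto",
                   endpoint: str = "", groups: tuple[str, str] = ("A", "B"),
                   levene_center: str = "mean") -> GroupComparison:
    """Independent two-sample t-test of group means.

    ``mode='auto'`` runs Levene's variance-homogeneity test first and uses
    the pooled t-test when its p ≥ 0.05, Welch's otherwise; the chosen
    variant is recorded in the result, never switched silently.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if mode not in ("auto", "pooled", "welch"):
        raise ValueError("mode must be auto, pooled, or welch")

    deg = _degenerate(a, b)
    if deg is not None:
        deg.endpoint, deg.groups = endpoint, tuple(groups)
        return deg

    levene_p = math.nan
    if mode == "auto":
        levene_p = float(sps.levene(a, b, center=levene_center).pvalue)
        chosen = "pooled" if levene_p >= ALPHA else "welch"
    else:
        chosen = mode
    res = sps.ttest_ind(a, b, equal_var=(chosen == "pooled"))
    return GroupComparison(
        endpoint, tuple(groups), f"t-{chosen}",
        float(res.statistic), float(res.pvalue), levene_p,
    )


def two_group_test_from_stats(mean_a: float, sd_a: float, n_a: int,
                              mean_b: float, sd_b: float, n_b: int,
                              mode: str = "pooled", endpoint: str = "",
                              groups: tuple[str, str] = ("A", "B")) -> GroupComparison:
    """t-test from published summary statistics (mean ± SD, n)."""
    if mode not in ("pooled", "welch"):
        raise ValueError("summary-statistic mode must be pooled or welch")
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=(mode == "pooled"))
    return GroupComparison(endpoint, tuple(groups), f"t-{mode}",
                           float(res.statistic), float(res.pvalue))


def multi_group_test(groups_values, mode: str = "anova", endpoint: str = "",
                     group_names: tuple[str, ...] | None = None) -> GroupComparison:
    """One-way ANOVA (F) or Kruskal–Wallis (H, mid-rank ties correction).

    All-identical observations yield the H = 0, p = 1 convention instead
    of an error.
    """
    arrays = [np.asarray(g, float) for g in groups_values]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if mode not in ("anova", "kruskal"):
        raise ValueError("mode must be anova or kruskal")
    names = tuple(group_names) if group_names else tuple(
        f"G{i + 1}" for i in range(len(arrays)))
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(endpoint, names,
                               "anova" if mode == "anova" else "kruskal-wallis",
                               0.0, 1.0, notes="degenerate: all values identical")
    if mode == "anova":
        for g in arrays:
            if len(g) < 2:
                raise ValueError("ANOVA needs at least two observations per group")
        res = sps.f_oneway(*arrays)
        return GroupComparison(endpoint, names, "anova",
                               float(res.statistic), float(res.pvalue))
    res = sps.kruskal(*arrays)
    return GroupComparison(endpoint, names, "kruskal-wallis",
                           float(res.statistic), float(res.pvalue))


def holm_adjust(pvalues) -> list[float]:
    """Holm step-down adjusted p-values (optional; reports default to
    unadjusted pairwise comparisons)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
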