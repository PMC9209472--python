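"""Group-level summaries: rank tests, Fisher 2x2 comparisons, FDR control.

Thin wrappers over scipy so every figure-style panel reports the same
quantities: group mean +/- SEM, the nonparametric test statistic and p, and
Benjamini-Hochberg adjusted q within a report family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    name: str
    statistic: float
    p: float
    q: float | None = None


@dataclass
class GroupSummary:
    label: str
    mean: float
    sem: float
    n: int


def group_summary(values: np.ndarray, label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return GroupSummary(label=label, mean=float(v.mean()) if n else np.nan, sem=sem, n=n)


def rank_sum(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult("rank-sum", float(res.statistic), float(res.pvalue))


def signed_rank(diff: np.ndarray) -> StatResult:
    """Two-sided Wilcoxon signed-rank test of paired differences against 0."""
    d = np.asarray(diff, dtype=float)
    d = d[np.isfinite(d)]
    if np.allclose(d, 0):
        return StatResult("signed-rank", 0.0, 1.0)
    res = stats.wilcoxon(d)
    return StatResult("signed-rank", float(res.statistic), float(res.pvalue))


def fisher_2x2(table: np.ndarray) -> tuple[float, StatResult]:
    """Odds ratio and two-sided exact test for a 2x2 count table."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), StatResult("fisher-exact", float(odds), float(p))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(tests: list[StatResult]) -> list[StatResult]:
    """Apply BH adjustment across one figure-style family of tests."""
    if not tests:
        return tests
    q = bh_adjust(np.array([t.p for t in tests]))
    for t, qi in zip(tests, q):
        t.q = float(qi)
    return tests


def summarize(
    metrics: dict[str, dict[str, np.ndarray]],
    paired: bool = False,
) -> dict[str, dict]:
    """Panel-style summary of two-group metrics with one FDR family.

    ``metrics`` maps metric name -> {group label -> values}.  Each metric
    gets per-group mean +/- SEM and a two-sided rank test (rank-sum, or
    signed-rank on differences when ``paired``); q-values are BH-adjusted
    across the whole family.  Pure function of its inputs.
    """
    out: dict[str, dict] = {}
    tests: list[StatResult] = []
    for name, groups in metrics.items():
        labels = list(groups)
        if len(labels) != 2:
            raise ValueError(f"metric {name!r} needs exactly two groups")
        a = np.asarray(groups[labels[0]], dtype=float)
        b = np.asarray(groups[labels[1]], dtype=float)
        test = signed_rank(a - b) if paired else rank_sum(a, b)
        tests.append(test)
        out[name] = {
            "groups": {lab: group_summary(vals, lab) for lab, vals in groups.items()},
            "test": test,
        }
    adjust_family(tests)
    return out
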