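"""Nonparametric and proportion statistics used across the analyses.

Per-nucleus CV/MFI distributions across strains are compared by the
Kruskal–Wallis rank test followed by Mann–Whitney U post-hoc pairs (no
adjustment by default, Holm/Bonferroni optional).  Percentages obtained from
categorical counts (e.g. % bridge-positive cells across replicate
experiments) are compared by Student's t-test after the variance-stabilizing
arcsine square-root transform y = arcsin(sqrt(p)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney",
    "mann_whitney_posthoc",
    "arcsine_ttest",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    labels: tuple[str, ...] = ()
    adjustment: str = "none"
    df: float | None = None


def kruskal_wallis(groups: list[np.ndarray], labels: list[str] | None = None) -> TestResult:
    """Kruskal–Wallis H test across >= 2 groups.

    H uses average ranks with the standard tie correction; the p-value is from
    the chi-square distribution on k−1 degrees of freedom.  All-identical
    values give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    total_n = sum(len(g) for g in groups)
    if total_n < 3:
        raise ValueError("need total N >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(labels or ()), df=len(groups) - 1)
    h, p = sps.kruskal(*groups)
    return TestResult(
        "kruskal_wallis", float(h), float(p), tuple(labels or ()), df=len(groups) - 1
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann–Whitney U.

    Exact null distribution when both samples have n <= 8 and no ties occur;
    otherwise the normal approximation with continuity and tie correction.
    The reported U is for the first sample (number of (x, y) pairs with
    x > y, plus half the ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", float(u), float(p))


def mann_whitney_posthoc(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    adjustment: str = "none",
) -> list[TestResult]:
    """Pairwise Mann–Whitney U tests, optionally multiplicity-adjusted.

    ``adjustment`` in {'none', 'holm', 'bonferroni'}.  Default none,
    matching the descriptive post-hoc convention; Holm available for rigor.
    """
    if adjustment not in {"none", "holm", "bonferroni"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = []
    for a, b in pairs:
        r = mann_whitney(groups[a], groups[b])
        results.append(
            TestResult(r.test, r.statistic, r.pvalue, labels=(a, b), adjustment=adjustment)
        )
    if adjustment != "none" and results:
        _, adj, _, _ = multipletests([r.pvalue for r in results], method=adjustment)
        for r, p in zip(results, adj):
            r.pvalue = float(p)
    return results


def arcsine_ttest(
    p1: np.ndarray, p2: np.ndarray, paired: bool = False
) -> TestResult:
    """Student's t-test on arcsine-square-root transformed proportions.

    Proportions must lie in [0, 1]; the transform y = arcsin(sqrt(p)) maps
    them to [0, π/2] and stabilizes binomial variance.  Unpaired uses the
    classic pooled-variance t; paired requires equal lengths.  Degenerate
    zero-variance identical samples report t = 0, p = 1 with a warning.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for arr in (p1, p2):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("proportions must lie in [0, 1]")
    y1 = np.arcsin(np.sqrt(p1))
    y2 = np.arcsin(np.sqrt(p2))
    if paired:
        if len(y1) != len(y2):
            raise ValueError("paired test requires equal lengths")
        diffs = y1 - y2
        if np.allclose(diffs.std(ddof=0), 0) and np.allclose(diffs, 0):
            warnings.warn("identical paired samples: zero variance, p reported as 1",
                          stacklevel=2)
            return TestResult("arcsine_paired_t", 0.0, 1.0, df=len(y1) - 1)
        t, p = sps.ttest_rel(y1, y2)
        df = len(y1) - 1
        name = "arcsine_paired_t"
    else:
        if np.allclose(np.concatenate([y1, y2]).std(ddof=0), 0):
            warnings.warn("all transformed values identical: zero variance, p reported as 1",
                          stacklevel=2)
            return TestResult("arcsine_unpaired_t", 0.0, 1.0, df=len(y1) + len(y2) - 2)
        t, p = sps.ttest_ind(y1, y2, equal_var=True)
        df = len(y1) + len(y2) - 2
        name = "arcsine_unpaired_t"
    return TestResult(name, float(t), float(p), df=df)
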