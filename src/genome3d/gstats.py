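"""Hypothesis tests for comparing model categories.

One-tailed Wilcoxon tests (signed-rank for paired samples, rank-sum
otherwise) and a category permutation test whose statistic is the
directional win count across the benchmark battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, wilcoxon

from .benchmark import BenchmarkReport, HIGHER_BETTER, LOWER_BETTER


@dataclass
class CategoryResults:
    """Per-model benchmark reports for one model category."""

    name: str
    reports: list[BenchmarkReport]

    def test_names(self) -> list[str]:
        names = set(self.reports[0].values)
        for r in self.reports[1:]:
            names &= set(r.values)
        return sorted(names)

    def matrix(self, tests: Sequence[str]) -> np.ndarray:
        return np.array([[r.values[t] for t in tests] for r in self.reports])

    def directions(self, tests: Sequence[str]) -> dict[str, str]:
        return {t: self.reports[0].directions[t] for t in tests}


def wilcoxon_one_tail(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    alternative: str = "greater",
) -> float:
    """One-sided p for ``x`` vs ``y``: signed-rank when paired, rank-sum otherwise.

    ``alternative='greater'`` tests whether ``x`` tends to exceed ``y``.
    All-zero paired differences return p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        diffs = x - y
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        stat = wilcoxon(x, y, alternative=alternative, zero_method="wilcox")
        return float(stat.pvalue)
    stat = mannwhitneyu(x, y, alternative=alternative)
    return float(stat.pvalue)


def wilcoxon_two_tail(x: Sequence[float], y: Sequence[float], paired: bool = False) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if np.all(x - y == 0):
            return 1.0
        return float(wilcoxon(x, y, alternative="two-sided", zero_method="wilcox").pvalue)
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# category permutation test


def _win_count(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    directions: Sequence[str],
) -> float:
    """Directional win count of category a over b across tests (ties 0.5)."""
    wins = 0.0
    med_a = np.median(mat_a, axis=0)
    med_b = np.median(mat_b, axis=0)
    for k, direction in enumerate(directions):
        if med_a[k] == med_b[k]:
            wins += 0.5
        elif direction == LOWER_BETTER:
            wins += med_a[k] < med_b[k]
        else:
            wins += med_a[k] > med_b[k]
    return wins


def _standardized_sum(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    directions: Sequence[str],
) -> float:
    pooled = np.vstack([mat_a, mat_b])
    sd = pooled.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (np.median(mat_a, axis=0) - np.median(mat_b, axis=0)) / sd
    sign = np.array([-1.0 if d == LOWER_BETTER else 1.0 for d in directions])
    return float(np.sum(z * sign))


def category_permutation_test(
    a: CategoryResults,
    b: CategoryResults,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "standardized_sum",
) -> tuple[float, float]:
    """Permutation p-value for the total benchmark advantage of ``a`` over ``b``.

    Models are shuffled between the two categories ``n_perm`` times and the
    total benchmark statistic is recomputed per draw.  The default statistic
    is the sum of directed, pooled-standardized median differences across
    tests; ``statistic='win_count'`` uses the directional win count of
    medians instead (ties counting 0.5).  The win count is insensitive to a
    category advantage that spans the whole battery: any permutation placing
    a majority of the better models on one side sweeps every test at once,
    so its permutation null concentrates on the extremes and cannot produce
    small p-values in exactly the situations of interest.  Returns
    ``(observed, p)`` with add-one smoothing:
    p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    tests = sorted(set(a.test_names()) & set(b.test_names()))
    if not tests:
        raise ValueError("no common benchmark tests")
    directions = [a.reports[0].directions[t] for t in tests]
    stat_fn = {"win_count": _win_count, "standardized_sum": _standardized_sum}[statistic]
    mat_a = a.matrix(tests)
    mat_b = b.matrix(tests)
    observed = stat_fn(mat_a, mat_b, directions)
    pooled = np.vstack([mat_a, mat_b])
    n_a = len(mat_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        perm = stat_fn(pooled[idx[:n_a]], pooled[idx[n_a:]], directions)
        if perm >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, float(p)


def minimal_sparseness(
    results_by_fraction: Mapping[float, Sequence[float]],
    full_results: Sequence[float],
    alpha: float = 0.01,
) -> float:
    """Smallest fraction from which all larger fractions match the full result.

    A fraction "matches" when a two-tailed rank-sum test cannot reject median
    equality with the full dataset at ``alpha``.
    """
    fractions = sorted(results_by_fraction)
    minimal = None
    for k, f in enumerate(fractions):
        ok = all(
            wilcoxon_two_tail(results_by_fraction[g], full_results) >= alpha
            for g in fractions[k:]
        )
        if ok:
            minimal = f
            break
    if minimal is None:
        minimal = fractions[-1]
    return minimal


def star_annotation(p: float) -> str:
    """Figure-caption style significance stars."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
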