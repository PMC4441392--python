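"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def signed_rank_exact_p(diffs):
    """Exhaustive one-sided p (greater): P(W+ >= observed) over all sign patterns."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    observed = ranks[diffs > 0].sum()
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        count += w >= observed
        total += 1
    return count / total


def rank_sum_exact_p(x, y):
    """Exhaustive one-sided p (x greater): P(rank sum >= observed) over all splits."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    observed = ranks[:nx].sum()
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(combo)].sum()
        count += w >= observed
        total += 1
    return count / total
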