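"""Sparsification, coordinate permutation and degree-weighted map merging.

The "poor-get-richer" merge adds predicted interactions to a base distance
map by drawing candidates with probability inversely proportional to the
product of the current degrees of their endpoint beads, refreshing degrees
after every draw.  This preferentially fills poorly covered regions and
reduces the variance of the degree distribution.
"""

from __future__ import annotations

import numpy as np

from .contacts import DistanceMap

MIN_DEGREE = 0.5  # floor assigned to isolated beads for numerical stability


def uniform_sample(dmap: DistanceMap, fraction: float, seed: int) -> DistanceMap:
    """Keep ``round(fraction * len)`` entries, sampled uniformly without replacement."""
    if len(dmap) == 0:
        raise ValueError("empty distance map")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(round(fraction * len(dmap)))
    if n_keep == 0:
        raise ValueError(f"fraction {fraction} keeps zero of {len(dmap)} entries")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(dmap), size=n_keep, replace=False)
    return DistanceMap(dmap.layout, dmap.i[keep], dmap.j[keep], dmap.v[keep])


def permute_coordinates(dmap: DistanceMap, seed: int) -> DistanceMap:
    """Relabel beads by a random permutation, preserving the distance multiset.

    A single permutation is applied to both endpoints of every entry, so the
    map stays symmetric and the distribution of distances is unchanged.
    """
    if len(dmap) == 0:
        raise ValueError("empty distance map")
    rng = np.random.default_rng(seed)
    pi = rng.permutation(dmap.layout.n_beads)
    return DistanceMap(dmap.layout, pi[dmap.i], pi[dmap.j], dmap.v)


def node_degrees(dmap: DistanceMap) -> np.ndarray:
    """Per-bead count of distinct interaction partners, floored at 0.5."""
    n = dmap.layout.n_beads
    deg = np.bincount(dmap.i, minlength=n).astype(float)
    off = dmap.i != dmap.j
    deg += np.bincount(dmap.j[off], minlength=n)
    return np.maximum(deg, MIN_DEGREE)


def poor_get_richer_merge(
    base: DistanceMap,
    candidates: DistanceMap,
    n: int,
    seed: int,
) -> DistanceMap:
    """Add ``n`` candidate interactions to ``base`` by degree-weighted sampling.

    Candidates whose bead pair already exists in ``base`` are excluded.  Each
    draw picks an available candidate (i, j) with probability proportional to
    1/(d_i * d_j) under the current degree vector; both endpoint degrees are
    updated after the draw.  Sampling is without replacement and
    seed-deterministic.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    base_keys = set(zip(base.i.tolist(), base.j.tolist()))
    avail = [
        (int(a), int(b), float(d))
        for a, b, d in zip(candidates.i, candidates.j, candidates.v)
        if (int(a), int(b)) not in base_keys
    ]
    if n > len(avail):
        raise ValueError(f"requested {n} additions but only {len(avail)} candidates available")
    rng = np.random.default_rng(seed)
    deg = node_degrees(base)
    ai = np.array([a for a, _, _ in avail], dtype=np.int64)
    aj = np.array([b for _, b, _ in avail], dtype=np.int64)
    av = np.array([d for _, _, d in avail])
    alive = np.ones(len(avail), dtype=bool)
    chosen: list[int] = []
    for _ in range(n):
        idx = np.nonzero(alive)[0]
        w = 1.0 / (deg[ai[idx]] * deg[aj[idx]])
        w /= w.sum()
        pick = idx[rng.choice(len(idx), p=w)]
        chosen.append(int(pick))
        alive[pick] = False
        a, b = ai[pick], aj[pick]
        # a bead's first real interaction replaces the 0.5 floor with 1
        for bead in (a, b) if a != b else (a,):
            deg[bead] = 1.0 if deg[bead] <= MIN_DEGREE else deg[bead] + 1.0
    chosen_arr = np.array(chosen, dtype=np.int64)
    new_i = np.concatenate([base.i, ai[chosen_arr]]) if chosen else base.i
    new_j = np.concatenate([base.j, aj[chosen_arr]]) if chosen else base.j
    new_v = np.concatenate([base.v, av[chosen_arr]]) if chosen else base.v
    merged = DistanceMap(base.layout, new_i, new_j, new_v)
    assert len(merged) == len(base) + n, "merge size mismatch (duplicate candidates?)"
    return merged
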