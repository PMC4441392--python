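"""Contact maps, target distance maps and frequency-to-distance conversion.

A contact map is a symmetric sparse matrix of nonnegative read counts over
bead pairs; a distance map holds positive target distances in nanometres.
Contact frequencies are converted to distances through a 100-bin profile of
mean frequency vs. genomic separation, inverted by linear interpolation and
scaled by a constant chromatin packing of 130 bp/nm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout

logger = logging.getLogger(__name__)

PACKING_BP_PER_NM = 130.0


def _canonical(i: np.ndarray, j: np.ndarray, v: np.ndarray, aggregate: str = "sum"):
    """Canonicalize pair entries: i <= j, duplicates merged, sorted by (i, j)."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    v = np.asarray(v, dtype=float)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    order = np.lexsort((hi, lo))
    lo, hi, v = lo[order], hi[order], v[order]
    keys = np.stack([lo, hi], axis=1)
    uniq, idx, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    if aggregate == "sum":
        vv = np.bincount(inv, weights=v, minlength=len(uniq))
    elif aggregate == "mean":
        vv = np.bincount(inv, weights=v, minlength=len(uniq)) / np.bincount(inv, minlength=len(uniq))
    elif aggregate == "first":
        vv = v[idx]
    else:
        raise ValueError(aggregate)
    return uniq[:, 0], uniq[:, 1], vv


@dataclass
class _SparsePairs:
    """Symmetric sparse pair table; each unordered pair stored once with i <= j."""

    layout: GenomeLayout
    i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    v: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    _aggregate = "sum"

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.i):
            n = self.layout.n_beads
            if self.i.max(initial=-1) >= n or self.j.max(initial=-1) >= n:
                raise ValueError("bead index out of range")
            if self.i.min(initial=0) < 0 or self.j.min(initial=0) < 0:
                raise ValueError("negative bead index")
        self.i, self.j, self.v = _canonical(self.i, self.j, self.v, self._aggregate)

    def __len__(self) -> int:
        return len(self.v)

    def pair_keys(self) -> np.ndarray:
        return self.i * self.layout.n_beads + self.j

    def to_dense(self) -> np.ndarray:
        n = self.layout.n_beads
        m = np.zeros((n, n))
        m[self.i, self.j] = self.v
        m[self.j, self.i] = self.v
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bead_i": self.i, "bead_j": self.j, "value": self.v})

    def genomic_separations(self) -> np.ndarray:
        """Separation in bp for intra-chromosomal pairs, NaN for trans pairs."""
        chrom_ids = self.layout.bead_chrom_ids()
        sep = np.abs(self.j - self.i).astype(float) * self.layout.resolution_bp
        sep[chrom_ids[self.i] != chrom_ids[self.j]] = np.nan
        return sep


class ContactMap(_SparsePairs):
    """Symmetric sparse contact-count map at bead resolution."""

    _aggregate = "sum"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.v < 0):
            raise ValueError("contact counts must be nonnegative")
        keep = self.v > 0
        self.i, self.j, self.v = self.i[keep], self.j[keep], self.v[keep]

    def total(self) -> float:
        return float(self.v.sum())

    def coverage(self) -> np.ndarray:
        """Per-bead total contact (diagonal entries counted once)."""
        n = self.layout.n_beads
        cov = np.bincount(self.i, weights=self.v, minlength=n)
        off = self.i != self.j
        cov += np.bincount(self.j[off], weights=self.v[off], minlength=n)
        return cov

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().rename(columns={"value": "count"})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, layout: GenomeLayout) -> "ContactMap":
        df = pd.read_csv(path, sep="\t")
        return cls(layout, df["bead_i"].to_numpy(), df["bead_j"].to_numpy(), df["count"].to_numpy())


class DistanceMap(_SparsePairs):
    """Symmetric sparse map of target distances (nm) between bead pairs."""

    _aggregate = "mean"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.v <= 0):
            raise ValueError("distances must be positive")

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().rename(columns={"value": "distance_nm"})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, layout: GenomeLayout) -> "DistanceMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            layout,
            df["bead_i"].to_numpy(),
            df["bead_j"].to_numpy(),
            df["distance_nm"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# raw (bp-coordinate) records


def read_contact_records(path: str | Path) -> pd.DataFrame:
    """Read a fragment- or bin-level contact TSV with bp coordinates."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom_i", "pos_i", "chrom_j", "pos_j", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns {sorted(missing)}")
    return df


def bin_contacts(records: pd.DataFrame, layout: GenomeLayout) -> ContactMap:
    """Sum raw contact records into bead-pair bins.

    Records with coordinates outside the layout are rejected and logged.
    """
    ii, jj, vv = [], [], []
    n_bad = 0
    known = set(layout.names)
    lengths = dict(layout.chromosomes)
    offsets = layout.chrom_offsets()
    res = layout.resolution_bp
    for ci, pi, cj, pj, c in zip(
        records["chrom_i"], records["pos_i"], records["chrom_j"], records["pos_j"], records["count"]
    ):
        if ci not in known or cj not in known or not (0 <= pi < lengths[ci]) or not (0 <= pj < lengths[cj]):
            n_bad += 1
            continue
        ii.append(offsets[ci] + int(pi) // res)
        jj.append(offsets[cj] + int(pj) // res)
        vv.append(c)
    if n_bad:
        logger.warning("bin_contacts: rejected %d out-of-range records", n_bad)
    return ContactMap(layout, np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64), np.array(vv, dtype=float))


# ---------------------------------------------------------------------------
# iterative correction (matrix balancing)


def ice_correct(cmap: ContactMap, max_iter: int = 200, tol: float = 1e-9) -> ContactMap:
    """Iteratively balance a contact map so all covered beads have equal coverage.

    Beads with zero coverage are left untouched; the total contact mass is
    rescaled to the input total after convergence.  If the relative spread of
    coverage does not fall below ``tol`` within ``max_iter`` sweeps, a warning
    is issued and the best iterate is returned.
    """
    if len(cmap) == 0:
        raise ValueError("empty contact map")
    v = cmap.v.astype(float).copy()
    i, j = cmap.i, cmap.j
    n = cmap.layout.n_beads
    total_in = v.sum()
    covered = np.zeros(n, dtype=bool)
    covered[i] = True
    covered[j] = True

    def coverage(values: np.ndarray) -> np.ndarray:
        cov = np.bincount(i, weights=values, minlength=n)
        off = i != j
        cov += np.bincount(j[off], weights=values[off], minlength=n)
        return cov

    converged = False
    for _ in range(max_iter):
        cov = coverage(v)
        c = cov[covered]
        rel = (c.max() - c.min()) / c.mean() if c.mean() > 0 else 0.0
        if rel < tol:
            converged = True
            break
        bias = np.ones(n)
        bias[covered] = cov[covered] / c.mean()
        v = v / (bias[i] * bias[j])
    if not converged:
        cov = coverage(v)
        c = cov[covered]
        rel = (c.max() - c.min()) / c.mean() if c.mean() > 0 else 0.0
        if rel >= tol:
            warnings.warn(f"ICE did not converge after {max_iter} sweeps (rel spread {rel:.2e})")
    v *= total_in / v.sum()
    return ContactMap(cmap.layout, i, j, v)


# ---------------------------------------------------------------------------
# frequency -> distance profile


@dataclass
class DistanceProfile:
    """Monotone profile of contact frequency vs. genomic separation (bp).

    ``freq`` is strictly interpreted as decreasing with ``sep_bp`` after
    isotonic pooling; inversion is linear interpolation on frequency.
    """

    freq: np.ndarray  # mean contact frequency per bin, descending order in sep
    sep_bp: np.ndarray  # mean genomic separation per bin, ascending
    packing_bp_per_nm: float = PACKING_BP_PER_NM

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.sep_bp = np.asarray(self.sep_bp, dtype=float)
        if self.packing_bp_per_nm <= 0:
            raise ValueError("packing must be positive")

    def invert(self, frequencies: np.ndarray) -> np.ndarray:
        """Map frequencies to genomic separations (bp) by linear interpolation.

        Frequencies above the profile maximum clamp to the minimum separation,
        below the minimum clamp to the maximum separation.
        """
        f = np.asarray(frequencies, dtype=float)
        # np.interp needs ascending x; freq descends with separation
        xs = self.freq[::-1]
        ys = self.sep_bp[::-1]
        # collapse plateaus (from isotonic pooling) so interp is well defined
        keep = np.concatenate([[True], np.diff(xs) > 0])
        return np.interp(f, xs[keep], ys[keep])

    def to_nm(self, frequencies: np.ndarray) -> np.ndarray:
        return self.invert(frequencies) / self.packing_bp_per_nm

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# packing_bp_per_nm={self.packing_bp_per_nm}\n")
            fh.write("mean_frequency\tmean_separation_bp\n")
            for f, s in zip(self.freq, self.sep_bp):
                fh.write(f"{f:.10g}\t{s:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceProfile":
        packing = PACKING_BP_PER_NM
        with open(path) as fh:
            first = fh.readline().strip()
            if first.startswith("#") and "packing_bp_per_nm=" in first:
                packing = float(first.split("=", 1)[1])
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["mean_frequency"].to_numpy(), df["mean_separation_bp"].to_numpy(), packing)


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing sequence (unit weights)."""
    # fit -y as non-decreasing
    vals = list(-y.astype(float))
    blocks: list[list[float]] = []  # (sum, count)
    for val in vals:
        blocks.append([val, 1.0])
        while len(blocks) > 1 and blocks[-2][0] / blocks[-2][1] > blocks[-1][0] / blocks[-1][1]:
            s, c = blocks.pop()
            blocks[-1][0] += s
            blocks[-1][1] += c
    out = np.concatenate([[s / c] * int(c) for s, c in blocks])
    return -out


def fit_distance_profile(
    cmap: ContactMap,
    n_bins: int = 100,
    packing: float = PACKING_BP_PER_NM,
) -> DistanceProfile:
    """Fit the frequency-vs-separation profile from intra-chromosomal contacts.

    Pairs are grouped into ``n_bins`` equal-count bins of genomic separation;
    per bin the mean frequency and mean separation are recorded, then
    frequency is made monotone decreasing by isotonic pooling.  Self-bin
    (diagonal) contacts are excluded.
    """
    sep = cmap.genomic_separations()
    mask = np.isfinite(sep) & (sep > 0)
    if not mask.any():
        raise ValueError("no intra-chromosomal contacts to fit a profile from")
    sep = sep[mask]
    freq = cmap.v[mask]
    n_distinct = len(np.unique(sep))
    if n_distinct < n_bins:
        logger.info("fit_distance_profile: reducing n_bins from %d to %d", n_bins, n_distinct)
        n_bins = n_distinct
    order = np.argsort(sep, kind="stable")
    sep, freq = sep[order], freq[order]
    edges = np.linspace(0, len(sep), n_bins + 1).round().astype(int)
    mean_f = np.array([freq[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    mean_s = np.array([sep[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    mean_f = _isotonic_decreasing(mean_f)
    return DistanceProfile(mean_f, mean_s, packing)


def contacts_to_distances(cmap: ContactMap, profile: DistanceProfile) -> DistanceMap:
    """Convert contact frequencies to target distances in nm.

    Diagonal entries are dropped (distance zero is meaningless as a target).
    """
    off = cmap.i != cmap.j
    n_diag = int((~off).sum())
    if n_diag:
        logger.info("contacts_to_distances: dropping %d diagonal entries", n_diag)
    nm = profile.to_nm(cmap.v[off])
    return DistanceMap(cmap.layout, cmap.i[off], cmap.j[off], nm)


# ---------------------------------------------------------------------------
# damped maps (simulated smaller experiment)


def damp_contacts(records: pd.DataFrame, layout: GenomeLayout, factor: float) -> ContactMap:
    """Simulate a smaller experiment from fragment-level records.

    Per fragment pair: divide the count by ``factor``, drop values below 1
    (detection threshold), round to the nearest integer (half away from
    zero), then sum per bead-pair bin.
    """
    if factor < 1:
        raise ValueError("damping factor must be >= 1")
    damped = records["count"].to_numpy(dtype=float) / factor
    keep = damped >= 1.0
    quantized = np.floor(damped[keep] + 0.5)  # half away from zero (counts > 0)
    kept = records.loc[keep].copy()
    kept["count"] = quantized
    return bin_contacts(kept, layout)


def damped_retained_pairs(records: pd.DataFrame, factor: float) -> set[tuple]:
    """Fragment pairs surviving the detection threshold at ``factor``."""
    damped = records["count"].to_numpy(dtype=float) / factor
    keep = damped >= 1.0
    kept = records.loc[keep]
    return set(zip(kept["chrom_i"], kept["pos_i"], kept["chrom_j"], kept["pos_j"]))


def damped_to_distances(damped: ContactMap, reference: DistanceMap, seed: int = 0) -> DistanceMap:
    """Assign distances to a damped map by rank against a reference distribution.

    The highest damped count receives the lowest reference distance and so on
    until the damped map is exhausted.  Ties in count are broken by a seeded
    random permutation for reproducibility.
    """
    if len(reference) == 0:
        raise ValueError("empty reference distance map")
    if len(damped) > len(reference):
        raise ValueError(
            f"damped map has {len(damped)} entries but reference only {len(reference)} distances"
        )
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(len(damped))
    order = np.lexsort((tiebreak, -damped.v))  # descending count, random within ties
    ref_sorted = np.sort(reference.v)
    dist = np.empty(len(damped))
    dist[order] = ref_sorted[: len(damped)]
    off = damped.i != damped.j
    return DistanceMap(damped.layout, damped.i[off], damped.j[off], dist[off])
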