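"""Predicted distance maps from orthologous organisms and codon usage.

Two sources of predicted bead-pair distances for a target organism A:

* projection of a measured distance map from an evolutionary related
  organism B through an ortholog table (averaging over ortholog pairs);
* a codon-usage functional distance between genes (a Jensen-Shannon-type
  divergence between 64-codon frequency vectors), used as a proxy for
  spatial proximity.

Both are rescaled to the median of the organism-A distance distribution,
band-filtered by quantile, and binned into bead coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import DistanceMap
from .layout import GeneAnnotation, GenomeLayout

logger = logging.getLogger(__name__)

CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))
CODON_INDEX = {c: k for k, c in enumerate(CODONS)}

ORTHO_BAND = (0.05, 0.0)  # bottom 5% of projected ortholog distances
ORTHO_FULL_MAP_BAND = (0.50, 0.0)  # when integrating into a complete map
CUFS_BAND = (0.10, 0.10)  # top and bottom 10% of codon-usage distances


@dataclass
class OrthologTable:
    """Map gene in organism A -> set of orthologous genes in organism B."""

    families: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.families = {a: set(bs) for a, bs in self.families.items() if bs}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a in sorted(self.families):
                for b in sorted(self.families[a]):
                    fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t")
        fams: dict[str, set[str]] = {}
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
            fams.setdefault(str(a), set()).add(str(b))
        return cls(fams)


# ---------------------------------------------------------------------------
# gene-level distance tables (dict keyed by frozenset-like sorted tuple)

GenePairDistances = dict[tuple[str, str], float]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def gene_pair_distances(map_b: DistanceMap, genes_b: GeneAnnotation) -> GenePairDistances:
    """Spatial distance per gene pair from the nearest measured bin pair.

    Each gene maps to its midpoint bead; a gene pair takes the distance of
    the measured bead pair nearest to the genes' beads (ties resolved toward
    lower bead indices).  Genes on chromosomes with no measured bead are
    skipped and logged.
    """
    layout = map_b.layout
    measured = np.unique(np.concatenate([map_b.i, map_b.j]))
    chrom_ids = layout.bead_chrom_ids()
    # nearest measured bead per bead, restricted to the same chromosome
    nearest = np.full(layout.n_beads, -1, dtype=np.int64)
    for ci in range(len(layout.chromosomes)):
        on_c = measured[chrom_ids[measured] == ci]
        beads_c = np.nonzero(chrom_ids == ci)[0]
        if len(on_c) == 0:
            continue
        for b in beads_c:
            k = np.argmin(np.abs(on_c - b))  # ties -> first (lower index)
            nearest[b] = on_c[k]
    lookup = dict(zip(zip(map_b.i.tolist(), map_b.j.tolist()), map_b.v.tolist()))
    gene_beads = genes_b.beads(layout)
    out: GenePairDistances = {}
    skipped = 0
    gene_list = sorted(gene_beads)
    for a, b in itertools.combinations(gene_list, 2):
        ba, bb = nearest[gene_beads[a]], nearest[gene_beads[b]]
        if ba < 0 or bb < 0:
            skipped += 1
            continue
        key = (min(ba, bb), max(ba, bb))
        d = lookup.get((int(key[0]), int(key[1])))
        if d is not None:
            out[_pair_key(a, b)] = d
    if skipped:
        logger.info("gene_pair_distances: skipped %d pairs with no measured bin", skipped)
    return out


def project_orthologous(dist_b: GenePairDistances, orthologs: OrthologTable) -> GenePairDistances:
    """Transfer gene-pair distances from organism B to A via ortholog families.

    The distance of an A-gene pair (i, j) is the mean of the B distances over
    all ortholog pairs (k, l), k in O_i, l in O_j, restricted to measured
    pairs; pairs with no measurable ortholog pair are omitted.
    """
    out: GenePairDistances = {}
    genes_a = sorted(orthologs.families)
    for a1, a2 in itertools.combinations(genes_a, 2):
        vals = [
            dist_b[_pair_key(k, l)]
            for k in orthologs.families[a1]
            for l in orthologs.families[a2]
            if _pair_key(k, l) in dist_b
        ]
        if vals:
            out[_pair_key(a1, a2)] = float(np.mean(vals))
    return out


def scale_to_median(dist: GenePairDistances, reference: DistanceMap | np.ndarray) -> GenePairDistances:
    """Rescale distances so their median matches the reference median."""
    if not dist:
        raise ValueError("empty distance table")
    ref_vals = reference.v if isinstance(reference, DistanceMap) else np.asarray(reference)
    if len(ref_vals) == 0:
        raise ValueError("empty reference")
    med = float(np.median(list(dist.values())))
    ref_med = float(np.median(ref_vals))
    if med == 0:
        raise ValueError("zero median in distances to scale")
    factor = ref_med / med
    return {k: v * factor for k, v in dist.items()}


def select_quantile_band(dist: GenePairDistances, low_q: float, high_q: float) -> GenePairDistances:
    """Keep values <= quantile(low_q) and >= quantile(1 - high_q)."""
    if low_q < 0 or high_q < 0 or low_q + high_q > 1:
        raise ValueError("invalid quantile band")
    vals = np.array(list(dist.values()))
    keep_low = np.quantile(vals, low_q) if low_q > 0 else -np.inf
    keep_high = np.quantile(vals, 1 - high_q) if high_q > 0 else np.inf
    return {k: v for k, v in dist.items() if v <= keep_low or v >= keep_high}


# ---------------------------------------------------------------------------
# codon usage frequency distance


@dataclass
class CodonProfile:
    """Normalized 64-codon frequency vector of a coding sequence."""

    gene: str
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (64,):
            raise ValueError("codon profile must have 64 entries")
        if np.any(self.freq < 0) or abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must be nonnegative and sum to 1")


def codon_frequencies(cds: str, gene: str = "") -> CodonProfile:
    """Codon composition of a CDS as a normalized 64-vector (stops included).

    The sequence length must be divisible by 3; codons containing characters
    outside ACGT are skipped (and logged).
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    counts = np.zeros(64)
    skipped = 0
    for k in range(0, len(seq), 3):
        idx = CODON_INDEX.get(seq[k : k + 3])
        if idx is None:
            skipped += 1
        else:
            counts[idx] += 1
    if skipped:
        logger.info("codon_frequencies(%s): skipped %d ambiguous codons", gene, skipped)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous codons in CDS")
    return CodonProfile(gene, counts / total)


def profiles_from_fasta(path: str | Path) -> list[CodonProfile]:
    from Bio import SeqIO

    return [codon_frequencies(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def _kl(p: np.ndarray, q: np.ndarray, base: float | None) -> float:
    mask = p > 0
    log = np.log(p[mask] / q[mask])
    if base is not None:
        log /= np.log(base)
    return float(np.sum(p[mask] * log))


def cufs_distance(
    p: CodonProfile | np.ndarray,
    q: CodonProfile | np.ndarray,
    sqrt: bool = False,
    base: float | None = None,
) -> float:
    """Codon usage frequency distance between two profiles.

    d(p, q) = KL(p, m) + KL(q, m) with m = (p + q) / 2 and 0*log 0 := 0.
    Natural log by default; ``sqrt=True`` returns the square root (a proper
    metric), rank-equivalent to the plain value.
    """
    pv = p.freq if isinstance(p, CodonProfile) else np.asarray(p, dtype=float)
    qv = q.freq if isinstance(q, CodonProfile) else np.asarray(q, dtype=float)
    m = 0.5 * (pv + qv)
    d = _kl(pv, m, base) + _kl(qv, m, base)
    d = max(d, 0.0)  # guard tiny negative rounding
    return float(np.sqrt(d)) if sqrt else float(d)


def cufs_matrix(
    profiles: list[CodonProfile],
    reference: DistanceMap | np.ndarray | None = None,
    sqrt: bool = False,
    base: float | None = None,
) -> GenePairDistances:
    """All-pairs codon usage distances, optionally median-scaled to a reference."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    out: GenePairDistances = {}
    freqs = np.stack([p.freq for p in profiles])
    names = [p.gene for p in profiles]
    for a in range(len(profiles)):
        m = 0.5 * (freqs[a] + freqs[a + 1 :])
        for off, mm in enumerate(m):
            b = a + 1 + off
            d = _kl(freqs[a], mm, base) + _kl(freqs[b], mm, base)
            d = max(d, 0.0)
            out[_pair_key(names[a], names[b])] = float(np.sqrt(d)) if sqrt else float(d)
    if reference is not None:
        out = scale_to_median(out, reference)
    return out


# ---------------------------------------------------------------------------


def gene_pairs_to_bins(
    dist: GenePairDistances,
    layout: GenomeLayout,
    genes: GeneAnnotation,
) -> DistanceMap:
    """Average gene-pair distances into bead-pair bins (midpoint assignment).

    Self-bead pairs (both genes in the same bead) are dropped: a zero or
    near-zero target distance is not a usable constraint.
    """
    beads = genes.beads(layout)
    ii, jj, vv = [], [], []
    for (a, b), d in dist.items():
        if a not in beads or b not in beads or d <= 0:
            continue
        ba, bb = beads[a], beads[b]
        if ba == bb:
            continue
        ii.append(min(ba, bb))
        jj.append(max(ba, bb))
        vv.append(d)
    if not ii:
        raise ValueError("no gene pairs mappable to distinct beads")
    return DistanceMap(layout, np.array(ii), np.array(jj), np.array(vv))
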