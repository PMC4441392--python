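"""Genome layout: chromosomes, fixed-size bins ("beads") and locus sets.

Chromosomes are discretized into beads of ``resolution_bp`` (default 10 kbp).
Bead ``k`` of a chromosome covers the half-open interval
``[k*res, (k+1)*res)`` in bp; the last bead of each chromosome is truncated.
Beads carry a single global 0-based index, concatenated in chromosome order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_RESOLUTION_BP = 10_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with a global bead indexing.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    resolution_bp:
        Bin size in bp; must be positive.
    centromeres:
        Optional map chromosome name -> centromere position (bp).
    """

    chromosomes: tuple[tuple[str, int], ...]
    resolution_bp: int = DEFAULT_RESOLUTION_BP
    centromeres: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, pos in self.centromeres.items():
            if name not in names:
                raise ValueError(f"centromere on unknown chromosome {name!r}")
            if not 0 <= pos < dict(self.chromosomes)[name]:
                raise ValueError(f"centromere of {name} outside chromosome bounds")

    # -- derived indexing ---------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_beads_of(self, chrom: str) -> int:
        return math.ceil(self.length_of(chrom) / self.resolution_bp)

    @property
    def n_beads(self) -> int:
        return sum(math.ceil(l / self.resolution_bp) for _, l in self.chromosomes)

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of each chromosome's first bead."""
        offsets: dict[str, int] = {}
        acc = 0
        for name, length in self.chromosomes:
            offsets[name] = acc
            acc += math.ceil(length / self.resolution_bp)
        return offsets

    def bead_of(self, chrom: str, pos_bp: int) -> int:
        """Global bead index of the bin containing ``pos_bp`` on ``chrom``."""
        length = self.length_of(chrom)
        if not 0 <= pos_bp < length:
            raise ValueError(f"position {pos_bp} outside {chrom} (length {length})")
        return self.chrom_offsets()[chrom] + pos_bp // self.resolution_bp

    def bead_chrom(self, bead: int) -> tuple[str, int]:
        """Return ``(chrom, local_bead_index)`` of a global bead index."""
        if not 0 <= bead < self.n_beads:
            raise ValueError(f"bead {bead} out of range")
        acc = 0
        for name, length in self.chromosomes:
            n = math.ceil(length / self.resolution_bp)
            if bead < acc + n:
                return name, bead - acc
            acc += n
        raise AssertionError("unreachable")

    def bead_chrom_ids(self):
        """Per-bead chromosome ordinal (0-based), as an array of length n_beads."""
        import numpy as np

        ids = np.empty(self.n_beads, dtype=np.int64)
        acc = 0
        for ci, (_, length) in enumerate(self.chromosomes):
            n = math.ceil(length / self.resolution_bp)
            ids[acc : acc + n] = ci
            acc += n
        return ids

    def telomere_beads(self) -> list[int]:
        """First and last bead of each chromosome (one bead if they coincide)."""
        out: list[int] = []
        offsets = self.chrom_offsets()
        for name, length in self.chromosomes:
            n = math.ceil(length / self.resolution_bp)
            first = offsets[name]
            last = first + n - 1
            out.append(first)
            if last != first:
                out.append(last)
        return out

    def centromere_beads(self) -> dict[str, int]:
        return {c: self.bead_of(c, p) for c, p in self.centromeres.items()}

    def adjacent_pairs(self):
        """(i, i+1) bead pairs along each chromosome, as two arrays."""
        import numpy as np

        lo, hi = [], []
        acc = 0
        for _, length in self.chromosomes:
            n = math.ceil(length / self.resolution_bp)
            lo.extend(range(acc, acc + n - 1))
            hi.extend(range(acc + 1, acc + n))
            acc += n
        return np.asarray(lo, dtype=np.int64), np.asarray(hi, dtype=np.int64)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for name, length in self.chromosomes:
            rows.append((name, length, self.centromeres.get(name, "")))
        df = pd.DataFrame(rows, columns=["name", "length_bp", "centromere_bp"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, resolution_bp: int = DEFAULT_RESOLUTION_BP) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t")
        chroms = [(str(r["name"]), int(r["length_bp"])) for _, r in df.iterrows()]
        cents: dict[str, int] = {}
        if "centromere_bp" in df.columns:
            for _, r in df.iterrows():
                v = r["centromere_bp"]
                if pd.notna(v) and str(v) != "":
                    cents[str(r["name"])] = int(v)
        return cls(tuple(chroms), resolution_bp=resolution_bp, centromeres=cents)


@dataclass
class LocusSet:
    """A named set of genomic intervals, optionally partitioned into subsets.

    Intervals are BED-style 0-based half-open ``(chrom, start, end)``.
    ``subsets`` maps a subset label to member indices; when present the
    labels must partition the members.
    """

    name: str
    members: list[tuple[str, int, int]]
    subsets: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if self.subsets is not None:
            flat = sorted(i for idxs in self.subsets.values() for i in idxs)
            if flat != list(range(len(self.members))):
                raise ValueError("subsets must partition the members")

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, start, end in self.members:
            length = layout.length_of(chrom)
            if not (0 <= start < end <= length):
                raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")

    def midpoint_beads(self, layout: GenomeLayout) -> list[int]:
        """One bead per member: the bin containing the interval midpoint."""
        return [layout.bead_of(c, (s + e) // 2) for c, s, e in self.members]

    def subset_beads(self, layout: GenomeLayout) -> dict[str, list[int]]:
        beads = self.midpoint_beads(layout)
        if self.subsets is None:
            return {self.name: beads}
        return {lab: [beads[i] for i in idxs] for lab, idxs in self.subsets.items()}

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.subsets is None:
                for chrom, start, end in self.members:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                label_of = {}
                for lab, idxs in self.subsets.items():
                    for i in idxs:
                        label_of[i] = lab
                for i, (chrom, start, end) in enumerate(self.members):
                    fh.write(f"{chrom}\t{start}\t{end}\t{label_of[i]}\n")

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "LocusSet":
        members: list[tuple[str, int, int]] = []
        labels: list[str | None] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                members.append((parts[0], int(parts[1]), int(parts[2])))
                labels.append(parts[3] if len(parts) > 3 else None)
        subsets: dict[str, list[int]] | None = None
        if any(l is not None for l in labels):
            subsets = {}
            for i, lab in enumerate(labels):
                subsets.setdefault(lab if lab is not None else "_", []).append(i)
        return cls(name or Path(path).stem, members, subsets)


@dataclass
class GeneAnnotation:
    """Gene id -> interval table; genes map to beads at their midpoint bin."""

    genes: dict[str, tuple[str, int, int]]

    def midpoint_bead(self, layout: GenomeLayout, gene: str) -> int:
        chrom, start, end = self.genes[gene]
        return layout.bead_of(chrom, (start + end) // 2)

    def beads(self, layout: GenomeLayout) -> dict[str, int]:
        return {g: self.midpoint_bead(layout, g) for g in self.genes}

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, (chrom, start, end) in self.genes.items():
                fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        genes: dict[str, tuple[str, int, int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, gene = line.split("\t")[:4]
                genes[gene] = (chrom, int(start), int(end))
        return cls(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
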