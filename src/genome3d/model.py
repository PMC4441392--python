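"""3D bead model representation and coordinate export/import (XYZ, PDB).

Coordinates are in nanometres with the origin at the nucleus centre.
PDB export writes one CA pseudo-atom per bead (coordinates in Angstrom,
i.e. nm x 10) with one chain per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layout import GenomeLayout

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


@dataclass
class Model3D:
    layout: GenomeLayout
    coords: np.ndarray  # (N, 3) float, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.layout.n_beads, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.layout.n_beads} beads"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    def pairwise_distances(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.coords[i] - self.coords[j], axis=-1)

    def all_pair_distances(self) -> np.ndarray:
        """Condensed distance vector over all bead pairs (scipy pdist order)."""
        from scipy.spatial.distance import pdist

        return pdist(self.coords)

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.coords, axis=1)

    # -- export / import ----------------------------------------------------

    def to_xyz(self, path: str | Path) -> None:
        lines = [str(self.layout.n_beads), "genome3d model (nm); columns: chrom:bead x y z"]
        for bead in range(self.layout.n_beads):
            chrom, local = self.layout.bead_chrom(bead)
            x, y, z = self.coords[bead]
            lines.append(f"{chrom}:{local}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_xyz(cls, path: str | Path, layout: GenomeLayout) -> "Model3D":
        lines = Path(path).read_text().splitlines()
        n = int(lines[0].strip())
        coords = np.empty((n, 3), dtype=float)
        for k, line in enumerate(lines[2 : 2 + n]):
            parts = line.split("\t")
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        return cls(layout, coords)

    def to_pdb(self, path: str | Path) -> None:
        """One CA atom per bead, chain per chromosome.

        Coordinates are written as nm x scale with the largest power-of-ten
        scale (at most 10, i.e. Angstrom) that fits the fixed PDB columns;
        the scale is recorded in a REMARK header.
        """
        scale = 10.0
        limit = np.abs(self.coords).max(initial=0.0)
        while scale > 1e-6 and limit * scale >= 1000:
            scale /= 10.0
        lines = [f"REMARK   coordinates = nm x {scale:g}"]
        serial = 0
        for ci, (chrom, _) in enumerate(self.layout.chromosomes):
            chain = _CHAIN_ALPHABET[ci % len(_CHAIN_ALPHABET)]
            n = self.layout.n_beads_of(chrom)
            offset = self.layout.chrom_offsets()[chrom]
            for local in range(n):
                serial += 1
                x, y, z = self.coords[offset + local] * scale
                lines.append(
                    f"ATOM  {serial:5d}  CA  BED {chain}{(local + 1) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            lines.append(f"TER   {serial + 1:5d}      BED {chain}")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_pdb(cls, path: str | Path, layout: GenomeLayout) -> "Model3D":
        scale = 10.0
        coords = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("REMARK") and "nm x" in line:
                scale = float(line.rsplit("x", 1)[1])
            elif line.startswith("ATOM"):
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                coords.append((x / scale, y / scale, z / scale))
        return cls(layout, np.asarray(coords))


def export_model(model: Model3D, path: str | Path, format: str | None = None) -> None:
    """Write ``model`` to ``path`` as XYZ or PDB (inferred from suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        model.to_xyz(path)
    elif fmt == "pdb":
        model.to_pdb(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def import_model(path: str | Path, layout: GenomeLayout, format: str | None = None) -> Model3D:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return Model3D.from_xyz(path, layout)
    if fmt == "pdb":
        return Model3D.from_pdb(path, layout)
    raise ValueError(f"unknown model format {fmt!r}")
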