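"""Synthetic ground-truth genomes, contact maps, CDS and ortholog tables.

Generates multi-chromosome bead structures confined in a sphere with
clustered centromeres and peripheral telomeres, contact counts decaying
with spatial distance, planted co-localized locus sets, coding sequences
whose codon composition tracks spatial clustering, and a jittered
"organism B" copy with an ortholog table.  Every generator is
seed-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import DistanceMap
from .layout import GeneAnnotation, GenomeLayout, LocusSet
from .model import Model3D
from .predicted import CODONS, OrthologTable
from .reconstruct import ReconstructionConfig, max_violation

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    layout: GenomeLayout
    true_model: Model3D
    planted_sets: list[LocusSet]
    genes: GeneAnnotation
    cds: dict[str, str] = field(default_factory=dict)
    layout_b: GenomeLayout | None = None
    model_b: Model3D | None = None
    genes_b: GeneAnnotation | None = None
    orthologs: OrthologTable | None = None
    dmap_b: DistanceMap | None = None
    params: dict = field(default_factory=dict)

    def true_distance_map(self, include_adjacent: bool = True) -> DistanceMap:
        """Complete noiseless distance map over all distinct bead pairs."""
        n = self.layout.n_beads
        iu, ju = np.triu_indices(n, k=1)
        if not include_adjacent:
            lo, hi = self.layout.adjacent_pairs()
            adj = set(zip(lo.tolist(), hi.tolist()))
            keep = np.array([(a, b) not in adj for a, b in zip(iu, ju)])
            iu, ju = iu[keep], ju[keep]
        d = self.true_model.pairwise_distances(iu, ju)
        return DistanceMap(self.layout, iu, ju, d)


# ---------------------------------------------------------------------------
# genome / structure generation


def _repair(
    coords: np.ndarray,
    layout: GenomeLayout,
    config: ReconstructionConfig,
    pinned: dict[int, np.ndarray] | None = None,
    max_rounds: int = 500,
) -> np.ndarray:
    """Alternating projection onto nucleus / adjacency / separation constraints."""
    R = config.nucleus_radius_nm * 0.995
    bound = config.adjacent_bound_nm(layout) * 0.995
    sep = config.min_separation_nm * 1.02
    lo, hi = layout.adjacent_pairs()
    adj = set(zip(lo.tolist(), hi.tolist()))
    pinned = pinned or {}
    x = coords.copy()
    for _ in range(max_rounds):
        # nucleus
        r = np.linalg.norm(x, axis=1)
        over = r > R
        x[over] *= (R / r[over])[:, None]
        # separation: push close non-adjacent pairs apart
        tree = cKDTree(x)
        pairs = tree.query_pairs(sep, output_type="ndarray")
        moved = False
        for a, b in pairs:
            a, b = (int(a), int(b)) if a < b else (int(b), int(a))
            if (a, b) in adj:
                continue
            dvec = x[a] - x[b]
            d = np.linalg.norm(dvec)
            if d < 1e-9:
                dvec = np.random.default_rng(a * 7919 + b).normal(size=3)
                d = np.linalg.norm(dvec)
            push = (sep - d) / 2.0
            x[a] += dvec / d * push
            x[b] -= dvec / d * push
            moved = True
        # adjacency: pull overstretched neighbors together
        d = np.linalg.norm(x[lo] - x[hi], axis=1)
        stretch = d > bound
        for a, b in zip(lo[stretch], hi[stretch]):
            dvec = x[a] - x[b]
            dd = np.linalg.norm(dvec)
            pull = (dd - bound) / 2.0
            x[a] -= dvec / dd * pull
            x[b] += dvec / dd * pull
            moved = True
        for bead, xyz in pinned.items():
            x[bead] = xyz
        mv = max_violation(Model3D(layout, x), config)
        if mv <= 1e-9:
            return x
        if not moved and not over.any():
            break
    mv = max_violation(Model3D(layout, x), config)
    if mv > 1e-6:
        raise RuntimeError(f"could not repair structure to feasibility (violation {mv:.3g} nm)")
    return x


def make_genome(
    n_chrom: int,
    beads_per_chrom: int | list[int],
    config: ReconstructionConfig | None = None,
    seed: int = 0,
    chrom_prefix: str = "chr",
) -> tuple[GenomeLayout, Model3D]:
    """Generate a layout and a feasible ground-truth structure.

    Chromosomes are confined random walks; centromere beads (mid-chromosome)
    are tethered to a small spherical cap, telomere beads are drawn toward
    the periphery (radius > 0.8 R).  The returned structure satisfies the
    reconstruction constraints of ``config``.
    """
    config = config or ReconstructionConfig()
    rng = np.random.default_rng(seed)
    if isinstance(beads_per_chrom, int):
        beads_per_chrom = [beads_per_chrom] * n_chrom
    if len(beads_per_chrom) != n_chrom:
        raise ValueError("beads_per_chrom length mismatch")
    res = 10_000
    chroms = []
    centromeres = {}
    for c in range(n_chrom):
        name = f"{chrom_prefix}{c + 1}"
        chroms.append((name, beads_per_chrom[c] * res))
        centromeres[name] = (beads_per_chrom[c] // 2) * res + res // 2
    layout = GenomeLayout(tuple(chroms), resolution_bp=res, centromeres=centromeres)

    R = config.nucleus_radius_nm
    bound = config.adjacent_bound_nm(layout)
    step = 0.75 * bound
    cen_center = np.array([0.0, 0.0, 0.55 * R])
    coords = np.empty((layout.n_beads, 3))
    offsets = layout.chrom_offsets()
    for name, _ in layout.chromosomes:
        n = layout.n_beads_of(name)
        off = offsets[name]
        cen_local = layout.bead_of(name, layout.centromeres[name]) - off
        cen_pos = cen_center + rng.normal(scale=0.06 * R, size=3)
        coords[off + cen_local] = cen_pos
        # territory direction shared by both arms keeps the chromosome compact
        territory = rng.normal(size=3)
        territory[2] = -abs(territory[2]) - 0.3  # away from the centromere cap
        territory /= np.linalg.norm(territory)
        for direction, end_local in ((-1, 0), (+1, n - 1)):
            arm_len = abs(end_local - cen_local)
            if arm_len == 0:
                continue
            anchor = territory + 0.35 * rng.normal(size=3)
            anchor = anchor / np.linalg.norm(anchor) * 0.88 * R
            pos = cen_pos.copy()
            for k in range(1, arm_len + 1):
                frac = k / arm_len
                drift = anchor - pos
                drift_n = np.linalg.norm(drift)
                steps_left = arm_len - k + 1
                pull = min(1.0, drift_n / (steps_left * step))  # stronger pull when behind
                direction_vec = (pull * 1.5 + 0.4 * frac) * drift / max(drift_n, 1e-9) + rng.normal(scale=0.8, size=3)
                direction_vec /= np.linalg.norm(direction_vec)
                pos = pos + direction_vec * step * rng.uniform(0.8, 1.0)
                r = np.linalg.norm(pos)
                if r > 0.97 * R:
                    pos *= (0.97 * R) / r
                coords[off + cen_local + direction * k] = pos
    coords = _repair(coords, layout, config)
    return layout, Model3D(layout, coords)


def place_genes(
    layout: GenomeLayout,
    genes_per_bead: int = 2,
    gene_len_bp: int = 1200,
    seed: int = 0,
    prefix: str = "g",
) -> GeneAnnotation:
    """Place non-overlapping genes inside beads (midpoint within the bead)."""
    rng = np.random.default_rng(seed)
    res = layout.resolution_bp
    genes: dict[str, tuple[str, int, int]] = {}
    k = 0
    for chrom, length in layout.chromosomes:
        n = layout.n_beads_of(chrom)
        for local in range(n):
            bin_start = local * res
            bin_len = min(res, length - bin_start)
            if bin_len < gene_len_bp * genes_per_bead:
                continue
            slot = bin_len // genes_per_bead
            for s in range(genes_per_bead):
                jitter = int(rng.integers(0, max(1, slot - gene_len_bp)))
                start = bin_start + s * slot + jitter
                genes[f"{prefix}{k:04d}"] = (chrom, start, start + gene_len_bp)
                k += 1
    return GeneAnnotation(genes)


def plant_compact_set(
    truth_model: Model3D,
    layout: GenomeLayout,
    size: int = 8,
    n_subsets: int = 3,
    seed: int = 0,
    name: str = "planted_compact",
) -> LocusSet:
    """Spatially compact subsets of beads around random centers.

    Each subset holds the ``size`` beads nearest to a random center bead,
    kept linearly spread (>= 5 beads apart on a chromosome) so that their
    co-localization is a spatial signal rather than chain adjacency.  The
    set's NSD is the mean over subsets; by construction it is well below 1.
    """
    rng = np.random.default_rng(seed)
    chrom_ids = layout.bead_chrom_ids()
    used: set[int] = set()
    members: list[tuple[str, int, int]] = []
    subsets: dict[str, list[int]] = {}
    res = layout.resolution_bp
    for s in range(n_subsets):
        center = int(rng.integers(layout.n_beads))
        d = np.linalg.norm(truth_model.coords - truth_model.coords[center], axis=1)
        beads: list[int] = []
        for b in np.argsort(d):
            b = int(b)
            if b in used:
                continue
            if all(chrom_ids[b] != chrom_ids[o] or abs(b - o) >= 5 for o in beads):
                beads.append(b)
            if len(beads) == size:
                break
        used.update(beads)
        idxs = []
        for b in sorted(beads):
            chrom, local = layout.bead_chrom(b)
            start = local * res + res // 4
            idxs.append(len(members))
            members.append((chrom, start, min(start + res // 2, layout.length_of(chrom))))
        subsets[f"cluster{s + 1}"] = idxs
    return LocusSet(name, members, subsets if n_subsets > 1 else None)


def plant_random_set(
    layout: GenomeLayout,
    size: int = 8,
    seed: int = 0,
    name: str = "planted_random",
) -> LocusSet:
    rng = np.random.default_rng(seed)
    beads = rng.choice(layout.n_beads, size=size, replace=False)
    res = layout.resolution_bp
    members = []
    for b in sorted(beads.tolist()):
        chrom, local = layout.bead_chrom(b)
        start = local * res + res // 4
        members.append((chrom, start, min(start + res // 2, layout.length_of(chrom))))
    return LocusSet(name, members)


# ---------------------------------------------------------------------------
# contacts


def simulate_contacts(
    truth: Model3D,
    reads: int,
    alpha: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson contact records with rate proportional to distance^(-alpha).

    Returns fragment-level records (bp coordinates inside the bead bins)
    with total count approximately ``reads``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    layout = truth.layout
    rng = np.random.default_rng(seed)
    cols = ["chrom_i", "pos_i", "chrom_j", "pos_j", "count"]
    if reads == 0:
        return pd.DataFrame(columns=cols)
    n = layout.n_beads
    iu, ju = np.triu_indices(n, k=1)
    d = truth.pairwise_distances(iu, ju)
    rates = d ** (-alpha)
    rates *= reads / rates.sum()
    counts = rng.poisson(rates)
    nz = counts > 0
    iu, ju, counts = iu[nz], ju[nz], counts[nz]
    res = layout.resolution_bp
    rows = []
    for a, b, c in zip(iu, ju, counts):
        ca, la = layout.bead_chrom(int(a))
        cb, lb = layout.bead_chrom(int(b))
        max_a = min(res, layout.length_of(ca) - la * res)
        max_b = min(res, layout.length_of(cb) - lb * res)
        pa = la * res + int(rng.integers(max_a))
        pb = lb * res + int(rng.integers(max_b))
        rows.append((ca, pa, cb, pb, int(c)))
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# coding sequences


def make_cds(
    truth: Model3D,
    genes: GeneAnnotation,
    k_clusters: int = 4,
    noise: float = 0.2,
    codons_per_gene: int = 200,
    seed: int = 0,
) -> dict[str, str]:
    """CDS per gene whose codon composition follows spatial clusters.

    Genes are k-means clustered on their bead coordinates; each cluster gets
    a Dirichlet codon-frequency center.  A gene's codon distribution is a
    soft mixture of the cluster centers weighted by proximity to the cluster
    centroids, so codon composition varies smoothly with spatial position,
    then mixed with a uniform noise floor ``(mix + noise/64) / (1 + noise)``.
    Larger ``noise`` washes out the spatial signal.
    """
    from scipy.cluster.vq import kmeans2

    rng = np.random.default_rng(seed)
    layout = truth.layout
    gene_ids = sorted(genes.genes)
    beads = genes.beads(layout)
    pts = np.array([truth.coords[beads[g]] for g in gene_ids])
    centroids, labels = kmeans2(pts, k_clusters, minit="++", seed=rng.integers(2**31))
    centers = rng.dirichlet(np.full(64, 0.3), size=k_clusters)
    flat = np.full(64, 1.0 / 64.0)
    # softness scale: a fraction of the typical centroid spacing
    from scipy.spatial.distance import cdist, pdist

    tau = 0.35 * float(np.median(pdist(centroids))) if k_clusters > 1 else 1.0
    d_to_centroids = cdist(pts, centroids)
    logw = -d_to_centroids / max(tau, 1e-9)
    logw -= logw.max(axis=1, keepdims=True)
    weights = np.exp(logw)
    weights /= weights.sum(axis=1, keepdims=True)
    out: dict[str, str] = {}
    for gi, g in enumerate(gene_ids):
        mix = weights[gi] @ centers
        probs = (mix + noise * flat) / (1.0 + noise)
        probs = probs / probs.sum()
        draw = rng.choice(64, size=codons_per_gene, p=probs)
        out[g] = "".join(CODONS[c] for c in draw)
    return out


def write_fasta(cds: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(cds):
            fh.write(f">{gene}\n")
            seq = cds[gene]
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


# ---------------------------------------------------------------------------
# organism B


def make_organism_b(
    truth: SyntheticTruth,
    jitter_nm: float = 50.0,
    ortho_coverage: float = 0.9,
    one_to_many_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[GenomeLayout, Model3D, GeneAnnotation, OrthologTable, DistanceMap]:
    """A jittered copy of the truth with an ortholog map and exact distances.

    Organism B has the same chromosome structure (relabeled), coordinates
    perturbed by isotropic Gaussian noise of scale ``jitter_nm``, genes at
    the same intervals, and an ortholog table covering ``ortho_coverage`` of
    the genes (mostly 1:1, with a 1:many fraction).  The returned distance
    map holds the exact pairwise bead distances of model B.
    """
    if jitter_nm < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    layout_a = truth.layout
    layout_b = GenomeLayout(
        tuple((f"B_{name}", length) for name, length in layout_a.chromosomes),
        resolution_bp=layout_a.resolution_bp,
        centromeres={f"B_{c}": p for c, p in layout_a.centromeres.items()},
    )
    coords_b = truth.true_model.coords + rng.normal(scale=jitter_nm, size=(layout_a.n_beads, 3))
    model_b = Model3D(layout_b, coords_b)
    genes_b = GeneAnnotation(
        {f"b_{g}": (f"B_{chrom}", s, e) for g, (chrom, s, e) in truth.genes.genes.items()}
    )
    gene_ids = sorted(truth.genes.genes)
    n_cov = int(round(ortho_coverage * len(gene_ids)))
    covered = sorted(rng.choice(len(gene_ids), size=n_cov, replace=False).tolist())
    families: dict[str, set[str]] = {}
    all_b = sorted(genes_b.genes)
    for idx in covered:
        g = gene_ids[idx]
        fam = {f"b_{g}"}
        if rng.random() < one_to_many_fraction:
            fam.add(all_b[int(rng.integers(len(all_b)))])
        families[g] = fam
    orthologs = OrthologTable(families)
    n = layout_b.n_beads
    iu, ju = np.triu_indices(n, k=1)
    dmap_b = DistanceMap(layout_b, iu, ju, model_b.pairwise_distances(iu, ju))
    return layout_b, model_b, genes_b, orthologs, dmap_b


# ---------------------------------------------------------------------------
# presets


PRESETS = {
    "small": dict(n_chrom=3, beads_per_chrom=50, genes_per_bead=2, reads=200_000),
    "medium": dict(n_chrom=6, beads_per_chrom=80, genes_per_bead=2, reads=1_000_000),
}


def make_truth(
    preset: str = "small",
    seed: int = 0,
    config: ReconstructionConfig | None = None,
    jitter_nm: float = 50.0,
    cds_noise: float = 0.2,
) -> SyntheticTruth:
    """Full synthetic dataset: structure, genes, planted sets, CDS, organism B."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    p = PRESETS[preset]
    config = config or ReconstructionConfig()
    layout, model = make_genome(p["n_chrom"], p["beads_per_chrom"], config, seed=seed)
    genes = place_genes(layout, genes_per_bead=p["genes_per_bead"], seed=seed + 1)
    planted = [
        plant_compact_set(model, layout, seed=seed + 2),
        plant_random_set(layout, seed=seed + 3),
    ]
    truth = SyntheticTruth(
        layout=layout,
        true_model=model,
        planted_sets=planted,
        genes=genes,
        params={"preset": preset, "seed": seed, "jitter_nm": jitter_nm, "cds_noise": cds_noise},
    )
    truth.cds = make_cds(model, genes, noise=cds_noise, seed=seed + 4)
    truth.layout_b, truth.model_b, truth.genes_b, truth.orthologs, truth.dmap_b = make_organism_b(
        truth, jitter_nm=jitter_nm, seed=seed + 5
    )
    return truth


def write_dataset(truth: SyntheticTruth, outdir: str | Path, reads: int | None = None, seed: int = 0) -> None:
    """Write the full synthetic dataset as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.layout.to_tsv(out / "genome.tsv")
    truth.true_model.to_xyz(out / "truth.xyz")
    truth.genes.to_bed(out / "genes.bed")
    for ls in truth.planted_sets:
        ls.to_bed(out / f"{ls.name}.bed")
    write_fasta(truth.cds, out / "cds.fasta")
    if truth.orthologs is not None:
        truth.orthologs.to_tsv(out / "orthologs.tsv")
        truth.layout_b.to_tsv(out / "genome_b.tsv")
        truth.model_b.to_xyz(out / "truth_b.xyz")
        truth.genes_b.to_bed(out / "genes_b.bed")
        truth.dmap_b.to_tsv(out / "distances_b.tsv")
    preset = truth.params.get("preset", "small")
    n_reads = reads if reads is not None else PRESETS[preset]["reads"]
    records = simulate_contacts(truth.true_model, n_reads, seed=seed)
    records.to_csv(out / "contacts.tsv", sep="\t", index=False)
    (out / "params.json").write_text(json.dumps(truth.params, indent=2) + "\n")
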