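"""Model quality battery: co-localization, arm ratios, similarity, correlations.

Every test reports a scalar together with its improvement direction, so
category comparisons know whether lower or higher is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .layout import GeneAnnotation, GenomeLayout, LocusSet
from .model import Model3D

logger = logging.getLogger(__name__)

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"

PPI_DISCONNECTED = 255  # finite large hop count for disconnected pairs


@dataclass
class BenchmarkReport:
    """name -> (value, direction); subset values kept for partitioned sets."""

    values: dict[str, float] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)
    subset_values: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, name: str, value: float, direction: str, subsets: dict[str, float] | None = None):
        self.values[name] = value
        self.directions[name] = direction
        if subsets is not None:
            self.subset_values[name] = subsets

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "directions": self.directions,
            "subset_values": self.subset_values,
        }


# ---------------------------------------------------------------------------
# co-localization


def _mean_pairwise(coords: np.ndarray) -> float:
    return float(pdist(coords).mean())


def nsd(
    model: Model3D,
    locus_set: LocusSet | Sequence[int],
    universe: Sequence[int] | None = None,
    n_random: int = 100,
    seed: int = 0,
) -> float:
    """Normalized set distance: mean within-set 3D distance over random expectation.

    The set's mean pairwise distance is divided by the mean over ``n_random``
    random equal-size sets drawn from ``universe`` (gene beads for gene sets,
    the full bead grid otherwise).  Values below 1 indicate co-localization.
    For a partitioned set the subset NSDs are averaged.
    """
    if isinstance(locus_set, LocusSet):
        groups = list(locus_set.subset_beads(model.layout).values())
    else:
        groups = [list(locus_set)]
    if universe is None:
        universe = np.arange(model.layout.n_beads)
    universe = np.asarray(universe)
    rng = np.random.default_rng(seed)
    vals = []
    for beads in groups:
        beads = np.asarray(beads)
        if len(beads) < 2:
            raise ValueError("set must have at least 2 mapped members")
        observed = _mean_pairwise(model.coords[beads])
        rand_means = np.empty(n_random)
        for r in range(n_random):
            draw = rng.choice(universe, size=len(beads), replace=False)
            rand_means[r] = _mean_pairwise(model.coords[draw])
        vals.append(observed / rand_means.mean())
    return float(np.mean(vals))


def telomere_radius(model: Model3D, layout: GenomeLayout | None = None) -> float:
    """Mean distance of telomere beads from the nucleus centre."""
    layout = layout or model.layout
    beads = layout.telomere_beads()
    return float(np.linalg.norm(model.coords[beads], axis=1).mean())


# ---------------------------------------------------------------------------
# chromosome arms


def _arms(layout: GenomeLayout) -> list[tuple[str, np.ndarray]]:
    """Bead runs on either side of each centromere bead (which joins neither arm)."""
    arms = []
    offsets = layout.chrom_offsets()
    for chrom, _ in layout.chromosomes:
        if chrom not in layout.centromeres:
            logger.info("arm analysis: no centromere for %s, skipped", chrom)
            continue
        cen = layout.bead_of(chrom, layout.centromeres[chrom])
        first = offsets[chrom]
        last = first + layout.n_beads_of(chrom) - 1
        left = np.arange(first, cen)
        right = np.arange(cen + 1, last + 1)
        if len(left):
            arms.append((chrom, left))
        if len(right):
            arms.append((chrom, right))
    return arms


def _mean_between(coords: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1)
    return float(d.mean())


def arm_ratios(
    model: Model3D,
    layout: GenomeLayout | None = None,
    short_arm_bp: int = 250_000,
) -> dict[str, float]:
    """Three mean-distance ratios over chromosome arms at bead resolution.

    ``cis_vs_trans``: distance between the two arms of a chromosome over the
    distance to all other chromosomes' arms, averaged over chromosomes.
    ``short_vs_long``: mean distance among short arms (< ``short_arm_bp``)
    over mean distance among long arms.  ``self_vs_else``: within-arm spread
    over distance to all other arms, averaged over arms.
    """
    layout = layout or model.layout
    arms = _arms(layout)
    coords = model.coords
    res = layout.resolution_bp

    # cis vs trans
    cis_ratios = []
    by_chrom: dict[str, list[np.ndarray]] = {}
    for chrom, beads in arms:
        by_chrom.setdefault(chrom, []).append(beads)
    for chrom, chrom_arms in by_chrom.items():
        if len(chrom_arms) != 2:
            continue
        cis = _mean_between(coords, chrom_arms[0], chrom_arms[1])
        others = [b for c, b in arms if c != chrom]
        if not others:
            continue
        trans_vals = [
            _mean_between(coords, own, other) for own in chrom_arms for other in others
        ]
        cis_ratios.append(cis / np.mean(trans_vals))
    cis_vs_trans = float(np.mean(cis_ratios)) if cis_ratios else float("nan")

    # short vs long
    short = [b for _, b in arms if len(b) * res < short_arm_bp]
    long_ = [b for _, b in arms if len(b) * res >= short_arm_bp]

    def group_mean(group: list[np.ndarray]) -> float:
        vals = [
            _mean_between(coords, group[x], group[y])
            for x in range(len(group))
            for y in range(x + 1, len(group))
        ]
        return float(np.mean(vals)) if vals else float("nan")

    sm, lm = group_mean(short), group_mean(long_)
    short_vs_long = sm / lm if np.isfinite(sm) and np.isfinite(lm) else float("nan")

    # self vs else
    self_ratios = []
    for k, (chrom, beads) in enumerate(arms):
        if len(beads) < 2:
            continue
        within = _mean_pairwise(coords[beads])
        others = [b for x, (_, b) in enumerate(arms) if x != k]
        if not others:
            continue
        else_vals = [_mean_between(coords, beads, other) for other in others]
        self_ratios.append(within / np.mean(else_vals))
    self_vs_else = float(np.mean(self_ratios)) if self_ratios else float("nan")

    return {
        "cis_vs_trans": cis_vs_trans,
        "short_vs_long": short_vs_long,
        "self_vs_else": self_vs_else,
    }


# ---------------------------------------------------------------------------
# similarity & correlations


def model_similarity(models: Sequence[Model3D]) -> float:
    """Mean Spearman correlation of all bead-pair distances over model pairs."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    layouts = {id(m.layout): m.layout.n_beads for m in models}
    if len({m.layout.n_beads for m in models}) != 1:
        raise ValueError("models must share a layout")
    dvecs = [m.all_pair_distances() for m in models]
    rhos = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            rho, _ = spearmanr(dvecs[a], dvecs[b])
            rhos.append(rho)
    return float(np.mean(rhos))


def pairwise_model_similarities(models: Sequence[Model3D]) -> np.ndarray:
    """Condensed vector of pairwise distance-vector Spearman correlations."""
    dvecs = [m.all_pair_distances() for m in models]
    out = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            out.append(spearmanr(dvecs[a], dvecs[b])[0])
    return np.asarray(out)


def binned_spearman(
    model_dist: np.ndarray,
    covariate: np.ndarray,
    n_bins: int = 2000,
) -> float:
    """Spearman correlation between bin-mean covariate and bin-mean 3D distance.

    Pairs are sorted by covariate and split into ``n_bins`` equal-count bins;
    the correlation is computed across bin means.  ``n_bins`` is reduced when
    there are fewer pairs than bins.
    """
    model_dist = np.asarray(model_dist, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if model_dist.shape != covariate.shape:
        raise ValueError("mismatched vectors")
    if np.all(covariate == covariate[0]):
        logger.warning("binned_spearman: constant covariate")
        return float("nan")
    n = len(covariate)
    if n < n_bins:
        logger.info("binned_spearman: reducing n_bins from %d to %d", n_bins, n)
        n_bins = n
    order = np.argsort(covariate, kind="stable")
    cov_s, dist_s = covariate[order], model_dist[order]
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    mean_c = np.array([cov_s[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    mean_d = np.array([dist_s[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    rho, _ = spearmanr(mean_c, mean_d)
    return float(rho)


def pa_distance(p: float, q: float) -> float:
    """Normalized abundance distance 2|p - q| / (p + q), in [0, 2)."""
    if p + q <= 0:
        raise ValueError("undefined for p + q <= 0")
    return 2.0 * abs(p - q) / (p + q)


def ppi_pair_distance(
    edges: Iterable[tuple[str, str]],
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Unweighted shortest-path hops per gene pair; disconnected/absent -> 255."""
    g = nx.Graph()
    g.add_edges_from(edges)
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        if a in g and b in g:
            try:
                out[k] = nx.shortest_path_length(g, a, b)
                continue
            except nx.NetworkXNoPath:
                pass
        out[k] = PPI_DISCONNECTED
    return out


# ---------------------------------------------------------------------------
# telomere clustering


def telomere_cluster(models: Sequence[Model3D]):
    """Average-linkage clustering of the cross-model mean telomere distances.

    Returns ``(mean_matrix, linkage_tree, leaf_order)`` where ``mean_matrix``
    is the telomere-telomere distance matrix averaged across models.
    """
    if not models:
        raise ValueError("need at least one model")
    beads = models[0].layout.telomere_beads()
    mats = [squareform(pdist(m.coords[beads])) for m in models]
    mean_mat = np.mean(mats, axis=0)
    tree = linkage(squareform(mean_mat, checks=False), method="average")
    order = leaves_list(tree)
    return mean_mat, tree, order


# ---------------------------------------------------------------------------
# assembling a report


def gene_pair_vectors(
    model: Model3D,
    genes: GeneAnnotation,
    covariates: Mapping[tuple[str, str], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (3D distance, covariate) vectors over the covariate's gene pairs."""
    beads = genes.beads(model.layout)
    d, c = [], []
    for (a, b), val in covariates.items():
        if a in beads and b in beads:
            d.append(np.linalg.norm(model.coords[beads[a]] - model.coords[beads[b]]))
            c.append(val)
    return np.asarray(d), np.asarray(c)


def run_battery(
    model: Model3D,
    locus_sets: Sequence[LocusSet] = (),
    genes: GeneAnnotation | None = None,
    covariates: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    covariate_directions: Mapping[str, str] | None = None,
    n_random: int = 100,
    n_bins: int = 2000,
    seed: int = 0,
) -> BenchmarkReport:
    """Run the standard battery on one model and return a directional report."""
    report = BenchmarkReport()
    layout = model.layout
    cen_beads = list(layout.centromere_beads().values())
    if len(cen_beads) >= 2:
        report.add("centromere_nsd", nsd(model, cen_beads, n_random=n_random, seed=seed), LOWER_BETTER)
    report.add("telomere_radius", telomere_radius(model), HIGHER_BETTER)
    ratios = arm_ratios(model)
    report.add("cis_vs_trans", ratios["cis_vs_trans"], LOWER_BETTER)
    if np.isfinite(ratios["short_vs_long"]):
        report.add("short_vs_long", ratios["short_vs_long"], LOWER_BETTER)
    report.add("self_vs_else", ratios["self_vs_else"], LOWER_BETTER)
    gene_universe = None
    if genes is not None:
        gene_universe = np.array(sorted(genes.beads(layout).values()))
    for ls in locus_sets:
        subset_beads = ls.subset_beads(layout)
        subs = {
            lab: nsd(model, beads, universe=gene_universe if genes else None, n_random=n_random, seed=seed)
            for lab, beads in subset_beads.items()
            if len(beads) >= 2
        }
        if subs:
            report.add(f"nsd_{ls.name}", float(np.mean(list(subs.values()))), LOWER_BETTER, subs)
    if covariates and genes is not None:
        for name, table in covariates.items():
            d, c = gene_pair_vectors(model, genes, table)
            rho = binned_spearman(d, c, n_bins=n_bins) if len(d) >= 3 else float("nan")
            direction = (covariate_directions or {}).get(name, HIGHER_BETTER)
            report.add(f"corr_{name}", rho, direction)
    return report
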