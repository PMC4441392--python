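"""End-to-end benchmark experiments on synthetic data.

Shared drivers for the property-style validation battery: oracle recovery,
the sparseness-similarity trend, real-vs-permuted contrasts, and the
predicted-distance integration experiment.  Each driver is deterministic
given its seed and sized to run on one CPU in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .benchmark import (
    HIGHER_BETTER,
    LOWER_BETTER,
    BenchmarkReport,
    nsd,
    run_battery,
)
from .contacts import DistanceMap, bin_contacts, contacts_to_distances, fit_distance_profile, ice_correct
from .gstats import CategoryResults, category_permutation_test, wilcoxon_one_tail
from .layout import GenomeLayout
from .model import Model3D
from .predicted import (
    CUFS_BAND,
    ORTHO_BAND,
    codon_frequencies,
    cufs_matrix,
    gene_pair_distances,
    gene_pairs_to_bins,
    project_orthologous,
    scale_to_median,
    select_quantile_band,
)
from .reconstruct import ReconstructionConfig, reconstruct
from .sampling import permute_coordinates, poor_get_richer_merge, uniform_sample
from .synthetic import SyntheticTruth, make_truth, simulate_contacts

logger = logging.getLogger(__name__)

FAST_RECON = dict(n_starts=1, max_iter=1000)


def _recon(targets: DistanceMap, layout: GenomeLayout, seed: int) -> Model3D:
    cfg = ReconstructionConfig(seed=seed, **FAST_RECON)
    return reconstruct(targets, layout, cfg).model


# ---------------------------------------------------------------------------


def oracle_recovery(seed: int = 1) -> dict:
    """Reconstruct from the complete noiseless truth map; report recovery."""
    from .reconstruct import objective

    truth = make_truth("small", seed=seed)
    dmap = truth.true_distance_map()
    model = _recon(dmap, truth.layout, seed=seed + 10)
    rho = float(spearmanr(model.all_pair_distances(), truth.true_model.all_pair_distances())[0])
    return {
        "spearman": rho,
        "objective_of_truth": objective(truth.true_model, dmap),
        "n_beads": truth.layout.n_beads,
    }


def contact_derived_map(truth: SyntheticTruth, reads: int = 200_000, alpha: float = 1.5, seed: int = 2) -> DistanceMap:
    """Noisy distance map via the full contact pipeline (Poisson, ICE, profile)."""
    records = simulate_contacts(truth.true_model, reads, alpha=alpha, seed=seed)
    cmap = ice_correct(bin_contacts(records, truth.layout))
    profile = fit_distance_profile(cmap)
    return contacts_to_distances(cmap, profile)


def sparseness_trend(
    seed: int = 1,
    fractions: tuple[float, ...] = (0.01, 0.1, 1.0),
    n_replicates: int = 5,
) -> dict[float, float]:
    """Median inter-replicate model similarity per sampling fraction.

    Replicates are reconstructions from independent uniform samples of a
    contact-derived (noisy) distance map.
    """
    truth = make_truth("small", seed=seed)
    dmap = contact_derived_map(truth, seed=seed + 1)
    out: dict[float, float] = {}
    for frac in fractions:
        models = []
        for rep in range(n_replicates):
            sub = uniform_sample(dmap, frac, seed=100 + rep) if frac < 1 else dmap
            models.append(_recon(sub, truth.layout, seed=1000 * rep + int(frac * 1000)))
        dvecs = [m.all_pair_distances() for m in models]
        sims = [
            spearmanr(dvecs[a], dvecs[b])[0]
            for a in range(len(models))
            for b in range(a + 1, len(models))
        ]
        out[frac] = float(np.median(sims))
    return out


def planted_contrast(
    seed: int = 1,
    n_models: int = 10,
    fraction: float = 0.05,
) -> dict:
    """Planted compact-set NSD: real-map vs permuted-map reconstructions."""
    truth = make_truth("small", seed=seed)
    dmap = truth.true_distance_map()
    planted = truth.planted_sets[0]
    real, perm = [], []
    for rep in range(n_models):
        sub = uniform_sample(dmap, fraction, seed=200 + rep)
        model = _recon(sub, truth.layout, seed=5000 + rep)
        real.append(nsd(model, planted, seed=rep))
        shuffled = permute_coordinates(sub, seed=300 + rep)
        model_r = _recon(shuffled, truth.layout, seed=6000 + rep)
        perm.append(nsd(model_r, planted, seed=rep))
    p = wilcoxon_one_tail(perm, real, paired=False, alternative="greater")
    return {"real_nsd": real, "permuted_nsd": perm, "p": p}


# ---------------------------------------------------------------------------
# integration experiment


@dataclass
class IntegrationResult:
    categories: dict[str, CategoryResults]
    planted_nsd: dict[str, list[float]]
    similarity: dict[str, list[float]]
    p_nsd: dict[str, float]
    p_similarity: dict[str, float]
    p_category: dict[str, float] = field(default_factory=dict)


def predicted_candidates(truth: SyntheticTruth, reference: DistanceMap) -> dict[str, DistanceMap]:
    """Build orthologous and codon-usage candidate maps on the reference scale."""
    gd_b = gene_pair_distances(truth.dmap_b, truth.genes_b)
    proj = scale_to_median(project_orthologous(gd_b, truth.orthologs), reference)
    ortho = gene_pairs_to_bins(
        select_quantile_band(proj, *ORTHO_BAND), truth.layout, truth.genes
    )
    profiles = [codon_frequencies(truth.cds[g], g) for g in sorted(truth.cds)]
    table = cufs_matrix(profiles, reference=reference)
    cufs = gene_pairs_to_bins(
        select_quantile_band(table, *CUFS_BAND), truth.layout, truth.genes
    )
    return {"ortho": ortho, "cufs": cufs}


def _per_model_similarity(models: list[Model3D]) -> list[float]:
    dvecs = [m.all_pair_distances() for m in models]
    out = []
    for a in range(len(models)):
        rhos = [spearmanr(dvecs[a], dvecs[b])[0] for b in range(len(models)) if b != a]
        out.append(float(np.mean(rhos)))
    return out


def integration_experiment(
    seed: int = 1,
    n_replicates: int = 10,
    base_fraction: float = 0.01,
    n_perm: int = 10_000,
    n_random_sets: int = 100,
    jitter_nm: float = 30.0,
    cds_noise: float = 0.15,
) -> IntegrationResult:
    """Paired comparison of base, ortho-, CUFS- and random-integrated models.

    Per replicate a base map (uniform sample of the truth distance map) is
    extended with an equal number of candidate interactions via
    poor-get-richer.  Each model is scored with the full battery plus the
    planted-set NSD; per-category model similarity is added per model.
    """
    truth = make_truth("small", seed=seed, jitter_nm=jitter_nm, cds_noise=cds_noise)
    dmap = truth.true_distance_map()
    cands = predicted_candidates(truth, dmap)
    arms = ("base", "ortho", "cufs", "random")
    models: dict[str, list[Model3D]] = {a: [] for a in arms}
    reports: dict[str, list[BenchmarkReport]] = {a: [] for a in arms}
    for rep in range(n_replicates):
        base = uniform_sample(dmap, base_fraction, seed=500 + rep)
        n_add = len(base)
        rand_cand = permute_coordinates(dmap, seed=900 + rep)
        maps = {
            "base": base,
            "ortho": poor_get_richer_merge(base, cands["ortho"], n_add, seed=rep),
            "cufs": poor_get_richer_merge(base, cands["cufs"], n_add, seed=rep),
            "random": poor_get_richer_merge(base, rand_cand, n_add, seed=rep),
        }
        for arm, m in maps.items():
            model = _recon(m, truth.layout, seed=3000 + rep)
            models[arm].append(model)
            rep_b = run_battery(
                model,
                locus_sets=truth.planted_sets,
                genes=truth.genes,
                n_random=n_random_sets,
                seed=rep,
            )
            reports[arm].append(rep_b)
    planted_nsd: dict[str, list[float]] = {}
    similarity: dict[str, list[float]] = {}
    for arm in arms:
        planted_nsd[arm] = [r.values["nsd_planted_compact"] for r in reports[arm]]
        similarity[arm] = _per_model_similarity(models[arm])
        for r, s in zip(reports[arm], similarity[arm]):
            r.add("model_similarity", s, HIGHER_BETTER)
    categories = {arm: CategoryResults(arm, reports[arm]) for arm in arms}
    p_nsd = {
        arm: wilcoxon_one_tail(planted_nsd["base"], planted_nsd[arm], paired=True, alternative="greater")
        for arm in ("ortho", "cufs", "random")
    }
    p_similarity = {
        arm: wilcoxon_one_tail(similarity[arm], similarity["base"], paired=True, alternative="greater")
        for arm in ("ortho", "cufs", "random")
    }
    p_category = {}
    for arm in ("ortho", "cufs"):
        _, p = category_permutation_test(
            categories[arm], categories["random"], n_perm=n_perm, seed=seed
        )
        p_category[arm] = p
    return IntegrationResult(categories, planted_nsd, similarity, p_nsd, p_similarity, p_category)
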