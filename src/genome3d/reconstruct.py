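"""Constrained least-squares reconstruction of bead coordinates.

Minimizes the sum of squared errors between model bead-pair distances and
the input target distances, subject to: containment in the nuclear sphere,
a maximum stretch between adjacent beads, a minimum separation between
non-adjacent beads, optional nucleolus membership, and optional fixed
beads.  Constraints are enforced through a quadratic penalty scheme with
increasing weights around an L-BFGS inner solver; fixed beads are removed
from the optimization variables and honored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .contacts import PACKING_BP_PER_NM, DistanceMap
from .layout import GenomeLayout
from .model import Model3D

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Nucleolus:
    center: tuple[float, float, float]
    radius: float
    inside_beads: frozenset[int] = frozenset()


@dataclass(frozen=True)
class ReconstructionConfig:
    nucleus_radius_nm: float = 1000.0
    adjacent_max_stretch: float = 1.5
    min_separation_nm: float = 30.0
    packing_bp_per_nm: float = PACKING_BP_PER_NM
    nucleolus: Nucleolus | None = None
    fixed_beads: dict = field(default_factory=dict)  # bead -> (x, y, z)
    n_starts: int = 4
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_nm <= 0:
            raise ValueError("nucleus radius must be positive")
        if self.adjacent_max_stretch < 1:
            raise ValueError("adjacent_max_stretch must be >= 1")
        if self.min_separation_nm >= 2 * self.nucleus_radius_nm:
            raise ValueError("min separation must be below the nucleus diameter")

    def adjacent_bound_nm(self, layout: GenomeLayout) -> float:
        return self.adjacent_max_stretch * layout.resolution_bp / self.packing_bp_per_nm


@dataclass
class ReconstructionResult:
    model: Model3D
    objective: float
    constraint_violation: float
    n_iterations: int
    seed_used: int
    converged: bool = True


# ---------------------------------------------------------------------------


def objective(model: Model3D, targets: DistanceMap) -> float:
    """Sum of squared errors between model distances and target distances."""
    d = model.pairwise_distances(targets.i, targets.j)
    return float(np.sum((d - targets.v) ** 2))


def random_init(layout: GenomeLayout, config: ReconstructionConfig, seed: int) -> Model3D:
    """Random chromosome walks inside the nucleus, honoring the adjacency bound.

    Each chromosome is an independent random walk with steps at most the
    adjacent bound, reflected back into the nuclear sphere.
    """
    rng = np.random.default_rng(seed)
    R = config.nucleus_radius_nm
    step_max = config.adjacent_bound_nm(layout)
    if step_max >= 2 * R:
        raise ValueError("nucleus too small for the adjacency bound")
    coords = np.empty((layout.n_beads, 3))
    offset = 0
    for chrom, _ in layout.chromosomes:
        n = layout.n_beads_of(chrom)
        # start uniformly inside a concentric sphere of radius 0.8 R
        while True:
            p = rng.uniform(-0.8 * R, 0.8 * R, size=3)
            if np.linalg.norm(p) <= 0.8 * R:
                break
        coords[offset] = p
        for k in range(1, n):
            step = rng.normal(size=3)
            step *= rng.uniform(0.3, 0.95) * step_max / np.linalg.norm(step)
            q = coords[offset + k - 1] + step
            r = np.linalg.norm(q)
            if r > R:
                q *= (2 * R - r) / r  # radial reflection stays within the step bound
            coords[offset + k] = q
        offset += n
    for bead, xyz in config.fixed_beads.items():
        coords[bead] = xyz
    return Model3D(layout, coords)


def constraint_report(model: Model3D, config: ReconstructionConfig) -> dict[str, float]:
    """Maximum violation (nm) of each constraint class; 0 when satisfied."""
    layout = model.layout
    x = model.coords
    R = config.nucleus_radius_nm
    radii = np.linalg.norm(x, axis=1)
    nucleus = max(0.0, float(radii.max(initial=0.0) - R))
    lo, hi = layout.adjacent_pairs()
    bound = config.adjacent_bound_nm(layout)
    adjacency = 0.0
    if len(lo):
        d = np.linalg.norm(x[lo] - x[hi], axis=1)
        adjacency = max(0.0, float(d.max() - bound))
    separation = _min_separation_violation(x, layout, config)
    report = {"nucleus": nucleus, "adjacency": adjacency, "separation": separation}
    if config.nucleolus is not None:
        nuc = config.nucleolus
        center = np.asarray(nuc.center)
        dist = np.linalg.norm(x - center, axis=1)
        inside = np.zeros(layout.n_beads, dtype=bool)
        inside[list(nuc.inside_beads)] = True
        v_in = max(0.0, float((dist[inside] - nuc.radius).max(initial=0.0)))
        v_out = max(0.0, float((nuc.radius - dist[~inside]).max(initial=0.0)))
        report["nucleolus"] = max(v_in, v_out)
    if config.fixed_beads:
        beads = np.array(sorted(config.fixed_beads), dtype=np.int64)
        want = np.array([config.fixed_beads[b] for b in beads], dtype=float)
        report["fixed"] = float(np.linalg.norm(x[beads] - want, axis=1).max())
    return report


def max_violation(model: Model3D, config: ReconstructionConfig) -> float:
    return max(constraint_report(model, config).values())


def _separation_pairs(layout: GenomeLayout) -> tuple[np.ndarray, np.ndarray]:
    """All non-adjacent bead pairs (adjacency = chain neighbors)."""
    n = layout.n_beads
    iu, ju = np.triu_indices(n, k=1)
    lo, hi = layout.adjacent_pairs()
    adj = set(zip(lo.tolist(), hi.tolist()))
    keep = np.array([(a, b) not in adj for a, b in zip(iu, ju)])
    return iu[keep], ju[keep]


def _min_separation_violation(x: np.ndarray, layout: GenomeLayout, config: ReconstructionConfig) -> float:
    from scipy.spatial import cKDTree

    s = config.min_separation_nm
    tree = cKDTree(x)
    pairs = tree.query_pairs(s, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    lo, hi = layout.adjacent_pairs()
    adj = set(zip(lo.tolist(), hi.tolist()))
    worst = 0.0
    for a, b in pairs:
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        if (a, b) in adj:
            continue
        worst = max(worst, s - float(np.linalg.norm(x[a] - x[b])))
    return worst


class _Problem:
    """Penalized objective with analytic gradient over free-bead coordinates."""

    def __init__(self, targets: DistanceMap, layout: GenomeLayout, config: ReconstructionConfig):
        self.layout = layout
        self.config = config
        n = layout.n_beads
        self.n = n
        self.ti, self.tj, self.tv = targets.i, targets.j, targets.v
        self.adj_lo, self.adj_hi = layout.adjacent_pairs()
        self.adj_bound = config.adjacent_bound_nm(layout)
        self.sep_i, self.sep_j = _separation_pairs(layout)
        fixed = sorted(config.fixed_beads)
        self.fixed_idx = np.array(fixed, dtype=np.int64)
        self.fixed_xyz = np.array([config.fixed_beads[b] for b in fixed], dtype=float).reshape(-1, 3)
        free_mask = np.ones(n, dtype=bool)
        free_mask[self.fixed_idx] = False
        self.free_idx = np.nonzero(free_mask)[0]
        if config.nucleolus is not None:
            nuc = config.nucleolus
            self.nuc_center = np.asarray(nuc.center, dtype=float)
            self.nuc_radius = nuc.radius
            inside = np.zeros(n, dtype=bool)
            inside[list(nuc.inside_beads)] = True
            self.nuc_inside = inside
        else:
            self.nuc_center = None

    def full_coords(self, z: np.ndarray) -> np.ndarray:
        x = np.empty((self.n, 3))
        x[self.free_idx] = z.reshape(-1, 3)
        if len(self.fixed_idx):
            x[self.fixed_idx] = self.fixed_xyz
        return x

    def value_and_grad(self, z: np.ndarray, mu: float) -> tuple[float, np.ndarray]:
        x = self.full_coords(z)
        grad = np.zeros_like(x)
        cfg = self.config

        # data term: sum (||xi-xj|| - delta)^2
        diff = x[self.ti] - x[self.tj]
        d = np.linalg.norm(diff, axis=1)
        d_safe = np.maximum(d, 1e-12)
        resid = d - self.tv
        f = float(np.sum(resid**2))
        g = (2.0 * resid / d_safe)[:, None] * diff
        np.add.at(grad, self.ti, g)
        np.add.at(grad, self.tj, -g)

        # nucleus containment: mu * sum max(0, r - R)^2
        r = np.linalg.norm(x, axis=1)
        over = r - cfg.nucleus_radius_nm
        mask = over > 0
        if mask.any():
            f += mu * float(np.sum(over[mask] ** 2))
            grad[mask] += (2.0 * mu * over[mask] / r[mask])[:, None] * x[mask]

        # adjacency stretch: mu * sum max(0, d - bound)^2
        diff = x[self.adj_lo] - x[self.adj_hi]
        d = np.linalg.norm(diff, axis=1)
        over = d - self.adj_bound
        mask = over > 0
        if mask.any():
            f += mu * float(np.sum(over[mask] ** 2))
            g = (2.0 * mu * over[mask] / d[mask])[:, None] * diff[mask]
            np.add.at(grad, self.adj_lo[mask], g)
            np.add.at(grad, self.adj_hi[mask], -g)

        # min separation (non-adjacent): mu * sum max(0, s - d)^2
        diff = x[self.sep_i] - x[self.sep_j]
        d = np.linalg.norm(diff, axis=1)
        under = cfg.min_separation_nm - d
        mask = under > 0
        if mask.any():
            d_m = np.maximum(d[mask], 1e-9)
            f += mu * float(np.sum(under[mask] ** 2))
            g = (-2.0 * mu * under[mask] / d_m)[:, None] * diff[mask]
            np.add.at(grad, self.sep_i[mask], g)
            np.add.at(grad, self.sep_j[mask], -g)

        # nucleolus membership
        if self.nuc_center is not None:
            dvec = x - self.nuc_center
            dist = np.linalg.norm(dvec, axis=1)
            d_safe = np.maximum(dist, 1e-12)
            over = np.where(self.nuc_inside, dist - self.nuc_radius, self.nuc_radius - dist)
            mask = over > 0
            if mask.any():
                f += mu * float(np.sum(over[mask] ** 2))
                sign = np.where(self.nuc_inside, 1.0, -1.0)
                g = (2.0 * mu * over[mask] * sign[mask] / d_safe[mask])[:, None] * dvec[mask]
                grad[mask] += g
        return f, grad[self.free_idx].ravel()


def _solve_single(
    targets: DistanceMap,
    layout: GenomeLayout,
    config: ReconstructionConfig,
    seed: int,
    problem: _Problem | None = None,
) -> ReconstructionResult:
    problem = problem or _Problem(targets, layout, config)
    init = random_init(layout, config, seed)
    z = init.coords[problem.free_idx].ravel().copy()
    total_iter = 0
    mu_schedule = (1.0, 10.0, 100.0, 1000.0)
    iters_per_round = max(50, config.max_iter // len(mu_schedule))
    converged = True
    for mu in mu_schedule:
        res = minimize(
            problem.value_and_grad,
            z,
            args=(mu,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": iters_per_round, "ftol": config.tol, "gtol": 1e-8},
        )
        z = res.x
        total_iter += res.nit
    model = Model3D(layout, problem.full_coords(z))
    viol = max_violation(model, config)
    obj = objective(model, targets)
    if viol > max(1.0, config.tol * config.nucleus_radius_nm):
        converged = False
    return ReconstructionResult(model, obj, viol, total_iter, seed, converged)


def reconstruct(
    targets: DistanceMap,
    layout: GenomeLayout,
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Best-of-``n_starts`` reconstruction from target distances.

    Each start is a random initialization solved by the penalty scheme; the
    best result is selected lexicographically by (constraint violation,
    objective).
    """
    config = config or ReconstructionConfig()
    if len(targets) == 0:
        raise ValueError("empty target distance map")
    problem = _Problem(targets, layout, config)
    results = [
        _solve_single(targets, layout, config, config.seed + k, problem)
        for k in range(config.n_starts)
    ]
    return select_best(results)


def select_best(results: Sequence[ReconstructionResult]) -> ReconstructionResult:
    """Lexicographic selection: smallest constraint violation, then objective."""
    if not results:
        raise ValueError("no results to select from")
    # violations below 1 nm are considered equally feasible
    return min(results, key=lambda r: (round(max(r.constraint_violation - 1.0, 0.0), 6), r.objective))


def normalized_objective(result: ReconstructionResult, random_results: Sequence[ReconstructionResult]) -> float:
    """Objective divided by the mean objective of equal-size random models."""
    if not random_results:
        raise ValueError("no random results to normalize against")
    return result.objective / float(np.mean([r.objective for r in random_results]))
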