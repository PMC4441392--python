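import numpy as np
import pytest
from scipy.stats import spearmanr

from genome3d.benchmark import (
    arm_ratios,
    binned_spearman,
    model_similarity,
    nsd,
    pa_distance,
    ppi_pair_distance,
    telomere_cluster,
    telomere_radius,
)
from genome3d.layout import GenomeLayout
from genome3d.model import Model3D


@pytest.fixture
def grid_model():
    layout = GenomeLayout((("c", 300_000),), resolution_bp=10_000)
    rng = np.random.default_rng(0)
    return Model3D(layout, rng.uniform(-500, 500, (30, 3)))


class TestNsd:
    def test_whole_universe_near_one(self, grid_model):
        val = nsd(grid_model, list(range(30)), n_random=100, seed=0)
        assert val == pytest.approx(1.0, abs=0.02)

    def test_coincident_beads_zero(self):
        layout = GenomeLayout((("c", 100_000),), resolution_bp=10_000)
        coords = np.arange(30, dtype=float).reshape(10, 3) * 50
        coords[3] = coords[4] = coords[5] = (10.0, 10.0, 10.0)
        model = Model3D(layout, coords)
        assert nsd(model, [3, 4, 5], n_random=50, seed=1) == 0.0

    def test_matches_two_stage_oracle(self, grid_model):
        from scipy.spatial.distance import pdist

        beads = [2, 7, 11, 19]
        seed = 5
        val = nsd(grid_model, beads, n_random=40, seed=seed)
        rng = np.random.default_rng(seed)
        observed = pdist(grid_model.coords[beads]).mean()
        rand = []
        for _ in range(40):
            draw = rng.choice(np.arange(30), size=4, replace=False)
            rand.append(pdist(grid_model.coords[draw]).mean())
        assert val == pytest.approx(observed / np.mean(rand))

    def test_planted_cluster_below_one(self, truth_small):
        assert nsd(truth_small.true_model, truth_small.planted_sets[0], seed=0) < 0.8

    def test_too_small_set(self, grid_model):
        with pytest.raises(ValueError):
            nsd(grid_model, [3], n_random=10, seed=0)

    def test_random_set_calibration(self, grid_model):
        rng = np.random.default_rng(7)
        vals = []
        for k in range(200):
            beads = rng.choice(30, size=5, replace=False)
            vals.append(nsd(grid_model, beads, n_random=20, seed=k))
        assert 0.95 <= np.mean(vals) <= 1.05


class TestTelomereRadius:
    def test_constant_radius(self):
        layout = GenomeLayout((("c", 50_000),), resolution_bp=10_000)
        coords = np.zeros((5, 3))
        coords[0] = (800, 0, 0)
        coords[4] = (0, 800, 0)
        assert telomere_radius(Model3D(layout, coords)) == pytest.approx(800.0)

    def test_mean_of_two(self):
        layout = GenomeLayout((("c", 50_000),), resolution_bp=10_000)
        coords = np.zeros((5, 3))
        coords[0] = (600, 0, 0)
        coords[4] = (0, 0, 1000)
        assert telomere_radius(Model3D(layout, coords)) == pytest.approx(800.0)

    def test_matches_norm_mean_oracle(self, grid_model):
        beads = grid_model.layout.telomere_beads()
        expected = np.mean([np.linalg.norm(grid_model.coords[b]) for b in beads])
        assert telomere_radius(grid_model) == pytest.approx(expected)


class TestArmRatios:
    def test_far_apart_chromosomes_cis_below_one(self):
        layout = GenomeLayout(
            (("a", 50_000), ("b", 50_000)),
            resolution_bp=10_000,
            centromeres={"a": 25_000, "b": 25_000},
        )
        coords = np.zeros((10, 3))
        # chromosome a compact near origin, chromosome b compact far away
        coords[:5] = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]])
        coords[5:] = coords[:5] + np.array([5000.0, 0, 0])
        ratios = arm_ratios(Model3D(layout, coords))
        assert ratios["cis_vs_trans"] < 0.1

    def test_symmetric_configuration_unity(self):
        # 4 single-bead arms at the corners of a regular tetrahedron via two
        # chromosomes: all inter-arm mean distances equal -> ratios 1
        layout = GenomeLayout(
            (("a", 30_000), ("b", 30_000)),
            resolution_bp=10_000,
            centromeres={"a": 15_000, "b": 15_000},
        )
        t = np.array(
            [[1, 1, 1], [1, -1, -1], [0, 0, 0], [-1, 1, -1], [-1, -1, 1], [0, 0, 0]],
            dtype=float,
        )
        # beads: a = [arm, cen, arm], b = [arm, cen, arm]
        coords = np.array([t[0], t[2], t[1], t[3], t[5], t[4]])
        ratios = arm_ratios(Model3D(layout, coords))
        assert ratios["cis_vs_trans"] == pytest.approx(1.0)

    def test_matches_bruteforce_means(self, truth_small):
        model = truth_small.true_model
        layout = truth_small.layout
        ratios = arm_ratios(model)
        # brute-force cis-vs-trans oracle
        offsets = layout.chrom_offsets()
        arms = []
        for chrom, _ in layout.chromosomes:
            cen = layout.bead_of(chrom, layout.centromeres[chrom])
            first = offsets[chrom]
            last = first + layout.n_beads_of(chrom) - 1
            arms.append((chrom, list(range(first, cen))))
            arms.append((chrom, list(range(cen + 1, last + 1))))

        def mean_dist(a, b):
            return np.mean(
                [np.linalg.norm(model.coords[x] - model.coords[y]) for x in a for y in b]
            )

        cis_vals = []
        for chrom, _ in layout.chromosomes:
            own = [a for c, a in arms if c == chrom]
            others = [a for c, a in arms if c != chrom]
            cis = mean_dist(own[0], own[1])
            trans = np.mean([mean_dist(o, x) for o in own for x in others])
            cis_vals.append(cis / trans)
        assert ratios["cis_vs_trans"] == pytest.approx(np.mean(cis_vals))

    def test_missing_centromere_skipped(self):
        layout = GenomeLayout(
            (("a", 50_000), ("b", 50_000)),
            resolution_bp=10_000,
            centromeres={"a": 25_000},
        )
        rng = np.random.default_rng(1)
        ratios = arm_ratios(Model3D(layout, rng.uniform(-100, 100, (10, 3))))
        assert np.isnan(ratios["cis_vs_trans"])  # single chromosome left, no trans


class TestModelSimilarity:
    def test_duplicate_model_unity(self, grid_model):
        assert model_similarity([grid_model, grid_model]) == pytest.approx(1.0)

    def test_mirror_image_unity(self, grid_model):
        mirrored = Model3D(grid_model.layout, grid_model.coords * np.array([-1, 1, 1]))
        assert model_similarity([grid_model, mirrored]) == pytest.approx(1.0)

    def test_mean_of_three_pairs(self):
        layout = GenomeLayout((("c", 100_000),), resolution_bp=10_000)
        rng = np.random.default_rng(2)
        models = [Model3D(layout, rng.uniform(-300, 300, (10, 3))) for _ in range(3)]
        got = model_similarity(models)
        dvecs = [m.all_pair_distances() for m in models]
        expected = np.mean([
            spearmanr(dvecs[0], dvecs[1])[0],
            spearmanr(dvecs[0], dvecs[2])[0],
            spearmanr(dvecs[1], dvecs[2])[0],
        ])
        assert got == pytest.approx(expected)

    def test_single_model_rejected(self, grid_model):
        with pytest.raises(ValueError):
            model_similarity([grid_model])


class TestBinnedSpearman:
    def test_perfect_covariate(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 100, 5000)
        assert binned_spearman(d, d, n_bins=100) == pytest.approx(1.0)

    def test_null_covariate_centered_on_zero(self):
        rng = np.random.default_rng(4)
        rhos = []
        for _ in range(100):
            d = rng.uniform(0, 100, 2000)
            c = rng.uniform(0, 100, 2000)
            rhos.append(binned_spearman(d, c, n_bins=50))
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        assert lo < 0 < hi
        assert abs(np.mean(rhos)) < 0.1

    def test_two_bins_matches_hand_computation(self):
        d = np.array([10.0, 20.0, 30.0, 40.0])
        c = np.array([1.0, 2.0, 3.0, 4.0])
        # bins by covariate: {1,2} and {3,4}; means (1.5, 15) and (3.5, 35)
        assert binned_spearman(d, c, n_bins=2) == pytest.approx(1.0)

    def test_nbins_equals_pairs_is_plain_spearman(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 10, 200)
        c = rng.uniform(0, 10, 200)
        assert binned_spearman(d, c, n_bins=200) == pytest.approx(spearmanr(c, d)[0])

    def test_constant_covariate_nan(self):
        out = binned_spearman(np.arange(10.0), np.ones(10), n_bins=5)
        assert np.isnan(out)


class TestPaDistance:
    def test_equal_zero(self):
        assert pa_distance(3.0, 3.0) == 0.0

    def test_three_vs_one(self):
        assert pa_distance(3.0, 1.0) == pytest.approx(1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p, q = rng.uniform(0.1, 50, 2)
            assert pa_distance(p, q) == pytest.approx(2 * abs(p - q) / (p + q))
            assert 0 <= pa_distance(p, q) < 2

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            pa_distance(0.0, 0.0)


class TestPpiPairDistance:
    def test_adjacent(self):
        out = ppi_pair_distance([("a", "b"), ("b", "c")], [("a", "b")])
        assert out[0] == 1

    def test_disconnected_255(self):
        out = ppi_pair_distance([("a", "b"), ("x", "y")], [("a", "x"), ("a", "zzz")])
        assert out.tolist() == [255, 255]

    def test_matches_bfs_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        nodes = [f"n{k}" for k in range(30)]
        edges = []
        for _ in range(40):
            a, b = rng.choice(nodes, 2, replace=False)
            edges.append((a, b))
        g = nx.Graph(edges)
        pairs = [tuple(rng.choice(nodes, 2, replace=False)) for _ in range(25)]
        got = ppi_pair_distance(edges, pairs)
        for k, (a, b) in enumerate(pairs):
            try:
                expected = nx.shortest_path_length(g, a, b) if a in g and b in g else 255
            except nx.NetworkXNoPath:
                expected = 255
            assert got[k] == expected


class TestTelomereCluster:
    def test_coincident_telomeres_merge_first(self):
        layout = GenomeLayout(
            (("a", 30_000), ("b", 30_000)), resolution_bp=10_000
        )
        coords = np.array(
            [[0, 0, 0], [50, 0, 0], [100, 0, 0],
             [100.0, 0.5, 0], [500, 0, 0], [900, 0, 0]]
        )
        mean_mat, tree, order = telomere_cluster([Model3D(layout, coords)])
        # telomeres: beads 0, 2, 3, 5 -> indices 1 and 2 nearly coincident
        assert sorted(tree[0, :2].astype(int).tolist()) == [1, 2]

    def test_three_point_linkage_by_hand(self):
        layout = GenomeLayout((("a", 10_000), ("b", 10_000), ("c", 10_000)))
        coords = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0]], dtype=float)
        _, tree, _ = telomere_cluster([Model3D(layout, coords)])
        assert sorted(tree[0, :2].astype(int).tolist()) == [0, 1]

    def test_single_model_matrix_is_direct_distances(self, grid_model):
        from scipy.spatial.distance import pdist, squareform

        mean_mat, _, _ = telomere_cluster([grid_model])
        beads = grid_model.layout.telomere_beads()
        np.testing.assert_allclose(mean_mat, squareform(pdist(grid_model.coords[beads])))


class TestRigidMotionInvariance:
    def test_ratio_tests_invariant(self, truth_small):
        model = truth_small.true_model
        rng = np.random.default_rng(8)
        # random rotation + mirror (no translation: radii measured from origin)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        q[:, 0] *= -1  # force an improper rotation
        moved = Model3D(model.layout, model.coords @ q)
        a, b = arm_ratios(model), arm_ratios(moved)
        for key in a:
            assert a[key] == pytest.approx(b[key])
        beads = truth_small.planted_sets[0].midpoint_beads(model.layout)
        assert nsd(moved, beads, seed=0) == pytest.approx(nsd(model, beads, seed=0))
        assert telomere_radius(moved) == pytest.approx(telomere_radius(model))
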