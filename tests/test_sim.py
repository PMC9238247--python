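import numpy as np
import pytest
from scipy.stats import spearmanr

from trajalign.sim import (SimulationTruth, TrajectoryTree,
                           add_noise_and_split, assign_batches,
                           base_kinetics, preset_tree, random_gam,
                           simulate_atac, simulate_identities, simulate_joint,
                           simulate_rna)


@pytest.fixture(scope="module")
def tri_tree():
    return preset_tree("trifurcating", cells_per_batch=150)


class TestTree:
    def test_cell_allocation_exact(self, tri_tree):
        ids, pt, br = simulate_identities(tri_tree, seed=0)
        counts = {b: int((br == b).sum()) for b in np.unique(br)}
        for p, c, _, n in tri_tree.edges:
            if n:
                assert counts[f"{p}_{c}"] == n

    def test_disconnected_tree_rejected(self):
        with pytest.raises(ValueError, match="reachable|connected"):
            TrajectoryTree([("root", "a", 1.0, 5), ("x", "y", 1.0, 5)], "root")

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TrajectoryTree([], "root")


class TestIdentities:
    def test_near_zero_step_collapses_to_root(self, tri_tree):
        ids, _, _ = simulate_identities(tri_tree, step_sd=1e-9, seed=1)
        assert np.ptp(ids, axis=0).max() < 1e-6

    def test_brownian_variance_law(self):
        # E||x(t) - x(0)||^2 = v * sd^2 * t, checked by Monte Carlo over seeds
        tree = TrajectoryTree([("root", "a", 1.0, 20), ("a", "b", 1.0, 20)],
                              "root")
        v, sd = 10, 0.8
        sq, ts = [], []
        for seed in range(200):
            ids, pt, _ = simulate_identities(tree, v=v, step_sd=sd, seed=seed)
            root_id = ids[np.argmin(pt)]
            sq.append(np.sum((ids - root_id) ** 2, axis=1))
            ts.append(pt - pt.min())
        sq = np.concatenate(sq)
        ts = np.concatenate(ts)
        mask = ts > 0.3
        ratio = (sq[mask] / (v * sd ** 2 * ts[mask])).mean()
        assert 0.8 <= ratio <= 1.2

    def test_branch_divergence(self):
        tree = TrajectoryTree([("root", "a", 2.0, 60), ("root", "b", 2.0, 60)],
                              "root")
        ids, _, br = simulate_identities(tree, v=15, step_sd=1.0, seed=3)
        a, b = ids[br == "root_a"], ids[br == "root_b"]
        intra = np.linalg.norm(a - a.mean(0), axis=1).mean()
        inter = np.linalg.norm(a.mean(0) - b.mean(0))
        assert inter > 0.5 * intra  # branch means separate from within-spread

    def test_invalid_params(self, tri_tree):
        with pytest.raises(ValueError):
            simulate_identities(tri_tree, v=0)
        with pytest.raises(ValueError):
            simulate_identities(tri_tree, step_sd=0.0)


class TestAtac:
    def test_sparsity_matches_target(self):
        rng = np.random.default_rng(0)
        ids = rng.normal(size=(2000, 10))
        X, _ = simulate_atac(ids, 300, seed=1, beta_params=(1.0, 8.0))
        assert X.mean() == pytest.approx(1.0 / 9.0, abs=0.02)

    def test_rank_order_preserved_within_region(self):
        rng = np.random.default_rng(1)
        ids = rng.normal(size=(100, 8))
        region_seed = 2
        X, region_ids = simulate_atac(ids, 50, noise=0.0, seed=region_seed)
        raw = ids @ region_ids.T
        for j in (0, 17, 33):
            if 0 < X[:, j].sum() < len(X):
                assert raw[X[:, j] == 1, j].min() >= raw[X[:, j] == 0, j].max()

    def test_identical_identities_identical_rows(self):
        ids = np.ones((5, 6))
        X, _ = simulate_atac(ids, 40, noise=0.0, seed=0)
        # all cells identical: any open region is open in the top-ranked
        # cells, but with exactly tied scores ranks are stable, so rows with
        # full-open or full-closed regions agree across cells
        full = (X.sum(axis=0) % len(X)) == 0
        assert np.all(X[:, full] == X[0, full])


class TestRna:
    def test_accessibility_raises_expression(self):
        rng = np.random.default_rng(0)
        n, G, R = 10_000, 1, 4
        gam = random_gam(R, G, links_per_gene=4, seed=0)
        ids = rng.normal(size=(n, 5))
        kin = base_kinetics(ids, G, seed=1)
        closed = simulate_rna(np.zeros((n, R)), gam, kin, seed=2)
        opened = simulate_rna(np.ones((n, R)), gam, kin, seed=2)
        assert opened.mean() > closed.mean()

    def test_always_on_limit(self):
        # k_on >> k_off: Beta(a, b) -> 1 and the mean count -> s/d
        n, G = 5000, 1
        gam = random_gam(2, G, 2, seed=0)
        ids = np.zeros((n, 3))
        kin = base_kinetics(ids, G, seed=1)
        kin.k_on = np.full((n, G), 1e5)
        kin.k_off = np.array([1e-3])
        X = simulate_rna(np.ones((n, 2)), gam, kin, seed=3,
                         coupling=(1.0, 0.0))
        assert X.mean() == pytest.approx(kin.s[0] / kin.d[0], rel=0.05)

    def test_counts_are_nonnegative_integers(self):
        rng = np.random.default_rng(2)
        ids = rng.normal(size=(50, 4))
        gam = random_gam(20, 10, 3, seed=0)
        X = simulate_rna((rng.random((50, 20)) < 0.3).astype(float), gam,
                         base_kinetics(ids, 10, seed=1), seed=4)
        assert np.all(X >= 0) and np.all(X == np.round(X))

    def test_linked_accessibility_correlates_with_expression(self):
        rng = np.random.default_rng(5)
        ids, pt, _ = simulate_identities(
            preset_tree("linear", cells_per_batch=400), seed=5)
        atac, _ = simulate_atac(ids, 100, seed=6)
        gam = random_gam(100, 40, 4, seed=7)
        kin = base_kinetics(ids, 40, seed=8)
        rna = simulate_rna(atac, gam, kin, seed=9)
        frac = (atac @ gam.A) / gam.A.sum(axis=0)
        linked = [spearmanr(frac[:, g], rna[:, g]).statistic
                  for g in range(40) if frac[:, g].std() > 0]
        assert np.nanmean(linked) > 0.05


class TestNoiseSplit:
    def make_truth(self, n=60, G=12, R=20, seed=0):
        truth = simulate_joint(
            TrajectoryTree([("root", "a", 1.0, n)], "root"),
            n_genes=G, n_regions=R, seed=seed)
        return assign_batches(truth, 2, seed=seed + 1)

    def test_identity_noise_preserves_counts(self):
        truth = self.make_truth()
        batches = add_noise_and_split(
            truth, capture_eff=[1.0, 1.0], batch_effect_sd=0.0,
            keep={"rna_batch_indices": [0], "atac_batch_indices": [1]}, seed=0)
        rna = batches[0]
        idx = np.flatnonzero(truth.batch_of == 0)
        np.testing.assert_array_equal(rna.dense(), truth.rna_counts[idx])

    def test_binomial_thinning_mean(self):
        truth = self.make_truth(n=400, G=60, seed=3)
        batches = add_noise_and_split(
            truth, capture_eff=[0.3, 0.3], batch_effect_sd=0.0,
            keep={"rna_batch_indices": [0], "atac_batch_indices": [1]}, seed=1)
        idx = np.flatnonzero(truth.batch_of == 0)
        ratio = batches[0].dense().sum() / truth.rna_counts[idx].sum()
        assert ratio == pytest.approx(0.3, abs=0.01)

    def test_modalities_disjoint_per_cell(self):
        truth = self.make_truth()
        batches = add_noise_and_split(
            truth, capture_eff=[1.0, 1.0], batch_effect_sd=0.1,
            keep={"rna_batch_indices": [0], "atac_batch_indices": [1]}, seed=0)
        cells = [set(b.cell_ids) for b in batches]
        assert cells[0].isdisjoint(cells[1])

    def test_bad_capture_eff(self):
        truth = self.make_truth()
        with pytest.raises(ValueError, match="capture_eff"):
            add_noise_and_split(truth, [0.0, 1.0], 0.0,
                                {"rna_batch_indices": [0],
                                 "atac_batch_indices": [1]})


class TestReproducibilityAndClusters:
    def test_bitwise_reproducible(self):
        t1 = simulate_joint(preset_tree("bifurcating", 80), n_genes=20,
                            n_regions=50, seed=9)
        t2 = simulate_joint(preset_tree("bifurcating", 80), n_genes=20,
                            n_regions=50, seed=9)
        np.testing.assert_array_equal(t1.rna_counts, t2.rna_counts)
        np.testing.assert_array_equal(t1.atac_counts, t2.atac_counts)
        np.testing.assert_array_equal(t1.pseudotime, t2.pseudotime)

    def test_cluster_mode_kmeans_recovery(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        truth = simulate_joint(preset_tree("clusters", 200), n_genes=80,
                               n_regions=250, seed=11, cluster_mode=True)
        labels = np.unique(truth.branch, return_inverse=True)[1]
        for X in (np.log1p(truth.rna_counts), truth.atac_counts):
            km = KMeans(len(set(labels)), random_state=0,
                        n_init=10).fit_predict(X)
            assert adjusted_rand_score(labels, km) > 0.9
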