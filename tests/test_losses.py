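import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from trajalign.io import GeneActivityMatrix
from trajalign.losses import (GAMMA_GRID, LossWeights, anchor_loss,
                              composite_loss, distance_loss, gam_penalty,
                              mmd_loss)
from trajalign.nn import Tensor, init_model


def kl_oracle(Qz, Qx, eps=1e-12):
    """Independent off-diagonal KL summation."""
    n = len(Qz)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += Qz[i, j] * np.log((Qz[i, j] + eps) / (Qx[i, j] + eps))
    return total


def mmd_oracle(Z1, Z2, gammas):
    """Independent double-loop kernel sums."""
    def kmean(A, B, g):
        s = 0.0
        for a in A:
            for b in B:
                s += np.exp(-np.sum((a - b) ** 2) / (2 * g))
        return s / (len(A) * len(B))
    return sum(kmean(Z1, Z1, g) + kmean(Z2, Z2, g) - 2 * kmean(Z1, Z2, g)
               for g in gammas)


def offdiag_normalize(D):
    Q = D.copy()
    np.fill_diagonal(Q, 0)
    return Q / Q.sum()


class TestDistanceLoss:
    def test_zero_on_isometric_embedding(self, rng):
        Z = rng.normal(size=(10, 4))
        D = squareform(pdist(Z))
        Qx = offdiag_normalize(D)
        assert distance_loss(Tensor(Z), Qx).item() == pytest.approx(0, abs=1e-9)
        # uniform scaling of Z cancels in the normalized distribution
        assert distance_loss(Tensor(3.7 * Z), Qx).item() == pytest.approx(
            0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        Z = rng.normal(size=(8, 3))
        Qx = offdiag_normalize(np.abs(rng.normal(size=(8, 8))) + 0.1)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        a = distance_loss(Tensor(Z), Qx).item()
        b = distance_loss(Tensor(Z @ R + 5.0), Qx).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_direct_summation_oracle(self, rng):
        Z = rng.normal(size=(4, 2))
        D = squareform(pdist(Z))
        Qz = offdiag_normalize(D)
        Qx = offdiag_normalize(np.abs(rng.normal(size=(4, 4))) + 0.2)
        expected = kl_oracle(Qz, Qx)
        assert distance_loss(Tensor(Z), Qx).item() == pytest.approx(
            expected, rel=1e-8)

    def test_nonnegative_and_permutation_invariant(self, rng):
        Z = rng.normal(size=(12, 3))
        Qx = offdiag_normalize(np.abs(rng.normal(size=(12, 12))) + 0.1)
        val = distance_loss(Tensor(Z), Qx).item()
        assert val >= -1e-9
        perm = rng.permutation(12)
        val_p = distance_loss(Tensor(Z[perm]),
                              Qx[np.ix_(perm, perm)]).item()
        assert val_p == pytest.approx(val, rel=1e-9)

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="3 cells"):
            distance_loss(Tensor(np.ones((2, 2))), np.ones((2, 2)))

    def test_no_offdiagonal_mass(self, rng):
        with pytest.raises(ValueError, match="off-diagonal"):
            distance_loss(Tensor(rng.normal(size=(4, 2))), np.eye(4))


class TestMmdLoss:
    def test_identical_sets_zero(self, rng):
        Z = rng.normal(size=(10, 4))
        assert mmd_loss(Tensor(Z), Tensor(Z.copy())).item() == pytest.approx(
            0, abs=1e-10)

    def test_two_point_closed_form(self):
        delta, gamma = 1.3, 0.5
        z1 = np.zeros((1, 2))
        z2 = np.array([[delta, 0.0]])
        expected = 2 - 2 * np.exp(-delta ** 2 / (2 * gamma))
        assert mmd_loss(Tensor(z1), Tensor(z2), gammas=(gamma,)
                        ).item() == pytest.approx(expected, rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        Z1 = rng.normal(size=(20, 3))
        Z2 = rng.normal(1.0, 1.0, size=(20, 3))
        expected = mmd_oracle(Z1, Z2, GAMMA_GRID)
        assert mmd_loss(Tensor(Z1), Tensor(Z2)).item() == pytest.approx(
            expected, abs=1e-10)

    def test_nonnegative_and_monotone_under_translation(self, rng):
        Z1 = rng.normal(size=(15, 2))
        vals = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            Z2 = Z1 + np.array([shift, 0.0])
            v = mmd_loss(Tensor(Z1), Tensor(Z2)).item()
            assert v >= -1e-12
            vals.append(v)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            mmd_loss(Tensor(rng.normal(size=(3, 2))),
                     Tensor(rng.normal(size=(3, 3))))


class TestGamPenalty:
    def small_model(self, n_regions=5, n_genes=3):
        return init_model(n_regions, n_genes, 2, seed=0, hidden_gact=(4, 3),
                          hidden_proj=(3, 2))

    def test_all_ones_prior_is_free(self):
        m = self.small_model()
        gam = GeneActivityMatrix(np.ones((5, 3)),
                                 [f"r{i}" for i in range(5)],
                                 [f"g{i}" for i in range(3)])
        assert gam_penalty(m.gact, gam).item() == 0.0

    def test_masked_weights_give_zero(self):
        # a rank-1 end-to-end map supported inside A
        m = self.small_model()
        for lin, shape in zip(m.gact.linears, [(4, 5), (3, 4), (3, 3)]):
            lin.W.data[:] = 0
        m.gact.linears[0].W.data[0, 1] = 2.0   # only region 1 feeds in
        m.gact.linears[1].W.data[0, 0] = 1.0
        m.gact.linears[2].W.data[2, 0] = 3.0   # only gene 2 receives
        A = np.zeros((5, 3))
        A[1, 2] = 1
        gam = GeneActivityMatrix(A, [f"r{i}" for i in range(5)],
                                 [f"g{i}" for i in range(3)])
        assert gam_penalty(m.gact, gam).item() == pytest.approx(0.0)

    def test_matches_explicit_summation(self, rng):
        m = self.small_model()
        A = np.ones((5, 3))
        zeros = [(0, 1), (2, 0), (3, 2), (4, 1)]
        for r, g in zeros:
            A[r, g] = 0
        gam = GeneActivityMatrix(A, [f"r{i}" for i in range(5)],
                                 [f"g{i}" for i in range(3)])
        W1, W2, W3 = [l.W.data for l in m.gact.linears]
        M = (W3 @ W2 @ W1).T
        expected = sum(abs(M[r, g]) for r, g in zeros)
        assert gam_penalty(m.gact, gam).item() == pytest.approx(expected,
                                                                rel=1e-10)


class TestAnchorLoss:
    def test_equal_means_zero(self, rng):
        Z = rng.normal(size=(5, 3))
        assert anchor_loss(Tensor(Z), Tensor(Z[::-1].copy())
                           ).item() == pytest.approx(0, abs=1e-12)

    def test_unit_offset_gives_one(self, rng):
        Z = rng.normal(size=(4, 3))
        shift = np.array([1.0, 0.0, 0.0])
        assert anchor_loss(Tensor(Z), Tensor(Z + shift)).item() == \
            pytest.approx(1.0, rel=1e-10)

    def test_row_permutation_invariance(self, rng):
        Za, Zb = rng.normal(size=(6, 2)), rng.normal(size=(4, 2))
        a = anchor_loss(Tensor(Za), Tensor(Zb)).item()
        b = anchor_loss(Tensor(Za[rng.permutation(6)]),
                        Tensor(Zb[rng.permutation(4)])).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anchor_loss(Tensor(np.empty((0, 2))), Tensor(np.ones((2, 2))))


class TestCompositeLoss:
    def setup_inputs(self, rng):
        m = init_model(6, 4, 2, seed=0, hidden_gact=(5, 3), hidden_proj=(4, 3))
        gam = GeneActivityMatrix((rng.random((6, 4)) < 0.5).astype(float),
                                 [f"r{i}" for i in range(6)],
                                 [f"g{i}" for i in range(4)])
        Z1 = Tensor(rng.normal(size=(8, 2)))
        Z2 = Tensor(rng.normal(size=(7, 2)))
        Qx = offdiag_normalize(np.abs(rng.normal(size=(8, 8))) + 0.1)
        return m, gam, Z1, Z2, Qx

    def test_zero_weights_leave_distance_only(self, rng):
        m, gam, Z1, Z2, Qx = self.setup_inputs(rng)
        total, comps = composite_loss("RNA", Z1, Qx, Z2,
                                      LossWeights(0.0, 0.0))
        assert total.item() == pytest.approx(comps["dist"], rel=1e-12)

    def test_components_sum_to_total(self, rng):
        m, gam, Z1, Z2, Qx = self.setup_inputs(rng)
        w = LossWeights(2.0, 3.0)
        total, c = composite_loss("ATAC", Z1, Qx, Z2, w, gact=m.gact, gam=gam)
        assert total.item() == pytest.approx(
            c["dist"] + 2.0 * c["mmd"] + 3.0 * c["gam"], rel=1e-10)

    def test_mmd_weight_linearity(self, rng):
        m, gam, Z1, Z2, Qx = self.setup_inputs(rng)
        t1, c1 = composite_loss("RNA", Z1, Qx, Z2, LossWeights(1.0, 0.0))
        t2, c2 = composite_loss("RNA", Z1, Qx, Z2, LossWeights(2.0, 0.0))
        assert t2.item() - t1.item() == pytest.approx(c1["mmd"], rel=1e-6)

    def test_missing_q_rejected(self, rng):
        m, gam, Z1, Z2, _ = self.setup_inputs(rng)
        with pytest.raises(ValueError, match="missing"):
            composite_loss("ATAC", Z1, None, Z2, LossWeights())
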