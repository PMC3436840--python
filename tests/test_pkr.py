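"""Closed-form pairwise kernel regression and its factorization identity."""

import numpy as np
import pytest

from conftest import random_spd_kernel
from pharmlink.pkr import (
    PairwiseKernelRegression,
    build_label_matrix,
    rank_predictions,
)


class TestLabelMatrix:
    def test_single_positive(self):
        lab = build_label_matrix({("d1", "t1")}, ["d1", "d2"], ["t1", "t2"])
        assert lab.Z.sum() == 1
        assert lab.Z[0, 0] == 1

    def test_masked_positive_is_zero(self):
        lab = build_label_matrix(
            {("d1", "t1")}, ["d1"], ["t1"], test_mask={("d1", "t1")}
        )
        assert lab.Z[0, 0] == 0

    def test_count_with_mask(self):
        drugs = [f"d{i}" for i in range(4)]
        targets = [f"t{j}" for j in range(3)]
        pos = {("d0", "t0"), ("d1", "t1"), ("d2", "t2"), ("d3", "t0"), ("d0", "t2")}
        lab = build_label_matrix(
            pos, drugs, targets, test_mask={("d0", "t0"), ("d1", "t1")}
        )
        assert lab.Z.sum() == 3

    def test_unknown_entity_is_hard_error(self):
        with pytest.raises(KeyError):
            build_label_matrix({("zzz", "t1")}, ["d1"], ["t1"])


class TestFit:
    def test_identity_kernels_give_B_equals_Z(self):
        lab = build_label_matrix({("d0", "t1")}, ["d0", "d1"], ["t0", "t1", "t2"])
        res = PairwiseKernelRegression(np.eye(2), np.eye(3), lab).fit()
        np.testing.assert_allclose(res.B, lab.Z, atol=1e-12)

    def test_two_by_two_closed_form(self):
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        lab = build_label_matrix({("d0", "t0")}, ["d0", "d1"], ["t0", "t1"])
        res = PairwiseKernelRegression(K, K, lab).fit()
        Kinv = np.linalg.inv(K)
        np.testing.assert_allclose(res.B, Kinv @ lab.Z @ Kinv, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_property(self, seed):
        """Unregularized fit reproduces the label matrix: K_x B K_y = Z."""
        rng = np.random.default_rng(seed)
        n_x, n_y = 7, 5
        Kx = random_spd_kernel(n_x, rng)
        Ky = random_spd_kernel(n_y, rng)
        Z = (rng.random((n_x, n_y)) < 0.3).astype(float)
        pos = {
            (str(i), str(j)) for i in range(n_x) for j in range(n_y) if Z[i, j]
        }
        lab = build_label_matrix(
            pos, [str(i) for i in range(n_x)], [str(j) for j in range(n_y)]
        )
        res = PairwiseKernelRegression(Kx, Ky, lab).fit()
        assert np.abs(Kx @ res.B @ Ky - lab.Z).max() <= 1e-8

    def test_singular_kernel_error_mentions_jitter(self):
        lab = build_label_matrix({("d0", "t0")}, ["d0", "d1"], ["t0", "t1"])
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            PairwiseKernelRegression(np.ones((2, 2)), np.eye(2), lab).fit()

    def test_misaligned_kernel_order_rejected(self):
        lab = build_label_matrix({("d0", "t0")}, ["d0", "d1"], ["t0", "t1"])
        from pharmlink.similarity import SimilarityMatrix

        K = SimilarityMatrix(["d1", "d0"], np.eye(2), "chem")
        with pytest.raises(ValueError, match="order"):
            PairwiseKernelRegression(K, np.eye(2), lab)


class TestFitRegularized:
    @pytest.fixture()
    def instance(self):
        rng = np.random.default_rng(9)
        n_x, n_y = 6, 5
        Kx = random_spd_kernel(n_x, rng)
        Ky = random_spd_kernel(n_y, rng)
        Z = (rng.random((n_x, n_y)) < 0.4).astype(float)
        pos = {
            (str(i), str(j)) for i in range(n_x) for j in range(n_y) if Z[i, j]
        }
        lab = build_label_matrix(
            pos, [str(i) for i in range(n_x)], [str(j) for j in range(n_y)]
        )
        return PairwiseKernelRegression(Kx, Ky, lab)

    def test_full_rank_equals_unregularized(self, instance):
        full = instance.fit()
        reg = instance.fit_regularized(q=5)
        np.testing.assert_allclose(reg.B, full.B, atol=1e-10)

    def test_rank_one_label_matrix_lossless_at_q1(self):
        rng = np.random.default_rng(4)
        Kx = random_spd_kernel(4, rng)
        Ky = random_spd_kernel(3, rng)
        # Z of true rank one: a single drug interacting with every target
        pos = {("0", str(j)) for j in range(3)}
        lab = build_label_matrix(pos, [str(i) for i in range(4)], [str(j) for j in range(3)])
        model = PairwiseKernelRegression(Kx, Ky, lab)
        np.testing.assert_allclose(
            model.fit_regularized(q=1).B, model.fit().B, atol=1e-10
        )

    def test_matches_independent_svd_truncation(self, instance):
        """Rank-q weights agree with a separately computed SVD route."""
        from scipy.linalg import svd as scipy_svd

        q = 2
        reg = instance.fit_regularized(q=q)
        U, s, Vt = scipy_svd(instance.labels.Z)
        Zq = U[:, :q] @ np.diag(s[:q]) @ Vt[:q]
        expected = np.linalg.inv(instance.K_x) @ Zq @ np.linalg.inv(instance.K_y)
        np.testing.assert_allclose(reg.B, expected, atol=1e-8)

    def test_out_of_range_q_rejected(self, instance):
        with pytest.raises(ValueError):
            instance.fit(q=0)
        with pytest.raises(ValueError):
            instance.fit(q=6)

    def test_reconstruction_error_nonincreasing_in_q(self, instance):
        errs = []
        for q in range(1, 6):
            res = instance.fit(q=q)
            errs.append(np.linalg.norm(instance.labels.Z - res.fittedvalues))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))


class TestPredict:
    def test_identity_kernels_training_scores_equal_Z(self):
        lab = build_label_matrix(
            {("d0", "t0"), ("d1", "t2")}, ["d0", "d1"], ["t0", "t1", "t2"]
        )
        res = PairwiseKernelRegression(np.eye(2), np.eye(3), lab).fit()
        np.testing.assert_allclose(res.predict(), lab.Z, atol=1e-12)

    def test_zero_kernel_row_scores_zero(self):
        rng = np.random.default_rng(2)
        Kx, Ky = random_spd_kernel(3, rng), random_spd_kernel(4, rng)
        pos = {("0", "1"), ("2", "3")}
        lab = build_label_matrix(pos, ["0", "1", "2"], ["0", "1", "2", "3"])
        res = PairwiseKernelRegression(Kx, Ky, lab).fit()
        scores = res.predict(kx_new=np.zeros((1, 3)), ky_new=Ky)
        np.testing.assert_allclose(scores, 0.0)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(11)
        n_x, n_y = 5, 4
        Kx, Ky = random_spd_kernel(n_x, rng), random_spd_kernel(n_y, rng)
        Z = (rng.random((n_x, n_y)) < 0.4).astype(float)
        pos = {(str(i), str(j)) for i in range(n_x) for j in range(n_y) if Z[i, j]}
        lab = build_label_matrix(
            pos, [str(i) for i in range(n_x)], [str(j) for j in range(n_y)]
        )
        res = PairwiseKernelRegression(Kx, Ky, lab).fit()
        kx_new = rng.random((3, n_x))
        ky_new = rng.random((2, n_y))
        scores = res.predict(kx_new, ky_new)
        for a in range(3):
            for b in range(2):
                brute = sum(
                    res.B[i, j] * kx_new[a, i] * ky_new[b, j]
                    for i in range(n_x)
                    for j in range(n_y)
                )
                assert scores[a, b] == pytest.approx(brute, abs=1e-10)

    def test_wrong_column_count_rejected(self):
        lab = build_label_matrix({("d0", "t0")}, ["d0"], ["t0"])
        res = PairwiseKernelRegression(np.eye(1), np.eye(1), lab).fit()
        with pytest.raises(ValueError, match="columns"):
            res.predict(kx_new=np.ones((1, 2)))


class TestFactorizationIdentity:
    def test_agrees_with_explicit_pairwise_space_model(self):
        """Tensor-product factorization equals the pairwise-space solution.

        The whole point of folding the weights into B is to avoid the
        (n_x n_y) x (n_x n_y) pairwise kernel; on small instances the two
        routes must agree to numerical precision.
        """
        rng = np.random.default_rng(21)
        for _ in range(10):
            n_x = int(rng.integers(2, 8))
            n_y = int(rng.integers(2, 100 // n_x + 1))
            Kx = random_spd_kernel(n_x, rng, jitter=1e-6)
            Ky = random_spd_kernel(n_y, rng, jitter=1e-6)
            Z = (rng.random((n_x, n_y)) < 0.35).astype(float)
            pos = {
                (str(i), str(j)) for i in range(n_x) for j in range(n_y) if Z[i, j]
            }
            lab = build_label_matrix(
                pos, [str(i) for i in range(n_x)], [str(j) for j in range(n_y)]
            )
            res = PairwiseKernelRegression(Kx, Ky, lab).fit()
            # explicit pairwise-space least squares on the tensor kernel
            K_pair = np.kron(Kx, Ky)
            beta = np.linalg.solve(K_pair, lab.Z.ravel())
            kq = rng.random((2, n_x))
            kt = rng.random((3, n_y))
            fast = res.predict(kq, kt)
            slow = (np.kron(kq, kt) @ beta).reshape(2, 3)
            assert np.abs(fast - slow).max() <= 1e-8

    def test_consistent_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(31)
        n_x, n_y = 6, 4
        Kx, Ky = random_spd_kernel(n_x, rng), random_spd_kernel(n_y, rng)
        Z = (rng.random((n_x, n_y)) < 0.4).astype(float)
        drugs = [f"d{i}" for i in range(n_x)]
        targets = [f"t{j}" for j in range(n_y)]
        pos = {
            (drugs[i], targets[j]) for i in range(n_x) for j in range(n_y) if Z[i, j]
        }
        lab = build_label_matrix(pos, drugs, targets)
        base = PairwiseKernelRegression(Kx, Ky, lab).fit().predict()

        pi = rng.permutation(n_x)
        pj = rng.permutation(n_y)
        lab2 = build_label_matrix(
            pos, [drugs[i] for i in pi], [targets[j] for j in pj]
        )
        perm = (
            PairwiseKernelRegression(Kx[np.ix_(pi, pi)], Ky[np.ix_(pj, pj)], lab2)
            .fit()
            .predict()
        )
        np.testing.assert_allclose(perm, base[np.ix_(pi, pj)], atol=1e-8)

    def test_scores_linear_in_labels(self):
        rng = np.random.default_rng(41)
        Kx, Ky = random_spd_kernel(5, rng), random_spd_kernel(4, rng)
        drugs = [str(i) for i in range(5)]
        targets = [str(j) for j in range(4)]
        pos = {("0", "1"), ("2", "2"), ("4", "0")}
        lab1 = build_label_matrix(pos, drugs, targets)
        lab2 = build_label_matrix(pos, drugs, targets, label_scale=2.0)
        s1 = PairwiseKernelRegression(Kx, Ky, lab1).fit().predict()
        s2 = PairwiseKernelRegression(Kx, Ky, lab2).fit().predict()
        np.testing.assert_allclose(s2, 2 * s1, atol=1e-9)


class TestRankPredictions:
    def test_threshold_above_max_gives_empty(self):
        scores = np.array([[1.0, 2.0]])
        assert rank_predictions(scores, ["d"], ["t1", "t2"], set(), 5.0) == []

    def test_all_pairs_when_threshold_minus_inf(self):
        scores = np.array([[1.0, 2.0]])
        out = rank_predictions(scores, ["d"], ["t1", "t2"], set(), -np.inf)
        assert [(d, t) for d, t, _ in out] == [("d", "t2"), ("d", "t1")]

    def test_known_pairs_excluded(self):
        scores = np.array([[3.0, 2.0]])
        out = rank_predictions(scores, ["d"], ["t1", "t2"], {("d", "t1")}, 0.0)
        assert [(d, t) for d, t, _ in out] == [("d", "t2")]

    def test_ties_broken_lexicographically(self):
        scores = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = rank_predictions(
            scores, ["db", "da"], ["t2", "t1"], set(), 0.5
        )
        assert [(d, t) for d, t, _ in out] == [
            ("da", "t1"), ("da", "t2"), ("db", "t1"), ("db", "t2")
        ]


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    Kx, Ky = random_spd_kernel(3, rng), random_spd_kernel(2, rng)
    lab = build_label_matrix({("0", "1")}, ["0", "1", "2"], ["0", "1"])
    res = PairwiseKernelRegression(Kx, Ky, lab).fit()
    res.save(tmp_path / "model")
    from pharmlink.pkr import PKRResults

    back = PKRResults.load(tmp_path / "model")
    np.testing.assert_allclose(back.B, res.B, atol=1e-10)
    assert back.model.drug_ids == res.model.drug_ids
    np.testing.assert_allclose(back.fittedvalues, res.fittedvalues, atol=1e-8)
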