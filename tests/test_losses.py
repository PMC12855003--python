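import numpy as np
import pytest

import scouter as sc
from scouter.losses import TripletBatch, total_loss_and_grad


def naive_autofocus(X, Xhat, P, gamma):
    """Literal double-sum over perturbation groups, cells and genes."""
    perts = sorted(set(P))
    m = len(perts)
    G = X.shape[1]
    total = 0.0
    for t in perts:
        rows = [i for i, p in enumerate(P) if p == t]
        inner = 0.0
        for i in rows:
            for g in range(G):
                inner += abs(X[i, g] - Xhat[i, g]) ** (2 + gamma)
        total += inner / (len(rows) * G)
    return total / m


def naive_direction(X, C, Xhat, P):
    perts = sorted(set(P))
    m = len(perts)
    G = X.shape[1]

    def sgn(v):
        return 0.0 if v == 0 else (1.0 if v > 0 else -1.0)

    total = 0.0
    for t in perts:
        rows = [i for i, p in enumerate(P) if p == t]
        inner = 0.0
        for i in rows:
            for g in range(G):
                inner += (sgn(X[i, g] - C[i, g]) - sgn(Xhat[i, g] - C[i, g])) ** 2
        total += inner / (len(rows) * G)
    return total / m


def random_batch(rng, n_max=10, g_max=8):
    n = int(rng.integers(1, n_max + 1))
    g = int(rng.integers(2, g_max + 1))
    n_perts = int(rng.integers(1, n + 1))
    P = [f"p{rng.integers(0, n_perts)}" for _ in range(n)]
    batch = TripletBatch(
        X=rng.normal(size=(n, g)),
        C=rng.normal(size=(n, g)),
        P=P,
        E=rng.normal(size=(n, 3)),
    )
    return batch, rng.normal(size=(n, g))


class TestOracleEquivalence:
    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_autofocus_matches_triple_loop(self, gamma):
        rng = np.random.default_rng(17)
        for _ in range(25):
            batch, xhat = random_batch(rng)
            assert sc.autofocus_loss(batch, xhat, gamma) == pytest.approx(
                naive_autofocus(batch.X, xhat, batch.P, gamma), abs=1e-12)

    def test_direction_matches_triple_loop(self):
        rng = np.random.default_rng(18)
        for _ in range(25):
            batch, xhat = random_batch(rng)
            assert sc.direction_loss(batch, xhat) == pytest.approx(
                naive_direction(batch.X, batch.C, xhat, batch.P), abs=1e-12)

    def test_hand_picked_two_gene_batch(self):
        # N=3 triplets over M=2 perturbations, |G|=2, gamma=0:
        # group a: rows 0,1 -> ((0.5^2+0^2)+(1^2+2^2))/(2*2) = 1.3125
        # group b: row 2 -> (1^2+3^2)/2 = 5 ; mean over M=2 -> 3.15625
        X = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, -1.0]])
        Xhat = np.array([[0.5, 2.0], [1.0, 3.0], [1.0, 2.0]])
        batch = TripletBatch(X=X, C=np.zeros((3, 2)), P=["a", "a", "b"], E=np.zeros((3, 1)))
        assert sc.autofocus_loss(batch, Xhat, 0.0) == pytest.approx(3.15625, abs=1e-12)

    def test_weighted_total_matches_oracle(self):
        rng = np.random.default_rng(19)
        batch, xhat = random_batch(rng)
        lam = 0.05
        expected = naive_autofocus(batch.X, xhat, batch.P, 0.0) + lam * naive_direction(
            batch.X, batch.C, xhat, batch.P)
        assert sc.total_loss(batch, xhat, 0.0, lam) == pytest.approx(expected, abs=1e-12)


class TestReductionsAndConventions:
    def test_perfect_prediction_is_zero(self):
        rng = np.random.default_rng(1)
        batch, _ = random_batch(rng)
        assert sc.autofocus_loss(batch, batch.X, 0.0) == 0.0
        assert sc.total_loss(batch, batch.X, 2.0, 0.5) >= 0.0

    def test_gamma_zero_single_group_is_plain_mse(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 5))
        Xhat = rng.normal(size=(4, 5))
        batch = TripletBatch(X=X, C=np.zeros_like(X), P=["p"] * 4, E=np.zeros((4, 2)))
        assert sc.autofocus_loss(batch, Xhat, 0.0) == pytest.approx(
            np.mean((X - Xhat) ** 2), abs=1e-12)

    def test_sign_zero_convention(self):
        # predicted no change (xhat == c) against a true change of either
        # sign contributes (+-1 - 0)^2 = 1 per entry
        X = np.array([[1.0, -1.0]])
        C = np.zeros((1, 2))
        batch = TripletBatch(X=X, C=C, P=["p"], E=np.zeros((1, 1)))
        assert sc.direction_loss(batch, C.copy()) == pytest.approx(1.0)

    def test_flipped_sign_penalty(self):
        # one of two genes flips sign: (1 - (-1))^2 / 2 = 2
        X = np.array([[1.0, 1.0]])
        C = np.zeros((1, 2))
        Xhat = np.array([[-1.0, 1.0]])
        batch = TripletBatch(X=X, C=C, P=["p"], E=np.zeros((1, 1)))
        assert sc.direction_loss(batch, Xhat) == pytest.approx(2.0)

    def test_entries_limited_to_0_1_4(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            batch, xhat = random_batch(rng)
            term = (np.sign(batch.X - batch.C) - np.sign(xhat - batch.C)) ** 2
            assert set(np.unique(term)).issubset({0.0, 1.0, 4.0})

    def test_lambda_zero_drops_direction_term(self):
        rng = np.random.default_rng(4)
        batch, xhat = random_batch(rng)
        assert sc.total_loss(batch, xhat, 0.0, 0.0) == sc.autofocus_loss(batch, xhat, 0.0)


class TestPerPerturbationWeighting:
    def test_duplicating_cells_within_group_preserves_loss(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(2, 3))
        Xhat = rng.normal(size=(2, 3))
        C = rng.normal(size=(2, 3))
        one = TripletBatch(X=X[:1], C=C[:1], P=["a"], E=np.zeros((1, 1)))
        # duplicate the single cell of group "a" three times
        dup = TripletBatch(
            X=np.repeat(X[:1], 3, axis=0), C=np.repeat(C[:1], 3, axis=0),
            P=["a"] * 3, E=np.zeros((3, 1)))
        dup_hat = np.repeat(Xhat[:1], 3, axis=0)
        assert sc.autofocus_loss(dup, dup_hat, 0.0) == pytest.approx(
            sc.autofocus_loss(one, Xhat[:1], 0.0), abs=1e-12)
        assert sc.direction_loss(dup, dup_hat) == pytest.approx(
            sc.direction_loss(one, Xhat[:1]), abs=1e-12)

    def test_adding_a_group_changes_m_weighting(self):
        X = np.array([[2.0, 0.0], [0.0, 0.0]])
        Xhat = np.zeros((2, 2))
        one_group = TripletBatch(X=X[:1], C=np.zeros((1, 2)), P=["a"], E=np.zeros((1, 1)))
        two_groups = TripletBatch(X=X, C=np.zeros((2, 2)), P=["a", "b"], E=np.zeros((2, 1)))
        # second group is perfectly predicted, so the mean over M=2 halves the loss
        assert sc.autofocus_loss(two_groups, Xhat, 0.0) == pytest.approx(
            0.5 * sc.autofocus_loss(one_group, Xhat[:1], 0.0), abs=1e-12)


class TestGradient:
    def test_value_matches_exact_loss(self):
        rng = np.random.default_rng(7)
        batch, xhat = random_batch(rng)
        v, _ = total_loss_and_grad(batch, xhat, 2.0, 0.1)
        assert v == pytest.approx(sc.total_loss(batch, xhat, 2.0, 0.1), abs=1e-12)

    @pytest.mark.parametrize("gamma", [0.0, 2.0])
    def test_autofocus_gradient_finite_difference(self, gamma):
        rng = np.random.default_rng(8)
        batch, xhat = random_batch(rng, n_max=4, g_max=4)
        _, grad = total_loss_and_grad(batch, xhat, gamma, 0.0)
        eps = 1e-6
        for _ in range(10):
            i = rng.integers(0, xhat.shape[0])
            g = rng.integers(0, xhat.shape[1])
            up, down = xhat.copy(), xhat.copy()
            up[i, g] += eps
            down[i, g] -= eps
            num = (sc.autofocus_loss(batch, up, gamma) -
                   sc.autofocus_loss(batch, down, gamma)) / (2 * eps)
            assert grad[i, g] == pytest.approx(num, abs=1e-5, rel=1e-4)

    def test_direction_surrogate_adds_gradient(self):
        rng = np.random.default_rng(9)
        batch, xhat = random_batch(rng)
        _, g_plain = total_loss_and_grad(batch, xhat, 0.0, 0.5)
        _, g_smooth = total_loss_and_grad(batch, xhat, 0.0, 0.5,
                                          direction_surrogate_alpha=5.0)
        assert not np.allclose(g_plain, g_smooth)
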