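import numpy as np
import pytest

import dropfuse as df
from dropfuse.vgae import EncoderParams, VGAEConfig


class TestNormalizeSimilarity:
    def test_identity_fixed_point(self):
        np.testing.assert_array_equal(
            df.normalize_similarity(np.eye(4)), np.eye(4))

    def test_all_ones_two_by_two(self):
        out = df.normalize_similarity(np.ones((2, 2)))
        np.testing.assert_allclose(out, np.full((2, 2), 0.5), atol=1e-15)

    def test_loop_oracle(self, rng):
        S = rng.random((5, 5))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 1.0)
        out = df.normalize_similarity(S)
        d = S.sum(axis=1)
        expected = np.empty_like(S)
        for i in range(5):
            for j in range(5):
                expected[i, j] = S[i, j] / np.sqrt(d[i] * d[j])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, out.T, atol=1e-12)

    def test_zero_diagonal_gets_self_loop(self):
        S = np.array([[0.0, 0.0], [0.0, 0.0]])
        out = df.normalize_similarity(S)
        np.testing.assert_allclose(out, np.eye(2))


class TestEncode:
    def _params(self, rng, f, h, l):
        return EncoderParams(W0=rng.normal(size=(f, h)),
                             Wmu=rng.normal(size=(h, l)),
                             Wsig=rng.normal(size=(h, l)))

    def test_zero_weights_give_zero(self, rng):
        S = df.normalize_similarity(rng.random((4, 4)) + np.eye(4))
        A = rng.random((4, 3))
        p = EncoderParams(np.zeros((3, 5)), np.zeros((5, 2)),
                          np.zeros((5, 2)))
        mu, logsig = df.encode(S, A, p)
        assert np.all(mu == 0) and np.all(logsig == 0)

    def test_identity_graph_reduces_to_mlp(self, rng):
        A = rng.normal(size=(6, 4))
        p = self._params(rng, 4, 5, 2)
        mu, _ = df.encode(np.eye(6), A, p)
        expected = np.maximum(A @ p.W0, 0.0) @ p.Wmu
        np.testing.assert_allclose(mu, expected, atol=1e-12)

    def test_hand_multiplication_oracle(self, rng):
        S = df.normalize_similarity(
            0.5 * (rng.random((4, 4)) + rng.random((4, 4)).T) + np.eye(4))
        A = rng.normal(size=(4, 2))
        p = self._params(rng, 2, 2, 2)
        mu, logsig = df.encode(S, A, p)
        hidden = np.zeros((4, 2))
        SA = np.zeros((4, 2))
        for i in range(4):
            for j in range(2):
                SA[i, j] = sum(S[i, t] * A[t, j] for t in range(4))
        for i in range(4):
            for j in range(2):
                hidden[i, j] = max(
                    sum(SA[i, t] * p.W0[t, j] for t in range(2)), 0.0)
        smoothed = np.zeros((4, 2))
        for i in range(4):
            for j in range(2):
                smoothed[i, j] = sum(S[i, t] * hidden[t, j] for t in range(4))
        np.testing.assert_allclose(mu, smoothed @ p.Wmu, atol=1e-12)
        np.testing.assert_allclose(logsig, smoothed @ p.Wsig, atol=1e-12)

    def test_shape_mismatch_named(self, rng):
        with pytest.raises(ValueError, match="feature"):
            df.encode(np.eye(3), rng.random((4, 2)),
                      self._params(rng, 2, 3, 2))


class TestReparameterize:
    def test_zero_eps_returns_mu(self, rng):
        mu = rng.normal(size=(4, 2))
        z = df.reparameterize(mu, rng.normal(size=(4, 2)),
                              eps=np.zeros((4, 2)))
        np.testing.assert_array_equal(z, mu)

    def test_vanishing_sigma_limit(self, rng):
        mu = rng.normal(size=(3, 2))
        z = df.reparameterize(mu, np.full((3, 2), -50.0),
                              eps=rng.normal(size=(3, 2)) * 100)
        np.testing.assert_allclose(z, mu, atol=1e-15)

    def test_seeded_determinism(self, rng):
        mu, logsig = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        np.testing.assert_array_equal(
            df.reparameterize(mu, logsig, seed=9),
            df.reparameterize(mu, logsig, seed=9))


class TestDecode:
    def test_all_ones(self):
        out = df.decode(np.ones((3, 1)), np.ones((4, 1)))
        np.testing.assert_array_equal(out, np.ones((3, 4)))

    def test_orthogonal_rows_give_zero(self):
        Zg = np.array([[1.0, 0.0]])
        Zc = np.array([[0.0, 1.0]])
        assert df.decode(Zg, Zc)[0, 0] == 0.0

    def test_loop_oracle(self, rng):
        Zg, Zc = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        out = df.decode(Zg, Zc)
        for i in range(3):
            for j in range(4):
                assert out[i, j] == pytest.approx(Zg[i] @ Zc[j], abs=1e-12)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError, match="latent"):
            df.decode(rng.normal(size=(3, 2)), rng.normal(size=(4, 3)))


class TestLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        A = rng.random((4, 5))
        assert df.vgae_loss(A, A.copy(), 0.5) == 0.0

    def test_lambda_endpoints(self, rng):
        A, At = rng.random((4, 5)), rng.random((4, 5))
        l_mse = np.mean((A - At) ** 2)
        assert df.vgae_loss(A, At, 1.0) == pytest.approx(l_mse, abs=1e-12)
        cos = [1 - A[i] @ At[i] / (np.linalg.norm(A[i]) * np.linalg.norm(At[i]))
               for i in range(4)]
        assert df.vgae_loss(A, At, 0.0) == pytest.approx(np.mean(cos),
                                                         abs=1e-12)

    def test_scalar_oracle(self, rng):
        A, At = rng.random((2, 3)), rng.random((2, 3))
        lam = 0.3
        l_mse = sum((A[i, j] - At[i, j]) ** 2
                    for i in range(2) for j in range(3)) / 6
        l_cos = np.mean([
            1 - sum(A[i, j] * At[i, j] for j in range(3))
            / (np.sqrt(sum(A[i, j] ** 2 for j in range(3)))
               * np.sqrt(sum(At[i, j] ** 2 for j in range(3))))
            for i in range(2)])
        expected = lam * l_mse + (1 - lam) * l_cos
        assert df.vgae_loss(A, At, lam) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_row_contributes_one(self, rng):
        A = np.zeros((2, 3))
        A[1] = rng.random(3)
        At = rng.random((2, 3))
        cos1 = A[1] @ At[1] / (np.linalg.norm(A[1]) * np.linalg.norm(At[1]))
        assert df.vgae_loss(A, At, 0.0) == pytest.approx(
            np.mean([1.0, 1 - cos1]), abs=1e-12)


class TestTraining:
    def _problem(self, rng, n_g=20, n_c=15):
        M = rng.random((n_g, n_c)) * 3
        M[rng.random(M.shape) < 0.4] = 0.0
        SG = df.gene_jaccard(M).values
        SC = df.fuse_cell_similarity(M).values
        return SG, SC, M

    def test_loss_decreases_monitored(self, rng):
        SG, SC, M = self._problem(rng)
        cfg = VGAEConfig(hidden_dim=16, latent_dim=4, epochs=100,
                         learning_rate=1e-2, seed=0)
        lat = df.train_vgae_pair(SG, SC, M, cfg)
        ls = [h["loss"] for h in lat.loss_history]
        assert ls[-1] < ls[0]
        # monitored descent: loss 10 epochs later within 5% tolerance
        violations = sum(ls[e + 10] > ls[e] * 1.05 + 1e-9
                         for e in range(40, len(ls) - 10))
        assert violations <= 5

    def test_rank_two_reconstruction(self):
        # graph-free limit: identity similarity makes the encoder an MLP,
        # so a noiseless rank-2 target should be recovered
        rng = np.random.default_rng(0)
        U = rng.uniform(0.5, 2.0, (20, 2))
        V = rng.uniform(0.5, 2.0, (15, 2))
        logM = U @ V.T
        cfg = VGAEConfig(hidden_dim=32, latent_dim=2, epochs=500,
                         learning_rate=1e-2, seed=0)
        lat = df.train_vgae_pair(np.eye(20), np.eye(15), logM, cfg)
        At = lat.Z_g @ lat.Z_c.T
        rel = np.linalg.norm(logM - At) / np.linalg.norm(logM)
        assert rel < 0.1

    def test_seeded_determinism(self, rng):
        SG, SC, M = self._problem(rng, 12, 10)
        cfg = VGAEConfig(hidden_dim=8, latent_dim=3, epochs=25, seed=77)
        a = df.train_vgae_pair(SG, SC, M, cfg)
        b = df.train_vgae_pair(SG, SC, M, cfg)
        np.testing.assert_array_equal(a.Z_g, b.Z_g)
        np.testing.assert_array_equal(a.Z_c, b.Z_c)

    def test_latents_match_block_dims(self, rng):
        SG, SC, M = self._problem(rng, 11, 7)
        cfg = VGAEConfig(hidden_dim=8, latent_dim=3, epochs=5, seed=1)
        lat = df.train_vgae_pair(SG, SC, M, cfg)
        assert lat.Z_g.shape == (11, 3)
        assert lat.Z_c.shape == (7, 3)
        assert np.all(np.isfinite(lat.Z_g)) and np.all(np.isfinite(lat.Z_c))
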