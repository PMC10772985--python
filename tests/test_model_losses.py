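import numpy as np
import pytest
import scipy.sparse as sp

from staa import model as M


def tiny_graph(rng, n=6):
    a = (rng.random((n, n)) < 0.5).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    target = (a + np.eye(n) > 0).astype(float)
    al = a + np.eye(n)
    d = al.sum(1)
    a_hat = sp.csr_matrix(np.diag(d ** -0.5) @ al @ np.diag(d ** -0.5))
    return target, a_hat


class TestEncoder:
    def test_zero_weights_give_standard_prior(self, rng):
        params = M.GeneratorParams(W_G1=np.zeros((4, 3)),
                                   W_G2=np.zeros((3, 2)),
                                   W_G2p=np.zeros((3, 2)),
                                   W_c=np.zeros((2, 2)), b_c=np.zeros(2))
        X = rng.normal(size=(5, 4))
        _, a_hat = tiny_graph(rng, 5)
        mu, logvar = M.encode(X, a_hat, params)
        assert np.all(mu == 0) and np.all(logvar == 0)

    def test_single_node_hand_arithmetic(self):
        params = M.GeneratorParams(W_G1=np.array([[0.5]]),
                                   W_G2=np.array([[3.0]]),
                                   W_G2p=np.array([[1.0]]),
                                   W_c=np.zeros((1, 2)), b_c=np.zeros(2))
        a_hat = sp.csr_matrix([[1.0]])
        mu, logvar = M.encode(np.array([[2.0]]), a_hat, params)
        assert mu[0, 0] == pytest.approx(3.0)      # ReLU(1*2*0.5)=1, 1*1*3
        assert logvar[0, 0] == pytest.approx(1.0)

    def test_relu_clamps_negative_preactivation(self):
        params = M.GeneratorParams(W_G1=np.array([[-2.0]]),
                                   W_G2=np.array([[5.0]]),
                                   W_G2p=np.array([[5.0]]),
                                   W_c=np.zeros((1, 2)), b_c=np.zeros(2))
        a_hat = sp.csr_matrix([[1.0]])
        mu, logvar = M.encode(np.array([[2.0]]), a_hat, params)
        assert mu[0, 0] == 0.0 and logvar[0, 0] == 0.0

    def test_shape_mismatch_raises(self, rng):
        params = M.init_generator(4, 3, 2, 2, rng)
        _, a_hat = tiny_graph(rng, 5)
        with pytest.raises(ValueError):
            M.encode(rng.normal(size=(5, 7)), a_hat, params)


class TestReparameterize:
    def test_zero_epsilon_returns_mean(self, rng):
        mu = rng.normal(size=(4, 3))
        z = M.reparameterize(mu, rng.normal(size=(4, 3)), np.zeros((4, 3)))
        np.testing.assert_array_equal(z, mu)

    def test_closed_form_scaling(self):
        # sigma = exp(ln 2) = 2, so Z = 0 + 2 * 1
        z = M.reparameterize(np.zeros((1, 1)),
                             np.full((1, 1), 2 * np.log(2.0)),
                             np.ones((1, 1)))
        assert z[0, 0] == pytest.approx(2.0)

    def test_standard_normal_moments(self):
        draws = np.random.default_rng(0).standard_normal((100_000, 1))
        z = M.reparameterize(np.zeros_like(draws), np.zeros_like(draws),
                             draws)
        assert abs(z.mean()) < 0.02
        assert 0.98 < z.var() < 1.02


class TestDecoder:
    def test_zero_embedding_gives_half(self):
        np.testing.assert_allclose(M.decode(np.zeros((3, 2))), 0.5)

    def test_antipodal_pair_closed_form(self):
        a = M.decode(np.array([[1.0], [-1.0]]))
        assert a[0, 1] == pytest.approx(1 / (1 + np.e), abs=1e-12)
        assert a[0, 1] == pytest.approx(0.2689, abs=1e-4)

    def test_symmetry(self, rng):
        a = M.decode(rng.normal(size=(10, 4)))
        assert np.abs(a - a.T).max() < 1e-12
        assert np.all((a > 0) & (a < 1))


class TestVgaeLoss:
    def test_prior_posterior_match_gives_zero_kl(self):
        assert M.kl_divergence(np.zeros((5, 3)), np.zeros((5, 3))) == 0.0

    def test_unit_mean_shift_kl(self):
        # KL(N(1,1) || N(0,1)) = 0.5 per spot, single latent dim
        assert M.kl_divergence(np.ones((1, 1)),
                               np.zeros((1, 1))) == pytest.approx(0.5)

    def test_kl_closed_form_random(self, rng):
        for _ in range(20):
            mu = rng.normal(size=(7, 4))
            logvar = rng.normal(size=(7, 4))
            expected = 0.5 / 7 * np.sum(mu ** 2 + np.exp(logvar) - 1
                                        - logvar)
            assert M.kl_divergence(mu, logvar) == pytest.approx(
                expected, abs=1e-12)
            assert M.kl_divergence(mu, logvar) >= 0

    def test_unweighted_bce_single_entry(self):
        # target 1 predicted 0.5: contribution -log 0.5
        s = np.zeros((1, 1))
        t = np.ones((1, 1))
        assert M.reconstruction_bce(s, t, pos_weight=1.0) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_rejects_non_binary_target(self, rng):
        with pytest.raises(ValueError, match="binary"):
            M.loss_vgae(np.full((2, 2), 0.5), np.zeros((2, 2)),
                        np.zeros((2, 1)), np.zeros((2, 1)), 1.0, 1.0)

    def test_moving_prediction_toward_target_decreases_loss(self, rng):
        target, _ = tiny_graph(rng)
        s = rng.normal(size=target.shape)
        s = (s + s.T) / 2
        base = M.reconstruction_bce(s, target, pos_weight=2.0)
        # push one logit toward its target's sign
        i, j = 0, 1
        step = 0.1 if target[i, j] == 1 else -0.1
        s2 = s.copy()
        s2[i, j] += step
        assert M.reconstruction_bce(s2, target, pos_weight=2.0) < base


class TestClassifier:
    def test_zero_weights_uniform(self, rng):
        probs = M.classify(rng.normal(size=(6, 3)), np.zeros((3, 4)),
                           np.zeros(4))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_dominant_logit_saturates(self):
        w = np.zeros((1, 3))
        probs = M.classify(np.ones((1, 1)), w, np.array([50.0, 0.0, 0.0]))
        assert probs[0, 0] > 0.999999

    def test_rows_sum_to_one(self, rng):
        probs = M.classify(rng.normal(size=(20, 5)),
                           rng.normal(size=(5, 7)), rng.normal(size=7))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)
        assert M.loss_classifier(np.arange(3), probs) == pytest.approx(0.0)

    def test_uniform_prediction_log_k(self):
        probs = np.full((10, 7), 1 / 7)
        assert M.loss_classifier(np.zeros(10, dtype=int),
                                 probs) == pytest.approx(np.log(7),
                                                         abs=1e-12)

    def test_two_sample_closed_form(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        got = M.loss_classifier(np.array([0, 0]), probs)
        assert got == pytest.approx(-(np.log(0.5) + np.log(0.25)) / 2,
                                    abs=1e-12)
        assert got == pytest.approx(1.0397, abs=1e-4)

    def test_out_of_range_label_raises(self):
        with pytest.raises(ValueError):
            M.loss_classifier(np.array([3]), np.full((1, 3), 1 / 3))


class TestCritic:
    def test_all_zero_weights_score_zero(self):
        critic = M.CriticParams(W_R1=np.zeros((3, 4)), b_R1=np.zeros(4),
                                W_R2=np.zeros((4, 2)), b_R2=np.zeros(2),
                                W_R3=np.zeros((2, 1)), b_R3=np.zeros(1))
        s = M.critic_score(np.ones((5, 3)), critic)
        np.testing.assert_array_equal(s, 0.0)

    def test_scalar_chain_forward_value(self):
        critic = M.CriticParams(W_R1=np.zeros((1, 1)), b_R1=np.zeros(1),
                                W_R2=np.zeros((1, 1)), b_R2=np.zeros(1),
                                W_R3=np.full((1, 1), 2.0), b_R3=np.zeros(1))
        s = M.critic_score(np.array([[7.0]]), critic)
        assert s[0] == pytest.approx(1.0)  # 2 * sigma(sigma(0) * 0) = 1

    def test_constant_when_first_layer_zero(self, rng):
        critic = M.init_critic(3, (4, 2), rng, scale=0.5)
        critic.W_R1[:] = 0.0
        s1 = M.critic_score(rng.normal(size=(6, 3)), critic)
        s2 = M.critic_score(rng.normal(size=(6, 3)), critic)
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestWassersteinLoss:
    def test_identical_scores_zero(self, rng):
        s = rng.normal(size=50)
        assert M.loss_wasserstein(s, s) == pytest.approx(0.0)

    def test_unit_mean_gap(self):
        assert M.loss_wasserstein(np.ones(10), np.zeros(10)) == -1.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert M.loss_wasserstein(a, b) == pytest.approx(
            -M.loss_wasserstein(b, a))

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            M.loss_wasserstein(np.array([]), np.ones(3))


class TestCombinedLoss:
    def test_lambda_one_silences_classifier(self):
        assert M.combined_loss(2.0, 99.0, 1.0, 1.0) == 1.0

    def test_midpoint_arithmetic(self):
        assert M.combined_loss(2.0, 4.0, 1.0, 0.5) == 2.0

    def test_lambda_zero_silences_reconstruction(self):
        assert M.combined_loss(99.0, 4.0, 1.0, 0.0) == 3.0

    def test_lambda_out_of_range_raises(self):
        with pytest.raises(ValueError):
            M.combined_loss(1.0, 1.0, 0.0, 1.5)


def test_fast_generator_path_matches_reference_bce(rng):
    """The sparse-aware BCE inside the generator equals the direct formula."""
    target, a_hat = tiny_graph(rng, 8)
    params = M.init_generator(5, 4, 3, 2, rng)
    X = rng.normal(size=(8, 5))
    eps = rng.normal(size=(8, 3))
    pw = M.adjacency_pos_weight(target)
    bundle, _, _, mu, Z = M.generator_loss_and_grads(
        params, X, a_hat, target, None, eps, 1.0, pw, 1 / 8)
    assert bundle.recon_bce == pytest.approx(
        M.reconstruction_bce(Z @ Z.T, target, pw), abs=1e-10)
    assert bundle.combined == pytest.approx(bundle.L1, abs=1e-12)
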