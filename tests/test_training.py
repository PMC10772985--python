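import numpy as np
import pytest

from staa import model as M
from staa.config import RunConfig, ablate
from staa.pre_clustering import initial_labels
from staa.preprocessing import normalize_counts, scale_features, select_hvg
from staa.spatial_graph import build_knn_graph
from staa.training import Adam, RMSprop, TrainingTrace, train


@pytest.fixture(scope="module")
def small_inputs(small_tissue):
    norm = normalize_counts(small_tissue.expression)
    hvg, _ = select_hvg(norm, 60)
    X = scale_features(hvg)
    graph = build_knn_graph(small_tissue.coordinates, 4)
    y = initial_labels(hvg, "gmm", 2, seed=0)
    return X, graph, y


def small_config(**kw):
    base = dict(n_clusters=2, k_neighbors=4, hidden_dim=16, latent_dim=4,
                epochs=2, seed=0)
    base.update(kw)
    return RunConfig(**base)


class TestTrain:
    def test_two_epochs_finite_trace(self, small_inputs):
        X, graph, y = small_inputs
        model = train(X, graph, y, small_config())
        assert len(model.trace.records) == 2
        for rec in model.trace.records:
            assert all(np.isfinite(v) for v in rec.values())
        assert model.embedding.shape == (100, 4)

    def test_seeded_determinism(self, small_inputs):
        X, graph, y = small_inputs
        a = train(X, graph, y, small_config(epochs=5, seed=42))
        b = train(X, graph, y, small_config(epochs=5, seed=42))
        np.testing.assert_array_equal(a.embedding, b.embedding)

    def test_different_seeds_differ(self, small_inputs):
        X, graph, y = small_inputs
        a = train(X, graph, y, small_config(epochs=3, seed=1))
        b = train(X, graph, y, small_config(epochs=3, seed=2))
        assert not np.array_equal(a.embedding, b.embedding)

    def test_critic_weights_clipped(self, small_inputs):
        X, graph, y = small_inputs
        cfg = small_config(epochs=10)
        model = train(X, graph, y, cfg)
        for arr in model.critic.as_dict().values():
            assert np.all(np.abs(arr) <= cfg.clip_value + 1e-12)

    def test_no_wgan_has_no_critic_and_zero_l3(self, small_inputs):
        X, graph, y = small_inputs
        model = train(X, graph, y, ablate(small_config(), no_wgan=True))
        assert model.critic is None
        assert all(rec["L3"] == 0.0 for rec in model.trace.records)

    def test_no_classifier_accepts_missing_labels(self, small_inputs):
        X, graph, _ = small_inputs
        cfg = ablate(small_config(), no_classifier=True)
        model = train(X, graph, None, cfg)
        assert all(rec["L2"] == 0.0 for rec in model.trace.records)

    def test_classifier_without_labels_rejected(self, small_inputs):
        X, graph, _ = small_inputs
        with pytest.raises(ValueError, match="labels"):
            train(X, graph, None, small_config())

    def test_parameter_isolation(self, small_inputs, rng):
        """Critic updates leave the generator untouched and vice versa."""
        X, graph, y = small_inputs
        params = M.init_generator(X.shape[1], 8, 4, 2, rng)
        critic = M.init_critic(4, (6, 4), rng)
        gen_before = {k: v.copy() for k, v in params.as_dict().items()}
        critic_before = {k: v.copy() for k, v in critic.as_dict().items()}

        # a critic step touches only critic weights
        cdict = critic.as_dict()
        opt = RMSprop({k: v.shape for k, v in cdict.items()}, lr=1e-3)
        _, cgrads = M.critic_loss_and_grads(
            critic, rng.normal(size=(20, 4)), rng.normal(size=(20, 4)))
        opt.step(cdict, cgrads)
        for k, v in params.as_dict().items():
            np.testing.assert_array_equal(v, gen_before[k])
        assert any(not np.array_equal(cdict[k], critic_before[k])
                   for k in cdict)

        # a generator step touches only generator weights
        critic_mid = {k: v.copy() for k, v in critic.as_dict().items()}
        target = np.asarray(
            (graph.adjacency[:20, :20].todense() + np.eye(20)) > 0,
            dtype=float)
        a_hat = graph.normalized_adjacency[:20, :20]
        _, grads, _, _, _ = M.generator_loss_and_grads(
            params, X[:20], a_hat, target, y.labels[:20],
            rng.normal(size=(20, 4)), 0.5,
            M.adjacency_pos_weight(target), 1 / 20, critic=critic)
        pdict = params.as_dict()
        gopt = Adam({k: v.shape for k, v in pdict.items()}, lr=1e-2)
        gopt.step(pdict, grads)
        for k in critic_mid:
            np.testing.assert_array_equal(critic.as_dict()[k],
                                          critic_mid[k])
        assert any(not np.array_equal(pdict[k], gen_before[k])
                   for k in pdict)


class TestAblate:
    def test_both_flags_reduce_to_plain_vgae(self):
        cfg = ablate(small_config(), no_wgan=True, no_classifier=True)
        assert not cfg.use_wgan and not cfg.use_classifier
        assert cfg.lambda_weight == 1.0

    def test_no_wgan_only(self):
        cfg = ablate(small_config(lambda_weight=0.3), no_wgan=True)
        assert not cfg.use_wgan
        assert cfg.use_classifier and cfg.lambda_weight == 0.3

    def test_default_flags_identity(self):
        cfg = small_config(lambda_weight=0.3)
        assert ablate(cfg) == cfg


def test_trace_rejects_nonfinite_losses():
    trace = TrainingTrace()
    bad = M.LossBundle(recon_bce=np.nan, kl=0, L1=np.nan, L2=0, L3=0,
                       combined=np.nan)
    with pytest.raises(FloatingPointError):
        trace.append(0, bad)


def test_optimizers_descend_simple_quadratic():
    # sanity on the two hand-rolled optimizers: minimize ||w||^2
    for opt_cls, lr in ((Adam, 0.1), (RMSprop, 0.05)):
        w = {"w": np.array([3.0, -2.0])}
        opt = opt_cls({"w": (2,)}, lr=lr)
        for _ in range(200):
            opt.step(w, {"w": 2 * w["w"]})
        assert np.linalg.norm(w["w"]) < 0.3
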