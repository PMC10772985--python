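"""Alternating minimax training of the adversarial graph autoencoder.

Each epoch runs ``critic_steps`` critic updates (RMSprop, weight clipping to
[-clip_value, clip_value] after every step, fresh prior draws r ~ N(0, I)
each step, the current embedding treated as a constant) followed by one
generator/classifier update (Adam) on lambda*L1 + (1-lambda)*L2 - mean(R(Z)).
The downstream embedding is the posterior mean mu of a final encoder pass,
which keeps clustering deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp

from . import model as M
from .config import RunConfig
from .types import LabelVector, SpatialGraph


class Adam:
    def __init__(self, shapes: Dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop:
    def __init__(self, shapes: Dict[str, tuple], lr: float,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.sq = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.sq[k] = self.alpha * self.sq[k] + (1 - self.alpha) * g * g
            params[k] -= self.lr * g / (np.sqrt(self.sq[k]) + self.eps)


@dataclass
class TrainingTrace:
    records: List[Dict] = field(default_factory=list)

    def append(self, epoch: int, bundle: M.LossBundle) -> None:
        rec = {"epoch": epoch, "recon_bce": bundle.recon_bce,
               "kl": bundle.kl, "L1": bundle.L1, "L2": bundle.L2,
               "L3": bundle.L3, "combined": bundle.combined}
        if not all(np.isfinite(v) for v in rec.values()):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {rec}")
        self.records.append(rec)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.records).to_csv(path, index=False)


@dataclass
class TrainedModel:
    params: M.GeneratorParams
    critic: Optional[M.CriticParams]
    embedding: np.ndarray          # posterior mean mu, n_spots x latent_dim
    initial_embedding: np.ndarray  # mu of the untrained encoder
    config: RunConfig
    trace: TrainingTrace

    def save(self, path) -> None:
        """Checkpoint weights + config to a single .npz archive."""
        arrays = {f"gen_{k}": v for k, v in self.params.as_dict().items()}
        if self.critic is not None:
            arrays.update({f"critic_{k}": v
                           for k, v in self.critic.as_dict().items()})
        arrays["embedding"] = self.embedding
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)


def train(X: np.ndarray, graph: SpatialGraph, y: Optional[LabelVector],
          config: RunConfig) -> TrainedModel:
    """Run the full adversarial optimization on one tissue section.

    ``X`` is the (scaled) feature matrix, ``graph`` carries both the binary
    adjacency (reconstruction target, with self-loops added) and its
    normalized form (encoder operator).  ``y`` supplies classifier labels;
    it may be None only when the classifier is ablated.
    """
    n = X.shape[0]
    if graph.n_spots != n:
        raise ValueError("graph and feature matrix disagree on spot count")
    if config.use_classifier and y is None:
        raise ValueError("classifier enabled but no labels supplied")
    if y is not None and len(y) != n:
        raise ValueError("label vector length mismatch")
    if graph.normalized_adjacency is None:
        raise ValueError("graph has no normalized adjacency")

    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    labels = y.labels if (y is not None and config.use_classifier) else None
    n_classes = (int(labels.max()) + 1) if labels is not None else 2
    lam = 1.0 if labels is None else config.lambda_weight

    dtype = np.float32  # training precision; analytic grads are dtype-generic
    X = np.ascontiguousarray(X, dtype=dtype)
    params = M.init_generator(X.shape[1], config.hidden_dim,
                              config.latent_dim, n_classes, rng)
    critic = (M.init_critic(config.latent_dim, config.critic_hidden, rng)
              if config.use_wgan else None)
    for holder in filter(None, (params, critic)):
        for k, v in holder.as_dict().items():
            setattr(holder, k, v.astype(dtype))

    target = np.asarray((graph.adjacency
                         + sp.eye(n, format="csr")).todense())
    target = (target > 0).astype(dtype)
    pos_weight = M.adjacency_pos_weight(target)
    kl_weight = 1.0 / n
    A_hat = graph.normalized_adjacency.astype(dtype)

    pdict = params.as_dict()
    gen_opt = Adam({k: v.shape for k, v in pdict.items()},
                   lr=config.lr_generator)
    if critic is not None:
        cdict = critic.as_dict()
        critic_opt = RMSprop({k: v.shape for k, v in cdict.items()},
                             lr=config.lr_critic)

    initial_mu, _ = M.encode(X, A_hat, params)

    trace = TrainingTrace()
    shape = (n, config.latent_dim)

    def draw():
        return rng.standard_normal(shape, dtype=dtype)

    for epoch in range(config.epochs):
        prior_mean = 0.0
        if critic is not None:
            mu, logvar = M.encode(X, A_hat, params)
            Z_det = M.reparameterize(mu, logvar, draw())
            for _ in range(config.critic_steps):
                r = draw()
                _, cgrads = M.critic_loss_and_grads(critic, r, Z_det)
                critic_opt.step(cdict, cgrads)
                critic.clip_(config.clip_value)
            prior_mean = float(np.mean(M.critic_score(draw(), critic)))

        eps = draw()
        bundle, grads, _, _, _ = M.generator_loss_and_grads(
            params, X, A_hat, target, labels, eps, lam, pos_weight,
            kl_weight, critic=critic, prior_scores_mean=prior_mean,
            use_kl=config.use_kl)
        gen_opt.step(pdict, grads)
        trace.append(epoch, bundle)

    mu, _ = M.encode(X, A_hat, params)
    return TrainedModel(params=params, critic=critic,
                        embedding=mu.astype(np.float64),
                        initial_embedding=initial_mu.astype(np.float64),
                        config=config, trace=trace)
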