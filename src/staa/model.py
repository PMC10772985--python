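"""The adversarial variational graph autoencoder network and its losses.

The network has three parts sharing a latent space:

* a **variational graph encoder** — one graph-convolution hidden layer
  ``X~ = ReLU(A_hat X W_G1)`` followed by two linear graph heads producing the
  posterior mean ``mu = A_hat X~ W_G2`` and log-variance
  ``logvar = A_hat X~ W_G2'``; the embedding ``Z`` is drawn by the
  reparameterization trick ``Z = mu + sigma * eps``;
* an **inner-product decoder** ``A' = sigmoid(Z Z^T)`` whose weighted binary
  cross-entropy against the spatial adjacency (plus the KL divergence to the
  standard-normal prior) forms the negative-ELBO loss L1;
* a **classifier head** (linear + softmax) trained with categorical
  cross-entropy L2 against pre-clustering labels, injecting global
  expression structure;
* a **Wasserstein critic** — an MLP with two logistic hidden layers and a
  linear output whose score difference between prior draws r ~ N(0, I) and
  embeddings estimates the 1-Wasserstein distance; its loss is
  ``L3 = -mean(R(r)) + mean(R(z))``.

The combined generator objective is ``lambda*L1 + (1-lambda)*L2 - L3``,
minimized over encoder+classifier and maximized over the critic.

Everything is plain NumPy with analytic gradients; forward passes cache the
intermediates their backward passes need.  Losses are computed on logits
where that is numerically safer (the decoder BCE, the classifier CE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy import special


# ---------------------------------------------------------------------------
# parameters

@dataclass
class GeneratorParams:
    """Encoder and classifier weights."""

    W_G1: np.ndarray      # input_dim x hidden_dim
    W_G2: np.ndarray      # hidden_dim x latent_dim (mean head)
    W_G2p: np.ndarray     # hidden_dim x latent_dim (log-variance head)
    W_c: np.ndarray       # latent_dim x K
    b_c: np.ndarray       # K

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"W_G1": self.W_G1, "W_G2": self.W_G2, "W_G2p": self.W_G2p,
                "W_c": self.W_c, "b_c": self.b_c}


@dataclass
class CriticParams:
    """Two logistic hidden layers, linear output."""

    W_R1: np.ndarray      # latent_dim x h1
    b_R1: np.ndarray
    W_R2: np.ndarray      # h1 x h2
    b_R2: np.ndarray
    W_R3: np.ndarray      # h2 x 1
    b_R3: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"W_R1": self.W_R1, "b_R1": self.b_R1, "W_R2": self.W_R2,
                "b_R2": self.b_R2, "W_R3": self.W_R3, "b_R3": self.b_R3}

    def clip_(self, clip_value: float) -> None:
        for arr in self.as_dict().values():
            np.clip(arr, -clip_value, clip_value, out=arr)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_generator(input_dim: int, hidden_dim: int, latent_dim: int,
                   n_classes: int, rng: np.random.Generator) -> GeneratorParams:
    return GeneratorParams(
        W_G1=_glorot(rng, input_dim, hidden_dim),
        W_G2=_glorot(rng, hidden_dim, latent_dim),
        W_G2p=_glorot(rng, hidden_dim, latent_dim),
        W_c=_glorot(rng, latent_dim, n_classes),
        b_c=np.zeros(n_classes),
    )


def init_critic(latent_dim: int, hidden: Tuple[int, int],
                rng: np.random.Generator, scale: float = 0.01) -> CriticParams:
    h1, h2 = hidden
    return CriticParams(
        W_R1=rng.normal(0, scale, size=(latent_dim, h1)),
        b_R1=np.zeros(h1),
        W_R2=rng.normal(0, scale, size=(h1, h2)),
        b_R2=np.zeros(h2),
        W_R3=rng.normal(0, scale, size=(h2, 1)),
        b_R3=np.zeros(1),
    )


# ---------------------------------------------------------------------------
# elementwise helpers

def sigmoid(t: np.ndarray) -> np.ndarray:
    """Standard increasing logistic 1 / (1 + e^{-t})."""
    t = np.asarray(t)
    if not np.issubdtype(t.dtype, np.floating):
        t = t.astype(float)
    return special.expit(t)


def softplus(t: np.ndarray) -> np.ndarray:
    return np.maximum(t, 0.0) + np.log1p(np.exp(-np.abs(t)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# forward passes

def encode(X: np.ndarray, A_hat: sp.spmatrix, params: GeneratorParams,
           return_cache: bool = False):
    """Posterior mean and log-variance of the graph encoder.

    ``X~ = ReLU(A_hat X W_G1)``; ``mu = A_hat X~ W_G2``;
    ``logvar = A_hat X~ W_G2'``.
    """
    if X.shape[1] != params.W_G1.shape[0]:
        raise ValueError("feature dimension does not match W_G1")
    AX = A_hat @ X
    pre = AX @ params.W_G1
    H = np.maximum(pre, 0.0)
    AH = A_hat @ H
    mu = AH @ params.W_G2
    logvar = AH @ params.W_G2p
    if return_cache:
        return mu, logvar, {"AX": AX, "pre": pre, "H": H, "AH": AH}
    return mu, logvar


def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                   epsilon: np.ndarray) -> np.ndarray:
    """Z = mu + exp(logvar / 2) * eps."""
    if mu.shape != logvar.shape or mu.shape != epsilon.shape:
        raise ValueError("mu, logvar and epsilon must share a shape")
    return mu + np.exp(0.5 * logvar) * epsilon


def decode(Z: np.ndarray) -> np.ndarray:
    """Edge-probability matrix A' = sigmoid(Z Z^T)."""
    return sigmoid(Z @ Z.T)


def classify(Z: np.ndarray, W_c: np.ndarray, b_c: np.ndarray) -> np.ndarray:
    """Class probabilities, rows summing to one."""
    return softmax(Z @ W_c + b_c)


def critic_score(points: np.ndarray, critic: CriticParams,
                 return_cache: bool = False):
    """Critic scores R(z) = W_R3 . sigma(W_R2 . sigma(W_R1 z))."""
    h1 = sigmoid(points @ critic.W_R1 + critic.b_R1)
    h2 = sigmoid(h1 @ critic.W_R2 + critic.b_R2)
    s = (h2 @ critic.W_R3 + critic.b_R3).ravel()
    if return_cache:
        return s, {"h1": h1, "h2": h2}
    return s


# ---------------------------------------------------------------------------
# losses

def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(q || N(0, I)) = (1/n) * 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    n = mu.shape[0]
    return float(0.5 / n * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar))


def reconstruction_bce(S: np.ndarray, target: np.ndarray,
                       pos_weight: float) -> float:
    """Weighted mean BCE of sigmoid(S) against the binary target.

    Positive entries are weighted by ``pos_weight`` to compensate for
    adjacency sparsity; computed on logits S for stability.
    """
    n2 = target.size
    per = pos_weight * target * softplus(-S) + (1.0 - target) * softplus(S)
    return float(per.sum() / n2)


def loss_vgae(target: np.ndarray, S: np.ndarray, mu: np.ndarray,
              logvar: np.ndarray, pos_weight: float,
              kl_weight: float) -> Tuple[float, float, float]:
    """Negative-ELBO pieces: (recon_bce, kl, L1 = recon + kl_weight * kl)."""
    uniq = np.unique(target)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("reconstruction target must be binary")
    recon = reconstruction_bce(S, target, pos_weight)
    kl = kl_divergence(mu, logvar)
    return recon, kl, recon + kl_weight * kl


def loss_classifier(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean categorical cross-entropy -(1/n) sum log p_{i, y_i}."""
    n, k = probs.shape
    labels = np.asarray(labels, dtype=int)
    if labels.max() >= k:
        raise ValueError("label outside classifier range")
    return float(-np.mean(np.log(np.maximum(probs[np.arange(n), labels],
                                            1e-300))))


def loss_wasserstein(real_scores: np.ndarray,
                     fake_scores: np.ndarray) -> float:
    """L3 = -mean(R(r)) + mean(R(z)) (negated critic estimate of W1)."""
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("score sets must be non-empty")
    return float(-np.mean(real_scores) + np.mean(fake_scores))


def combined_loss(L1: float, L2: float, L3: float,
                  lambda_weight: float) -> float:
    """lambda * L1 + (1 - lambda) * L2 - L3."""
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must lie in [0, 1]")
    return lambda_weight * L1 + (1.0 - lambda_weight) * L2 - L3


def adjacency_pos_weight(target: np.ndarray) -> float:
    n_pos = float(target.sum())
    return (target.size - n_pos) / n_pos


@dataclass
class LossBundle:
    recon_bce: float
    kl: float
    L1: float
    L2: float
    L3: float
    combined: float


# ---------------------------------------------------------------------------
# backward passes

def _critic_input_grad(ds: np.ndarray, cache: Dict[str, np.ndarray],
                       critic: CriticParams) -> np.ndarray:
    """d(sum ds_i * s_i) / d points for the generator path."""
    h1, h2 = cache["h1"], cache["h2"]
    dh2 = ds[:, None] @ critic.W_R3.T
    dpre2 = dh2 * h2 * (1.0 - h2)
    dh1 = dpre2 @ critic.W_R2.T
    dpre1 = dh1 * h1 * (1.0 - h1)
    return dpre1 @ critic.W_R1.T


def critic_param_grads(points: np.ndarray, ds: np.ndarray,
                       critic: CriticParams,
                       cache: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Gradients of sum(ds_i * s_i) w.r.t. critic weights."""
    h1, h2 = cache["h1"], cache["h2"]
    dh2 = ds[:, None] @ critic.W_R3.T
    dpre2 = dh2 * h2 * (1.0 - h2)
    dh1 = dpre2 @ critic.W_R2.T
    dpre1 = dh1 * h1 * (1.0 - h1)
    return {
        "W_R3": h2.T @ ds[:, None],
        "b_R3": np.array([ds.sum()]),
        "W_R2": h1.T @ dpre2,
        "b_R2": dpre2.sum(axis=0),
        "W_R1": points.T @ dpre1,
        "b_R1": dpre1.sum(axis=0),
    }


def critic_loss_and_grads(critic: CriticParams, real: np.ndarray,
                          fake: np.ndarray):
    """Critic objective (to minimize) and its parameter gradients.

    The critic maximizes mean(R(real)) - mean(R(fake)); we return the
    negation so a descent step improves the critic.
    """
    n_r, n_f = real.shape[0], fake.shape[0]
    both = np.concatenate([real, fake], axis=0)
    s, cache = critic_score(both, critic, return_cache=True)
    loss = -(np.mean(s[:n_r]) - np.mean(s[n_r:]))
    ds = np.concatenate([np.full(n_r, -1.0 / n_r, dtype=s.dtype),
                         np.full(n_f, 1.0 / n_f, dtype=s.dtype)])
    grads = critic_param_grads(both, ds, critic, cache)
    return float(loss), grads


def generator_loss_and_grads(
    params: GeneratorParams,
    X: np.ndarray,
    A_hat: sp.spmatrix,
    target: np.ndarray,
    labels: Optional[np.ndarray],
    epsilon: np.ndarray,
    lambda_weight: float,
    pos_weight: float,
    kl_weight: float,
    critic: Optional[CriticParams] = None,
    prior_scores_mean: float = 0.0,
    use_kl: bool = True,
):
    """Generator objective lambda*L1 + (1-lambda)*L2 - mean(R(Z)) and grads.

    ``critic=None`` drops the adversarial term (L3 reported as 0);
    ``labels=None`` drops the classifier term (L2 reported as 0, used with
    lambda=1).  ``prior_scores_mean`` only shifts the *reported* L3 to the
    two-sample form -mean(R(r)) + mean(R(z)); it does not affect gradients.
    Returns (LossBundle, grads dict keyed like GeneratorParams.as_dict).
    """
    n = X.shape[0]
    mu, logvar, cache = encode(X, A_hat, params, return_cache=True)
    sigma = np.exp(0.5 * logvar)
    Z = mu + sigma * epsilon

    # --- reconstruction (positives handled sparsely: target is ~k/n dense) ---
    S = Z @ Z.T
    n2 = target.size
    pos = target > 0
    sig = sigmoid(S)
    sp_all = softplus(S)
    s_pos = S[pos]
    recon = float((sp_all.sum() - sp_all[pos].sum()
                   + pos_weight * softplus(-s_pos).sum()) / n2)
    kl = kl_divergence(mu, logvar) if use_kl else 0.0
    L1 = recon + kl_weight * kl

    scale = lambda_weight / n2
    dS = sig * scale
    dS[pos] = -pos_weight * (1.0 - sig[pos]) * scale
    dZ = (dS + dS.T) @ Z

    # --- classifier ---
    if labels is not None:
        logits = Z @ params.W_c + params.b_c
        probs = softmax(logits)
        L2 = loss_classifier(labels, probs)
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), labels] = 1.0
        dlogits = (probs - onehot) / n * (1.0 - lambda_weight)
        dZ += dlogits @ params.W_c.T
        dW_c = Z.T @ dlogits
        db_c = dlogits.sum(axis=0)
    else:
        L2 = 0.0
        dW_c = np.zeros_like(params.W_c)
        db_c = np.zeros_like(params.b_c)

    # --- adversarial term: minimize -mean(R(Z)) ---
    if critic is not None:
        s_f, ccache = critic_score(Z, critic, return_cache=True)
        L3 = float(-prior_scores_mean + np.mean(s_f))
        ds = np.full(s_f.shape, -1.0 / n)
        dZ += _critic_input_grad(ds, ccache, critic)
        adv = -float(np.mean(s_f))
    else:
        L3 = 0.0
        adv = 0.0

    # --- back through the reparameterization ---
    dmu = dZ.copy()
    dlogvar = dZ * epsilon * 0.5 * sigma
    if use_kl:
        w = lambda_weight * kl_weight
        dmu += w * mu / n
        dlogvar += w * 0.5 * (np.exp(logvar) - 1.0) / n

    # --- back through the encoder ---
    AH = cache["AH"]
    dAH = dmu @ params.W_G2.T + dlogvar @ params.W_G2p.T
    dW_G2 = AH.T @ dmu
    dW_G2p = AH.T @ dlogvar
    dH = A_hat.T @ dAH
    dpre = dH * (cache["pre"] > 0)
    dW_G1 = cache["AX"].T @ dpre

    objective = lambda_weight * L1 + (1.0 - lambda_weight) * L2 + adv
    bundle = LossBundle(recon_bce=recon, kl=kl, L1=L1, L2=L2, L3=L3,
                        combined=combined_loss(L1, L2, L3, lambda_weight))
    grads = {"W_G1": dW_G1, "W_G2": dW_G2, "W_G2p": dW_G2p,
             "W_c": dW_c, "b_c": db_c}
    return bundle, grads, objective, mu, Z


def generator_objective(params: GeneratorParams, X, A_hat, target, labels,
                        epsilon, lambda_weight, pos_weight, kl_weight,
                        critic=None, use_kl=True) -> float:
    """Scalar generator objective (for finite-difference verification)."""
    _, _, objective, _, _ = generator_loss_and_grads(
        params, X, A_hat, target, labels, epsilon, lambda_weight,
        pos_weight, kl_weight, critic=critic, use_kl=use_kl)
    return objective


def critic_objective(critic: CriticParams, real: np.ndarray,
                     fake: np.ndarray) -> float:
    loss, _ = critic_loss_and_grads(critic, real, fake)
    return loss
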