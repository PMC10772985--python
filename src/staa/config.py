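"""Run configuration for the full pipeline.

Defaults follow the conventions of the graph-autoencoder spatial-clustering
method family: k=6 spatial neighbors (hexagonal Visium neighborhoods),
3000 highly variable genes, a single 128-unit hidden graph layer with a
32-dimensional latent space, equal weighting (lambda=0.5) of reconstruction
and classifier losses, and the original WGAN recipe for the critic
(RMSprop at 5e-5, 5 critic steps per generator step, weight clipping at
0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict


@dataclass
class RunConfig:
    k_neighbors: int = 6
    n_hvg: int = 3000
    n_clusters: int = 7
    lambda_weight: float = 0.5
    hidden_dim: int = 128
    latent_dim: int = 32
    epochs: int = 500
    critic_steps: int = 5
    critic_hidden: tuple = (64, 16)
    lr_generator: float = 1e-3
    lr_critic: float = 5e-5
    clip_value: float = 0.01
    seed: int = 0
    pre_cluster_method: str = "gmm"
    final_cluster_method: str = "gmm"
    scale_features: bool = True
    encoder_input: str = "pca"   # pca | hvg
    n_pca: int = 30
    use_kl: bool = True
    use_wgan: bool = True
    use_classifier: bool = True

    def __post_init__(self) -> None:
        for name in ("k_neighbors", "n_hvg", "n_clusters", "hidden_dim",
                     "latent_dim", "epochs", "critic_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        for name in ("lr_generator", "lr_critic", "clip_value"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pre_cluster_method", "final_cluster_method"):
            if getattr(self, name) not in ("gmm", "louvain"):
                raise ValueError(f"{name} must be 'gmm' or 'louvain'")
        if self.encoder_input not in ("pca", "hvg"):
            raise ValueError("encoder_input must be 'pca' or 'hvg'")
        if self.n_pca < 1:
            raise ValueError("n_pca must be >= 1")

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["critic_hidden"] = list(self.critic_hidden)
        return d


def ablate(config: RunConfig, no_wgan: bool = False,
           no_classifier: bool = False) -> RunConfig:
    """Return a config with the WGAN critic and/or classifier head removed.

    ``no_wgan`` drops the critic updates and the -L3 term from the combined
    objective; ``no_classifier`` silences the classifier loss by setting the
    mixing weight lambda to 1.  Both together reduce training to a plain
    variational graph autoencoder.
    """
    d = config.to_dict()
    d["critic_hidden"] = tuple(d["critic_hidden"])
    if no_wgan:
        d["use_wgan"] = False
    if no_classifier:
        d["use_classifier"] = False
        d["lambda_weight"] = 1.0
    return RunConfig(**d)
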