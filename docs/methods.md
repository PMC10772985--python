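# Methods

## Model

`staa` identifies spatial domains by learning a per-spot latent embedding
that reconciles three sources of information: local spatial context (via a
graph built from spot coordinates), global expression structure (via a
classifier supervised by an expression-only pre-clustering), and a
standard-normal prior on the latent space (via a Wasserstein critic).

### Spatial graph

Spots are connected to their k nearest Euclidean neighbors (default k = 6,
the hexagonal neighborhood of Visium arrays) and the directed relation is
symmetrized by union, so every spot keeps at least k neighbors. Distance
ties are broken by lower spot index, which makes the graph deterministic
even on degenerate (duplicated) coordinates. All encoder layers use the
renormalized operator `Â = D^{-1/2}(A + I)D^{-1/2}` with self-loops; the
raw adjacency is numerically unstable as a convolution operator because its
spectral radius grows with degree. k-NN graphs are invariant to translation,
rotation and uniform scaling of the coordinates, so platform units never
need conversion.

### Encoder, decoder, losses

The encoder is a single graph-convolution hidden layer (ReLU) followed by
linear graph heads for the posterior mean and log-variance. One hidden
layer is the default because deeper stacks oversmooth: each extra layer
widens the receptive field by one hop, and beyond two hops neighboring
domains start to blend (depth is configurable to 2–3).

The decoder is the inner product `sigmoid(Z Zᵀ)`, i.e. edge probability
grows with latent similarity. Its loss is a positive-reweighted binary
cross-entropy over all spot pairs: with ~k·n edges among n² pairs the
positive class is rare, and without the reweighting
`pos_weight = (n² − |E|)/|E|` the all-zero predictor is a near-optimum.
The KL term uses the standard diagonal-Gaussian closed form and is scaled
by `1/n` (on top of the per-spot average), the conventional VGAE weighting;
it can be disabled entirely (`use_kl=False`), since the Wasserstein critic
already enforces the prior — on the synthetic benchmark the two settings
are indistinguishable, so the term stays on by default.

The classifier is a single linear layer + softmax trained with categorical
cross-entropy against pre-clustering labels. The classifier loss is
categorical (not binary) because spatial datasets have 4–20 domains.

The critic is an MLP with two logistic hidden layers (64, 16) and a linear
output. It is trained with the original WGAN recipe: RMSprop at 5e-5,
5 critic steps per generator step, all critic weights clipped to
[−0.01, 0.01] after every update, fresh prior draws each step. The
generator (encoder + classifier, Adam at 1e-3) minimizes
`λ·L1 + (1 − λ)·L2 − mean(R(Z))` with the critic frozen; λ defaults
to 0.5. Training runs full-graph for 500 epochs; the dense n×n
reconstruction makes this practical up to roughly 5 000 spots on one core,
which covers bench-scale work (larger sections should be subsampled).

The clustering embedding is the posterior mean μ, not a sample Z, so the
downstream step is deterministic given the trained weights.

All forward and backward passes are hand-derived NumPy; there is no
autodiff dependency. Every gradient is checked against central finite
differences (relative tolerance 1e-4) in the test suite, and the losses on
logits use softplus/expit forms that are stable for |logit| ≫ 1.

### Pre-clustering and final clustering

Initial labels come from expression alone: PCA to 50 components, then
either a Gaussian mixture fitted by EM (10 seeded restarts) or Louvain
modularity on a 15-NN expression graph with the resolution bisected to
reach the requested cluster count. The mixture's covariance structure
(spherical / diagonal / tied / full) is selected by BIC, mirroring how
model-based clustering tools choose among covariance parameterizations;
on noisy, high-dimensional reductions an unconstrained full covariance is
ill-conditioned and BIC reliably prefers the constrained forms. The final
clustering applies the same machinery to the latent embedding (used
directly when its width is ≤ 64, PCA-reduced otherwise). Labels are
renumbered 0..K−1 by decreasing cluster size for stable output.

### Encoder input features

Counts are library-size normalized to 10 000 per spot, log1p-transformed,
reduced to the 3 000 most dispersed genes (variance/mean, ties by gene
index), and z-scaled per gene with clipping at ±10. By default the encoder
receives the top 30 standardized principal components of this matrix
rather than the genes themselves (`encoder_input="pca"`; set `"hvg"` for
the direct route). Feeding PCs is the convention of several graph-based
spatial methods, and it matters for robustness: per-gene noise in
overdispersed, sparse counts otherwise propagates straight into the first
graph layer, and on the synthetic benchmark the direct route occasionally
produces poorly separated embeddings on unlucky seeds while the PCA route
does not. Thirty components is the field's customary choice for this
family of methods.

## Synthetic tissue generator

The generator emulates a sectioned tissue with known domain structure:
spots on a jittered √n×√n grid; domains assigned as horizontal strips
(cortical-layer-like; default), concentric rings, or Voronoi patches, so
truth labels are spatially contiguous; counts drawn from a negative
binomial with variance `m + φ·m²` (dispersion φ = 0.5 by default);
each domain's marker genes (10 per domain) elevated by `exp(lfc)` with
lfc = ln 4; independent Bernoulli dropout (rate 0.2) zeroing entries.
Baseline mean 2 with these settings gives sparsity and signal strength in
the range of spot-level platforms. The canonical fixture
(`standard_tissue()`) is 600 spots × 200 genes, 4 strip domains, seed 7.

What the generator does **not** emulate: within-domain expression
gradients, spatially correlated technical noise, platform-specific spot
geometries, histology, doublets, or batch effects. Tests passing on this
fixture therefore demonstrate that the optimization and clustering
machinery recovers contiguous domains from overdispersed, sparse counts —
not that the method matches its reported accuracy on any real tissue.

## Numerical and design notes

- The decoder's sigmoid is the standard increasing logistic
  `1/(1+e^{-t})`, as an edge-probability decoder requires (the decreasing
  variant `1/(1+e^t)` sometimes seen in writeups of this architecture
  would invert the similarity-probability relationship).
- The ELBO is implemented in minimization form (BCE + KL), so the combined
  objective is coherently a minimum over the generator and a maximum over
  the critic.
- All randomness flows from the single `RunConfig.seed` through a
  `SeedSequence`; identical config + seed reproduces labels and embeddings
  bitwise. Training runs in float32 (weights, features, noise draws);
  reported embeddings are float64.
- Degenerate inputs: all-zero spots survive normalization as zero rows
  (warning); constant genes z-scale to zero; duplicate coordinates are
  allowed with deterministic tie-breaks; coincident cluster centroids make
  the Davies–Bouldin index +inf (warning) rather than an exception.
- Divergent training (non-finite loss) aborts immediately with the
  offending epoch's loss record.

## Evaluation

ARI is the chance-corrected pair-counting agreement with truth labels
(spots with truth −1 are excluded from ARI only). SC and DB are computed
in the same embedding space that is clustered, with Euclidean distances.
ARI and silhouette delegate to scikit-learn; Davies–Bouldin is computed
in-package so the all-singleton and coincident-centroid boundary cases
behave as documented. Independent brute-force implementations of all three
serve as oracles in the tests.

## Limitations

- Full-graph dense reconstruction is O(n²) memory/time; no mini-batching.
- The classifier can overfit noisy pre-clustering labels on long
  schedules; the 500-epoch default balances this against convergence of
  the reconstruction term.
- Weight clipping (not gradient penalty) is the default Lipschitz
  mechanism; a gradient-penalty critic is a straightforward extension but
  is not implemented.
- Histology images, batch correction and trajectory analysis are out of
  scope.
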