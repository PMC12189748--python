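# Methods

## The model

`gexgan` synthesizes gene expression profiles with a conditional Wasserstein
GAN whose generator performs message passing over a prior gene graph. Given a
latent draw z ~ N(0, I_d) and categorical covariates c (tissue, condition,
sex, ...) mapped to learned embeddings, a dense layer assigns an initial
scalar h0_i = sigma(W_I [z, c] + b_I)_i to every gene node i. L rounds of
message passing over the prior graph then refine these node features, and the
final per-gene values are the synthetic expression vector. The critic is an
MLP (two hidden layers of 256, leaky ReLU slope 0.2) scoring real and
generated samples, optionally concatenated with the covariate embedding.

Two message-passing families are implemented:

* **GraphConv** (1-hop): h_i' = sigma(h_i W1 + sum_{j in N(i)} A_{j,i} h_j W2),
  where A_{j,i} is the edge weight from j to i. Suited to homophilous graphs
  (co-expression networks, where connected genes have similar profiles).
* **Heterophily-aware (H2GCN-style)**: separate degree-normalized 1-hop and
  2-hop aggregates, concatenated per layer without mixing in the ego
  embedding, with a readout that concatenates all intermediate
  representations (h0 through hL) and projects them to one value per gene.
  Suited to regulatory networks, where a repressor and its target are
  *dissimilar* by construction.

Training minimizes the WGAN-GP objective: the critic takes
mean D(fake) − mean D(real) + lambda E[(||grad_xhat D(xhat)||_2 − 1)^2] with
xhat drawn per sample on the real–fake segment; the generator takes
−mean D(fake), one step per `n_critic` critic steps.

## Prior graphs

* **Co-expression**: undirected; edge (i, j) present iff
  |pearson(g_i, g_j)| >= threshold (defaults 0.8/0.9), weighted by the signed
  correlation (binarization optional). Correlation is computed on the matrix
  as given; build the graph in the same normalized space the generator trains
  in. Tissue-specific graphs can be built per label group (groups with < 3
  samples are skipped) and merged by keeping, per gene pair, the weight of
  maximum absolute value — the merge feeds one prior to one generator, while
  the per-tissue map is retained for analysis.
* **Regulatory**: directed and signed, +1 activation / −1 repression, loaded
  from an edge list and restricted to the expression matrix's gene universe.
  Regulation is not mirrored. Contradictory duplicate edges keep the last
  occurrence with a warning. Message passing uses in-neighborhoods: A_{i,j}
  means i regulates j, so information flows source → target.

## Numerical choices

* **H2GCN degree normalization.** The update is implemented as
  A_{j,i} / sqrt(|N(i)| |N(j)|) per hop (each hop normalized by its own
  neighborhood sizes), with a `product_degree` variant (divide by
  |N(i)| |N(j)|) available. 2-hop neighborhoods use exact distance 2
  (excluding self and 1-hop overlap) with indicator weights, since the prior
  assigns no weight to non-adjacent pairs.
* **Autodiff.** The networks run on a small numpy reverse-mode engine
  (`gexgan.autodiff`) whose vector–Jacobian products are themselves tracked
  operations, so the second-order gradients required by the gradient-penalty
  term come from calling `grad` twice. First- and second-order gradients are
  finite-difference-verified in the test suite.
* **Normalization conventions.** min–max maps each gene to [0, 1] using
  training-split extremes; constant genes map to 0 (not NaN) to keep values
  in range. log2 + standard scaling uses the population sd (divide by n);
  this convention is fixed so the invert/apply round trip is exact to 1e-6.
  Out-of-range values from held-out or generated samples are not clipped by
  default (`clip=True` is available for generation post-processing). The
  generator's output activation is sigmoid for min–max data and identity for
  z-scored data, matching the data codomain.
* **Greedy-sample filter.** "Dominated" samples are defined by the
  top-k-fraction rule: remove a sample when its top_k = 10 highest-expressed
  genes carry more than max_fraction = 0.5 of its total expression. Both
  knobs are exposed; the rule is this package's concrete instantiation of an
  informally described preprocessing step.
* **Embedding dimension rule.** The default maps a vocabulary of size l to
  floor(l + 1) dimensions, kept for fidelity to the reference setup even
  though it makes embeddings larger than their vocabularies; a compact
  floor(sqrt(l)) + 1 rule is provided (`rule="sqrt_plus_one"`). Embedding
  tables are shared between generator and critic and updated through the
  generator objective.
* **Degenerate batches.** A trailing batch of size 1 is dropped (batch
  statistics degenerate); the interpolation coefficient for the gradient
  penalty is drawn once per sample, not per feature.

## Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| epochs / batch | 500 / 32 | reference training budget |
| Adam lr, beta1, beta2 | 1e-4, 0.5, 0.9 | reference optimizer setting |
| n_critic | 5 | critic steps per generator step (standard WGAN-GP) |
| gp lambda | 10 | gradient-penalty strength (standard WGAN-GP) |
| latent dim d | 64 | matches the CVAE latent size, the only printed latent size |
| message-passing layers L | 4 | reference depth |
| node feature width p | 8 | hidden width between layers (not externally specified) |
| leaky slope | 0.2 | used in h0, GraphConv, and the critic |

**Desk-scale training runs** (the examples, the acceptance script, and the
scaled-down comparison test) use lr 1e-3 with 200 epochs on the 50-gene/500-
sample fixture. At that problem size a 200-epoch run contains only ~400
generator updates; with Adam's normalized steps the reference lr of 1e-4
moves weights by ~0.04 in total, so no generator — graph-informed or not —
leaves its initialization. Scaling the learning rate with the step budget is
the package's choice for these runs; the library default remains 1e-4.

Baselines: fully connected GAN and WGAN-GP generators (two hidden layers of
256, leaky ReLU) and a CVAE (one hidden layer of 256, latent 64, ELBO = MSE
reconstruction + closed-form Gaussian KL). The plain GAN uses the saturating
log(1 − D(G(z))) generator loss in stable softplus form; its mode collapse on
multimodal data is expected behavior, and the evaluation stack flags it as
the high-precision/zero-recall signature.

## Evaluation stack

* **Manifold precision/recall** (t = 10): each set's support is a union of
  spheres with radii equal to the distance to the t-th nearest neighbor
  within the same set; precision is the fraction of synthetic points inside
  the real support, recall the converse. Mode collapse shows as precision
  ≈ 1 with recall ≈ 0.
* **Correlation coefficient** c(X, Xhat): Pearson correlation between the
  upper-triangle entries of the two gene–gene correlation matrices,
  normalized so c(X, X) = 1 (population-sd convention over pairs). For a
  single gene pair, centering is degenerate and the normalized raw product is
  used (+1 identical structure, −1 anti-structure). Genes constant in either
  matrix are dropped pairwise with a warning.
* **Detectability**: F1 of logistic regression (L2, C=1), random forest (100
  trees), and an early-stopped 100-unit MLP trained to separate real (label
  1) from synthetic (label 0) on stratified 70/30 splits, averaged over 10
  seeded runs; rows are canonically ordered first so the metric is invariant
  to input shuffling. The PC variant fits the first min(100, n−1, genes)
  principal components on the real training rows only — synthetic structure
  never leaks into the projection.
* **TSTR**: classifiers fitted on synthetic data only, scored on held-out
  real data with balanced accuracy and macro-F1 ("balanced F1" is read as
  equal class weighting).
* **Per-gene statistics**: two-sample Kolmogorov–Smirnov per gene with
  Benjamini–Hochberg adjustment, and the mean per-gene one-dimensional
  2-Wasserstein distance on the merged quantile grid (the WD2 curve metric;
  the per-gene 1-D average is this package's instantiation).

Metrics operate in the normalized training space by default; inverse
transformation to raw space is available through the normalizer.

## Synthetic data

The simulator draws a signed directed acyclic regulatory graph (regulator
genes upstream) and samples expression from a linear-Gaussian structural
equation model in topological order:

    x_j = mu[class(sample), j] + sum_{i in parents(j)} w_ij x_i + eps_j

* Class-conditional mean shifts (scale `effect_size`, default 0.5) model
  tissue/condition structure; covariates are categorical with configurable,
  imbalanced proportions including an explicit MISSING class — matching the
  covariate design the conditional generator is built for. Class means are
  structural (fixed by the spec seed); covariate draws and residual noise
  come from a separate replicate seed, so independent replicates share the
  same population.
* Exogenous (parentless) genes receive intrinsic noise sd 1.0 (`driver_sd`)
  while regulated genes receive `noise_sd` (default 0.3). This separation is
  deliberate: if every gene had the same residual sd s, a weight-w edge's
  pair correlation would be bounded by w/sqrt(1+w^2) (≈ 0.62 at w = 0.8)
  *independently of s*, and no strongly weighted edge could ever clear a 0.8
  correlation threshold. With unit-variance drivers, a w = 0.8 edge yields
  pair correlation ≈ 0.84 at noise 0.3.
* Regulator in-degree is capped at 1 by default (`max_in_degree`; `None`
  restores independent Bernoulli edges). With summed multi-parent inputs the
  target's variance grows with each extra parent and dilutes every incident
  edge's correlation below the threshold regardless of noise level; the cap
  keeps each regulated gene dominated by a single upstream driver, which is
  what makes planted strong edges recoverable by thresholding (the module's
  contract). Edge signs are −1 with probability `repression_prob` (default
  0.25) and magnitudes uniform in `edge_weight_range` (default 0.6–0.95).
* Profiles: `tiny` (20 genes × 64 samples, 2 balanced classes), `small`
  (50 × 500, 3 classes with 10% MISSING), `medium` (200 × 1000, 5 classes).
  Splits are deterministic 70/30 under the profile seed.

What the simulator does **not** emulate: count-level sequencing noise,
library-size and probe effects, batch structure, nonlinear regulation (a
per-gene link-function hook exists but defaults to identity), and feedback
loops. Tests passing on this simulator therefore demonstrate that the
architecture, losses, and metrics behave as designed on data with planted
linear dependencies and class structure — not that the model matches any
particular real platform's noise characteristics.

## Known limitations

* With a one-dimensional input the gradient penalty's unit-norm constraint
  makes the two critic orientations (slope ±1) disconnected; the penalty
  warm-up can lock the critic into the anti-separating one and the pair
  fails to converge. This is a property of WGAN-GP at trivial input
  dimension, not of this implementation (gradients are finite-difference
  verified); convergence checks use ≥ 8 genes.
* The pure-numpy networks are single-threaded and sized for desk-scale
  experiments (hundreds of genes); the dense adjacency fast path is used up
  to 2000 genes, sparse operators beyond.
* Evaluation defaults (classifier settings, 10 evaluation runs, PC count
  100) are configurable; the defaults are the documented reading of the
  reference protocol, not a tuned setting.
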