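# Methods

`bmvae` infers clonal substructure from an N-cell × M-locus ternary mutation
matrix X with entries in {0, 1, missing}. Internally missing entries are the
sentinel `-1`; on disk they default to the code `3`. The pipeline has three
stages — latent embedding, cluster-number selection, and genotype/error-rate
inference — followed by optional evaluation against simulated ground truth.

## 1. Variational autoencoder embedding

The observed matrix is modelled entry-wise as Bernoulli given a low-dimensional
latent code per cell. The encoder maps a cell's M-vector through two hidden
layers of sizes ⌊M/5⌋ and ⌊M/10⌋ (LeakyReLU, slope 0.01) to the mean and
log-variance of a diagonal-Gaussian posterior over a `latent_dim = 3` code; the
decoder mirrors the encoder and ends in a sigmoid. Training minimizes

    L = Σ_observed BCE(x̂_ij, x_ij) + λ · KL( q(z|x) ‖ N(0, I) ),   λ = 1e-4,

where the Bernoulli cross-entropy sums only over observed entries (missing
entries are fed to the network as 0 but masked out of the loss and its
gradient), and the KL term is the closed form for diagonal Gaussians. Sampling
uses the standard reparameterization z = μ + σ ⊙ ε.

The implementation is plain NumPy with hand-written backpropagation and an
RMSprop optimizer (decay 0.99, eps 1e-8). Defaults: learning rate 1e-4,
batch size 64, 300 epochs, float32 arithmetic, probabilities clamped to
[1e-7, 1 − 1e-7] inside the loss. Weights are initialized uniformly in
±1/√fan_in. `BinaryMutationVAE` exposes `fit` / `transform` (the transform
returns the posterior means μ, which are the coordinates used downstream) and
records `loss_history_` / `kl_loss_history_`.

## 2. Cluster-number selection

Cells are clustered in the 3-D latent space with full-covariance Gaussian
mixtures (EM, 5 initializations per k, k-means init, covariance regularizer
1e-6). The scan fits k = 1, 2, 3, … and tracks BIC = −2 log L + p ln N; it
stops when the incumbent minimum has not improved for `patience = 10`
consecutive k (ties keep the smaller k) or when k reaches
`max_clusters = min(N − 1, 100)`. Empty components of the winning model are
dropped and labels compacted. `GaussianMixtureBIC` exposes `labels_`,
`n_clusters_`, `selected_k_` and the full `bic_trace_`.

## 3. Genotype and error-rate inference

Given cluster labels, clone genotypes E ∈ {0,1}^{K×M} and global error rates
α (false positive) and β (false negative) are inferred by alternating:

- **Gibbs step.** For each clone k and locus j, with n1/n0 the counts of
  observed 1s/0s among the clone's cells at that locus, the conditional
  posterior under a uniform prior is

      p(E_kj = 1 | X, α, β) = logistic( n1·log((1−β)/α) + n0·log(β/(1−α)) ),

  and E_kj is resampled from it (missing entries contribute to neither count).

- **Rate update.** α and β are set to their closed-form maximizers given the
  current E: α = (# observed 1s where E says 0) / (# observed entries where E
  says 0), and symmetrically for β; both are clamped to [1e-6, 1 − 1e-6], with
  a fallback to the initial value if a denominator is empty.

Initialization α = β = 0.01; convergence is declared when both rates move by
less than 1e-4 for 5 consecutive iterations (cap 200). The final point
estimate is Ê_kj = 1 iff the last conditional posterior exceeds 0.5 (an exact
0.5 — which only occurs for clone-locus pairs with no observed data — maps
to 0). `GibbsGenotyper.fit(X, labels)` sets `genotypes_`, `alpha_`, `beta_`,
`posterior_`, `n_iter_`, `converged_`.

## 4. Simulator

`simulate_dataset` draws a random clonal tree over K nodes (each non-root node
attaches to a uniformly chosen earlier node), assigns each of the M mutations
to a uniformly chosen node (each node receives at least one), and defines a
clone's genotype as the union of mutations on its root path. Cells receive
clones via Dirichlet(1) proportions with a minimum clone fraction of 0.01.
A fraction `doublet_rate = 0.10` of cells are doublets: their genotype is the
element-wise OR of their host clone and a second, uniformly chosen different
clone. Observation noise flips 1→0 with probability β and 0→1 with probability
α, then a fraction `missing_rate = 0.02` of entries is masked. Defaults:
N = M = 1000, K = 20, α = 0.01, β = 0.3.

Presets `D1`–`D6` vary one factor at a time: D1 β ∈ {0.3, 0.4, 0.5, 0.6};
D2 α; D3 M ∈ {500, 1000, 2000} at N = 1000; D4 K ∈ {20, 30, 40, 50} at
N = M = 2000; D5 N; D6 M ∈ {20, 30, 40, 50, 60} at N = 500, K = 5.

**Scope.** The generator captures tree-structured clonal genotypes,
asymmetric binary noise, missingness, and OR-merged doublets. It does not
emulate read-depth or allele-count data, copy-number events, mutation loss
(infinite-sites violations), site-specific error rates, or cell lineages
within a clone. Clone sizes follow a symmetric Dirichlet, which at small K
often produces highly skewed clone sizes.

## 5. Evaluation and benchmark protocol

- **ARI** between inferred and true cell labels (permutation-invariant).
- **Genotyping accuracy**: clone genotypes are expanded to an N×M cell-level
  matrix via the inferred labels and compared entry-wise with the true
  cell-level genotypes.

The benchmark driver (`bmvae.benchmark`) simulates several replicates per
setting, runs the pipeline several times per sample with different seeds, and
keeps the best value of each metric per replicate (mirroring the common
practice of reporting best-of-five runs for stochastic methods).

**Doublets are excluded from scoring** (while still being generated and fed to
inference). Rationale: a doublet is the merged profile of two clones and has
no single well-defined true label. Empirically, if doublets are scored under
their host-clone label, even the Bayes-optimal classifier — given the true
genotypes and error rates — caps near ARI 0.90 on the default setting, so
labeled-doublet scoring cannot distinguish good from perfect methods; the
non-doublet Bayes optimum is ≈ 1.0. `evaluate_run` supports both modes
(`exclude_doublets`).

## 6. Determinism and seeds

A single pipeline seed is split into independent per-stage seeds with
`numpy.random.SeedSequence.spawn`, so stages cannot collide and runs are fully
reproducible: the same input and seed produce identical outputs
(`summary.yaml` excepted for timing fields, which are not written). Benchmark
replicate seeds derive from (seed, level, preset name) deterministically.

## 7. Known limitations

- **Small locus counts.** With M ≤ 60 the 3-D latent space underseparates
  clones: even a supervised Gaussian classifier in the latent space reaches
  only ARI ≈ 0.73–0.81 on 5-clone, 500-cell data where a Bayes classifier on
  the raw matrix is near-perfect. Longer training does not close this gap; it
  is a property of the fixed architecture at small M. Skewed Dirichlet clone
  sizes (clones of only a few cells) compound it. Expect degraded clustering
  below roughly M = 100.
- Error rates are global; per-site error rates are not modelled.
- Genotype inference conditions on hard cluster labels; label errors propagate
  into clone genotypes (though accuracy degrades gracefully because mis-placed
  cells usually land in genotypically similar clones).
- The VAE is single-threaded NumPy; a 2000×2000 matrix trains in roughly
  2–3.5 minutes depending on epoch count.
- For large many-clone problems `GaussianMixtureBIC` exposes two runtime
  controls: `min_clusters` (restrict the scan window when small k is
  known to be grossly underparameterized) and `em_max_iter` (cap EM
  iterations per fit). Defaults leave both unrestricted (k from 1,
  100 iterations).
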