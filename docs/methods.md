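# Methods

## The problem

Melting temperature (Tm, °C) is a high-throughput proxy for absolute
protein stability. Large cross-species Tm datasets have made supervised
prediction from frozen protein-language-model embeddings popular, with
pooled Spearman correlations above 0.7 routinely reported. Cross-species
Tm data is, however, *hierarchical*: species mean Tm values spread far more
widely (thermophiles vs. mesophiles) than proteins spread within one
species. A model that only ranks species therefore scores highly on any
pooled metric while being useless for the questions practitioners actually
ask (which variant of *this* protein, in *this* organism, is more stable?).
This package implements the full analysis pipeline around that observation:
a synthetic generator with controllable two-level structure, the prediction
architectures and objectives, pooled/per-species training regimes, and
stratified evaluation.

## Synthetic data model

For species `s = 1..S` and protein `i` in `s`:

    mu_s   ~ Normal(mu0, sigma_between^2)          species mean Tm
    delta_i ~ Normal(0, sigma_within^2)            protein offset
    Tm_i   = mu_s + delta_i

Every residue row of protein `i`'s embedding (length `L_i` uniform on
`length_range`) is

    x = a_s * signature_s + kappa * delta_i * w + eps,
    a_s = (mu_s - mu0) / sigma_between,   eps ~ Normal(0, noise_sd^2) i.i.d.

The species signatures are drawn as orthonormal random directions (QR of a
Gaussian matrix) and the within-species direction `w` is orthogonalized
against all of them, which requires `embedding_dim > n_species`. Encoding
the species mean *linearly* (through `a_s`) matches the frozen-embedding +
shallow-head regime the pipeline studies: a linear probe of the pooled
embedding can recover the between-species trend. `kappa` dials the
within-species signal: at `kappa = 0` the embeddings are pure noise with
respect to `delta_i` (the Simpson's-paradox regime); at
`kappa >= 5 * noise_sd / sigma_within` an ordinary least-squares probe of
mean-pooled embeddings already attains within-species r > 0.5, since the
per-coordinate signal-to-noise after pooling is
`kappa * sigma_within / (noise_sd / sqrt(L))`.

Defaults (°C where applicable): 25 species with per-species counts taken
from the train-partition sizes of the public cross-species meltome
benchmark clipped to [50, 3000], `mu0 = 50`, `sigma_between = 12`,
`sigma_within = 5`, `noise_sd = 1`, `kappa = 0.3`, `embedding_dim = 32`
(a stand-in for 1280-dimensional language-model embeddings), lengths
50–120, splits (0.8, 0.1, 0.1) stratified within species so every species
appears in every split. The two mean-predictor closed forms under this
model are `sigma_within` (per-species scope) and
`sqrt(sigma_between^2 + sigma_within^2)` (global scope), i.e. 5 and 13 °C —
deliberately reproducing the magnitude gap between the global and
per-species mean-predictor references seen in real meltome data.

What the generator does *not* emulate: positional structure within the
embedding (each protein is one underlying row plus i.i.d. residue noise),
sequence- or structure-derived correlations between proteins, species- or
assay-specific measurement error, and heavy-tailed or skewed Tm
distributions. Passing tests therefore demonstrate correctness of the
pipeline and the qualitative two-level phenomena, not performance on real
embeddings.

## Architecture

Light attention: two depthwise 1-D convolutions (kernel 9, same padding,
separate filters for attention logits A and values V) over the length axis;
per feature, softmax(A) over positions weights V, and the weighted sum is
concatenated with a per-feature max over V, giving a fixed-size `2d`
vector. Variable-length batches use a boolean mask; masked positions are
zeroed before convolution and receive zero softmax weight, so padding is
provably inert (tested). Dropout 0.25 is applied to the pooled vector
during training only. The head is an MLP with ReLU hidden layers
(128, 64) and a linear output of size `n` (1 for plain regression, 2 for
the dual head). Mean pooling is available as an alternative
(`pooling="mean"`).

The dual head's outputs are a species-level estimate `y_ogt` and a
per-protein offset `y_bias`, with `phi_tm = y_ogt + y_bias`. The loss adds
`MSE(y_ogt, mu_tm)` to the prediction term, where `mu_tm` is the species'
mean Tm **on the training split only** (leakage hygiene; the anchor is a
proxy for the species' optimal growth temperature).

Rank-N-Contrast: the encoder is a residue-wise MLP (64 hidden, 32 out)
shared across positions; the contrastive similarity is the negative
Euclidean distance between masked length-means of encoder outputs, with
temperature `tau = 2` (the published defaults of the procedure this
follows). Two-view batches pair each protein with a Gaussian-perturbed
copy of its embedding (default sigma: 0.1 x the per-feature training SD;
the perturbed view keeps its source's label). Ties in the rank set are
included (the `>=` in its definition taken literally). After contrastive
training the encoder is frozen and the standard pooling + MLP predictor is
trained on its outputs.

Because no automatic-differentiation stack is part of the package's
dependency set, the layer stack ships with hand-written reverse-mode
gradients (`tmelt.nn`), all verified against central finite differences in
the test suite; the Rank-N-Contrast gradient is verified the same way and
the loss itself against a brute-force triple loop.

## Training protocol

AdamW (betas 0.9/0.999, decoupled weight decay 0.01, biases exempt) with
the regime-dependent learning rates: global and species-balanced models
1e-4, species-specific models 1e-3; contrastive encoder 1e-5 with
predictor 1e-4 (global) or 1e-3 (species-specific). Targets are z-scored
on the training split of the model being fit and predictions mapped back
to °C; this keeps the stated learning rates meaningful across the very
different target scales of pooled (SD ≈ 13 °C) and per-species (SD ≈ 5 °C)
training, and is inverted exactly at prediction time. Batch size 64
(capped at the species size for per-species models), early stopping on
validation RMSE with patience 20 and a 500-epoch cap by default; runs in
the examples, tests and acceptance script use smaller caps (80–200 epochs)
matched to their dataset sizes. A validation split smaller than 5 samples
falls back to train-loss early stopping with a warning; a species with no
validation data at all is skipped (with a warning) in the per-species
regime. The species-balanced regime (GB) resamples the training set each
epoch with inverse-frequency weights, one plausible reading of "balanced
by species during training"; loss reweighting would be the alternative.

## Evaluation

Metrics are reported pooled and per species: Spearman rho (pooled, and the
*unweighted* mean of per-species rhos), RMSE (°C) and MRAE
(`100 * mean(|err| / |Tm|)`, percent). Species with fewer than 2 test
proteins or a constant vector are excluded from rank correlations (logged)
but stay in RMSE aggregates; the pooled RMSE satisfies
`RMSE_global^2 = sum_s (n_s / n) RMSE_s^2` exactly (tested to 1e-10).
Uncertainties are nonparametric bootstrap SDs over test proteins (1000
resamples by default, seed-deterministic). Regime comparisons use a
two-sided paired t-test on per-protein absolute errors, paired by protein
id — the pairing unit that yields the large degrees of freedom such
comparisons report; zero-variance difference vectors are flagged as
degenerate rather than assigned a spurious p-value.

## Numerical and design choices

* Seeds: every stochastic component (generator, initialization, batching,
  dropout, augmentation, bootstrap) derives from one integer via
  `numpy.random.SeedSequence` spawning; identical configs and seeds give
  bit-identical datasets, predictions and report files (HDF5 written with
  `track_times=False`, CSV floats with `%.17g`).
* Softmax over length is computed with the max-subtraction trick on masked
  logits; an all-masked row is rejected (`L >= 1` is an invariant).
* The Rank-N-Contrast denominator always contains its numerator's term
  (`j` belongs to its own rank set), so every per-sample term is the
  negative log of a valid probability and the loss is finite and
  non-negative by construction.
* A single-species dataset under the per-species regime reuses the global
  regime's seed path, making the degenerate partition exactly equivalent
  to global training (up to the learning-rate defaults).
* Early stopping keeps a copy of the best parameters and restores them,
  rather than stopping in place.
* Dropout inside the pooling block is inactive at inference.

## Problem sizes

The examples, tests and the acceptance script run scaled-down study
conditions chosen by the package (6–25 species, 120–500 proteins per
species, embedding dimension 16–32, lengths 50–80 where the pooling layer
matters and 1–3 where only labels are used): the two-level phenomena of
interest — the pooled-vs-stratified Spearman gap at `kappa = 0`, the
species-specific advantage at learnable `kappa`, and the mean-predictor
closed forms — are scale-free in the ways that matter, and these sizes
keep the complete pipeline reproducible on a single CPU. Because the
stated learning rates are per optimizer step, scaled-down datasets supply
proportionally fewer steps per epoch; runs on small data therefore use a
smaller batch (32) and a larger epoch cap where a converged global model
is the point of the exercise, keeping the optimizer-step budget comparable
to full-size training. The dataset-level defaults above remain the
package's reference conditions for full-scale runs.

## Known limitations

* The species-specific advantage in the synthetic world arises because the
  global model must read the species level through a noisy signature
  projection while per-species models absorb it in calibration; real
  cross-species transfer failure plausibly involves richer mechanisms
  (covariate shift, composition effects) the generator does not model.
* The fine-tuning family of approaches (adapting the embedding model
  itself) is out of scope; embeddings are always consumed precomputed.
* MRAE is scale-dependent (°C, not Kelvin); Tm = 0 °C is rejected rather
  than handled.
* The contrastive encoder is residue-wise by design, so it cannot learn
  positional interactions; it satisfies the fixed-size requirement of the
  loss while keeping the downstream light-attention dataflow.
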