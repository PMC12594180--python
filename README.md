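# tmelt

Cross-species vs. species-specific protein melting-temperature (Tm)
regression from frozen per-residue embeddings, with stratified evaluation.

## The problem

Supervised Tm predictors trained on cross-species meltome data report
pooled Spearman correlations above 0.7 — yet perform disappointingly when
asked the question practitioners care about: ranking variants *within* a
species. The reason is structural. Cross-species Tm data is hierarchical:
species means spread widely (σ_between ≈ 12 °C between thermophiles and
mesophiles) while proteins within a species spread narrowly
(σ_within ≈ 5 °C). A model that merely ranks *species* inherits a high
pooled rank correlation — a Simpson's-paradox effect — while the
per-species correlations it actually delivers sit near zero.

`tmelt` packages this analysis end to end, for anyone building or auditing
Tm predictors:

* **`tmelt.synthetic`** — a generator with the two-level structure above:
  `Tm = mu_s + delta_i`, embeddings encoding the species mean linearly and
  the within-species offset along a direction `w` with tunable strength
  `kappa`, plus closed-form mean-predictor baselines
  (σ_within per species; √(σ_between² + σ_within²) globally).
* **`tmelt.model`** — light-attention pooling (two depthwise 1-D
  convolutions producing attention logits and values; softmax over length;
  weighted sum ++ max-pool) feeding an MLP head (128, 64, n); `n = 2` gives
  the dual head with `phi_Tm = y_OGT + y_bias`.
* **`tmelt.objectives`** — MSE; the OGT-anchored dual loss
  `L = MSE(phi_Tm, y_Tm) + MSE(y_OGT, mu_Tm)` with `mu_Tm` the species'
  train-split mean Tm; and the Rank-N-Contrast loss
  `l_i = 1/(2N−1) Σ_{j≠i} −log[ exp(sim(v_i,v_j)/τ) / Σ_{k∈S_ij} exp(sim(v_i,v_k)/τ) ]`
  with `S_ij = {k ≠ i : |y_i − y_k| ≥ |y_i − y_j|}`, two-view Gaussian
  augmentation, and contrastive encoder training.
* **`tmelt.experiment`** — the approach × regime grid: {baseline, concat,
  rnc, dual} × {G (pooled), S (one model per species), GB
  (species-balanced sampling)}, AdamW with regime-dependent learning rates
  (G 1e-4, S 1e-3; encoder 1e-5), early stopping on validation RMSE, and
  mean-predictor references.
* **`tmelt.evaluation`** — pooled *and* per-species Spearman/RMSE/MRAE,
  bootstrap standard errors, and paired t-tests on per-protein absolute
  errors between regimes.
* **`tmelt.data`** — the on-disk layout (CSV table + HDF5 embedding
  store), a reader for benchmark-style tables with validation rows flagged
  inside the train partition, the 50-residue length filter, and species
  partitioning — synthetic and real data are interchangeable.

Models are small, so the package ships its own compact numpy layer stack
with hand-written gradients (verified against finite differences in the
test suite); no deep-learning framework is required.

## Worked example

`examples/02_simpsons_paradox.py` trains the pooled baseline on data whose
embeddings carry **no** within-species signal (`kappa = 0`):

```
pooled test Spearman rho:        +0.881
mean per-species Spearman rho:   +0.006
  s00: rho = -0.132
  s01: rho = +0.196
  ...
pooled test RMSE: 6.26 degC
```

A pooled rho of 0.88 next to per-species rhos scattered around zero is the
paradox in one screen: the model ranks species, not proteins.

`examples/03_regime_comparison.py` switches the within-species signal on
(`kappa = 0.3`) and compares pooled (G) with per-species (S) training:

```
approach   rmse_G  ...   rmse_S  ...  t_G_vs_S     p_G_vs_S
baseline 5.935868  ... 1.371889  ... 10.021967 3.129529e-15
    dual 6.841183  ... 1.985086  ... 10.054691 2.728665e-15
```

Species-specific models win decisively — the pooled model must read the
species level through a noisy embedding projection, while each per-species
model absorbs it in calibration — mirroring the direction seen on real
meltome benchmarks for every approach. The other examples cover the
generator and its analytic baselines (`01`) and the two bespoke losses on
hand-checkable inputs (`04`).

A thin CLI runs the whole pipeline from a YAML config with a manifest for
provenance:

```sh
tmelt generate --config config.yaml
tmelt run      --config config.yaml   # or: tmelt all --config config.yaml
tmelt report   --config config.yaml
```

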