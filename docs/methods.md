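# Methods

## The federated procedure

`fedleaf` simulates cross-silo federated learning with full participation,
in process and sequentially (no network transport). One experiment is:

1. **Initialization.** The server builds the global classifier; its initial
   weights are fully determined by a seed derived from the experiment's
   `base_seed` and the model spec's `init_seed`.
2. **Partitioning.** The training pool is split IID: one seeded uniform
   shuffle of the indices is dealt contiguously to the `C` clients. Exactly
   equal shares are impossible when `C` does not divide the pool, so the
   first `n mod C` clients receive one extra item — the minimal
   deterministic relaxation of equal partitions. The test split is sharded
   the same way so each client owns a private test shard.
3. **Rounds.** For `r = 1..R`: broadcast the global weights; each client
   loads them into its own model instance and runs `E_c` full epochs of
   mini-batch SGD (cross-entropy loss, batch `B_c`, learning rate `L_R`,
   seeded per-epoch shuffles, last batch possibly short); the server
   aggregates the returned weight vectors as `W ← Σₖ (nₖ/n) Wₖ` (FedAvg);
   each client then evaluates the *new* global weights on its test shard.
   Evaluating after aggregation means round 1 already reflects one step of
   collaborative training.
4. **Reporting.** Per round we record per-client metrics, their mean, and
   the metrics of the pooled (summed) confusion matrix. The pooled values
   are the headline numbers: they weight every test image equally and are
   insensitive to shard-size fluctuation. With `C = 1`, the loop provably
   reduces to centralized training (FedAvg of one update is the identity);
   this equivalence is asserted to 1e-5 per parameter in the test suite and
   in practice holds exactly.

Weights travel as `WeightVector`: all trainable parameters flattened into
one ordered float64 array plus a layout manifest (name, shape). Two vectors
are aggregation-compatible iff their layouts are identical; mismatches are
reported with the first differing parameter name.

## Models and optimization

The native desk-scale model is `tiny_cnn`: conv(3→8, 3×3, pad 1) → ReLU →
max-pool 2×2 → conv(8→16, 3×3, pad 1) → ReLU → max-pool 2×2 → global
average pooling → linear head (≈1.5k parameters for 4 classes). Forward and
backward passes are implemented directly in numpy (the convolution is nine
shifted matrix products; max-pool ties split the gradient equally, a
measure-zero event on continuous inputs), so every computation is
bit-deterministic on one CPU — there is no non-deterministic backend mode.
Gradient correctness is pinned by finite-difference checks and, for the
`linear` probe model (flatten → linear softmax), by the closed-form
cross-entropy gradient.

The optimizer is plain SGD without momentum or weight decay, and the loss
is cross-entropy: the configuration exposes exactly one learning rate, and
these are the simplest consistent choices; both are config-visible
decisions rather than hidden defaults. Fine-tuning, layer freezing and
learning-rate schedules are out of scope. The seven full-size backbones are
registry entries whose construction raises an informative error unless a
deep-learning backend is installed; they share the `WeightVector` contract,
so the aggregation and orchestration layers are architecture-agnostic.

Default hyper-parameters mirror the standard experimental grid for this
task: batch size 16, learning rate 0.01, 1 or 5 local epochs, 3/5/7
clients, 10–100 rounds. The desk-scale profile runs 32×32 images and
10 rounds so a full sweep finishes in seconds on one CPU; 224×224 inputs
remain available via the resize target for full-size backbones.

## Synthetic data: what it does and does not emulate

The generator renders each class as an elliptical "leaf" with a distinct
base hue (hues spread evenly around the color wheel), mild radial shading,
and a class-specific lesion motif — spot count, radius, darkness and
placement spread drawn from a per-class parameter table; the healthy class
has no lesions. Per-image jitter comes from one RNG seeded by the dataset
spec, so identical specs are bit-identical. i.i.d. Gaussian pixel noise of
amplitude `noise_level` (default 0.1) is the difficulty dial; at 0 the
classes are separable by a nearest-class-template rule, and template
accuracy is non-increasing in noise. Presets mirror the four standard leaf
datasets (grape/apple/corn with 4 classes, tomato with 10, one healthy
class each).

This reproduces the *statistical structure* the pipeline depends on —
balanced multi-class labels, one healthy class, visually discriminative
patterns, adjustable difficulty — but not the photographic variability of
real leaf images (pose, illumination, background clutter, intra-class
disease progression). Consequently the synthetic task is much easier than
real archives: convergence to ~100% accuracy within a few rounds shows the
federated machinery is correct, not that any architecture would reach that
accuracy on real photographs.

Train/test splitting is stratified with a default test fraction of 0.2 (a
conventional choice; the allocation uses cumulative rounding across classes
so the overall test size tracks the fraction exactly). Channel statistics
(mean and population standard deviation — the population form is the image
normalization convention) are computed on the training split only, before
federation, and applied unchanged to test data; `stats_source: preset`
substitutes the canonical ImageNet statistics instead, the convention when
fine-tuning pretrained backbones.

## Numerical and design choices

- **Seeds.** All randomness derives from `base_seed` through SHA-256
  hashing (`_seeds.derive_seed`), giving decorrelated but reproducible
  streams per purpose (split, train/test partitions, model init, and per
  round × client). Derived seeds stay below 2³¹.
- **FedAvg weighting.** Sample-size weighting is used even though
  partitions differ by at most one item: it is the definition of the
  aggregation rule and makes the ≤1-item imbalance explicit rather than
  approximating it with a plain mean.
- **Zero-division metrics.** A class with no predicted instances
  (precision) or no actual instances (recall) contributes 0 to the macro
  average and raises a warning — degenerate classifiers lower the score
  instead of being silently dropped. Macro averaging is the default (on
  balanced data it coincides with accuracy, matching how near-identical
  accuracy/F1 pairs arise); micro averaging is available by config.
- **Resize.** Bilinear, the common default; a resize to the input's own
  size short-circuits to an exact copy so the identity case is bitwise.
- **Constant channels.** A channel whose pixel standard deviation is below
  1e-12 is treated as zero-variance and rejected (σ must be > 0).
- **Evaluation timing** is after aggregation (see above); both last-round
  and best-round summaries are emitted, with last-round as the default,
  since either convention is defensible for single-number reporting.

## Problem sizes used in tests and the acceptance script

The reference conditions are a synthetic 4-class dataset with 150 images
per class at 32×32 and noise 0.1, split 80/20, trained with 3 clients ×
10 rounds × 1 local epoch (batch 16, lr 0.01); the client-scaling
comparison repeats this at 7 clients over 5 seeds with the total data
fixed. These sizes make a full run take a few seconds while leaving the
learning problem non-trivial (the first round is typically imperfect). The
single-client/centralized equivalence check uses 40 images per class with
3 rounds × 2 epochs.

## Known limitations

- No non-IID (label- or quantity-skew) partitioning, client dropout,
  partial participation, differential privacy, secure aggregation, or
  communication-cost accounting; alternative aggregators (FedProx,
  federated SGD, secure-multiparty averaging) are out of scope.
- The native models are CPU-scale; full-size backbone training requires an
  external deep-learning backend and is not exercised here.
- Synthetic data cannot certify real-world accuracy (see above); disk
  round-trips quantize pixels to 8 bits.
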