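# Methods

## Model

The classifier is `f(x) = softmax(ψ(Σᵢ φᵢ(xᵢ)))` over N non-overlapping
features.  Three encoder layouts cover the supported input families:

* **Independent encoders** (tabular): one MLP per feature, all mapping into
  the same D-dimensional latent space.  They are evaluated as a single
  stacked tensor contraction per layer, so separability — feature `j`'s
  values never influence `zᵢ` for `i ≠ j` — holds by construction, not by
  convention, and is verified by finite differences in the tests.
* **Shared encoder with positions** (image patches): one MLP applied to
  every patch, with a learned positional embedding (same width as the
  flattened patch) added to the input.  Parameter count is then independent
  of N.
* **Token encoder** (sequences): a learned token-embedding table; a
  feature's k token embeddings are concatenated, a learned positional
  embedding of the same width is added, and a shared MLP produces the
  latent.  Paired sequences are encoded receptor-then-epitope with one
  global position index (the alternative — two separate position spaces —
  is equivalent up to a relabeling of the embedding table and was not
  given a separate code path).

The predictor head `ψ` maps the summed latent to class logits; softmax is
applied outside `ψ`, so single-feature logits `ψ(zᵢ)` are directly
comparable to full-model logits.  `ψ` can be an MLP (default), a single
affine map (`predictor="linear"`, optionally bias-free), or the identity
(`predictor="identity"`, requiring D = M) — the last two exist because they
make interpretation statements exact and reduce the model to multinomial
logistic regression, respectively, which the tests exploit as oracles.

### Assumptions

The additive form models no explicit feature interactions; its capacity
rests on the predictor head recombining the summed latents nonlinearly.
Tasks whose labels depend on high-order interactions between many features
that a sum cannot disentangle are outside the model's sweet spot, and the
single-feature ("algorithmic") interpretation is only first-order accurate:
its residual grows with the curvature of `ψ`.

## Training

Minibatch cross-entropy with Adam (lr 1e-3 default, Kaiming-uniform
initialization), optional decoupled weight decay, stratified validation
split with early stopping on validation loss, and class balancing by
inverse-frequency class weights (default), a minimal SMOTE (numeric
features only), or nothing.  An optional group-lasso-style penalty

```
λ · meanₛ Σᵢ ‖zᵢ‖₂
```

shrinks per-feature latents toward zero.  This penalty matters beyond
sparsity cosmetics: without it, an *uninformative* feature's encoder has no
gradient pressure toward zero and typically converges to a constant,
non-zero latent (a constant offset is absorbed by `ψ`), which pollutes the
latent-norm importance ranking.  With a small λ the norms of uninformative
features collapse and the ranking becomes faithful; the reference
experiments therefore train with λ = 0.03 (tabular) and λ = 0.01 (images).
The trade-off is mild — on the tabular benchmark λ = 0.03 *improves* test
AUC slightly by suppressing noise features.

All randomness (initialization, splitting, shuffling, oversampling) derives
from the seed in the training config; on one thread the training log is
reproducible bit for bit.  The latent sum accumulates in ascending feature
order.  Non-finite loss raises a divergence error carrying the last stable
parameters.

## Interpretation

* **Latent-norm importance**: `‖zᵢ‖₂` (Euclidean; the norm is configurable
  in principle but Euclidean is used throughout).  Class-level tables mean-
  aggregate per class — grouping by true or predicted label, both provided —
  and normalize each feature column by its maximum, so every non-empty
  column peaks at 1.  Empty classes yield NaN rows and are flagged rather
  than zeroed.
* **Algorithmic interpretation**: reports `softmax(ψ(zᵢ))`, the exact
  prediction change `softmax(ψ(z*+zᵢ)) − softmax(ψ(z*))`, and the residual
  `‖(ψ(z*+zᵢ) − ψ(z*)) − ψ(zᵢ)‖` computed on logits (the first-order
  statement is exact for linear `ψ` only before the output nonlinearity).
  The per-sample report lists the top-3 classes for the full prediction and
  for each of the 7 highest-norm features; PAD-only features are excluded
  from the ranking by default.
* **Prototypes**: PAM K-Medoids (greedy BUILD + best-improvement SWAP on a
  precomputed Euclidean distance matrix over aggregate latents), run per
  *predicted* class, k = 6 per class by default; groups of ≤ k samples are
  returned whole.  PAM is exact on every exhaustively checkable group size
  tested (≤ 12).
* **Nearest neighbors**: Euclidean distance between aggregate latents,
  default k = 3, deterministic tie-break by sample id.
* **Post-hoc baselines** (for comparison only): saliency (gradient
  magnitude of the predicted-class logit), input×gradient, and integrated
  gradients (midpoint Riemann sum from a zero baseline, 32 steps by
  default; exact at any step count for linear networks).  Token inputs are
  attributed at the embedding layer since token ids are discrete.  Element
  scores reduce to per-feature scores by the maximum within the feature.

## Evaluation protocols

* **ROC-AUC**: binary AUC for M = 2, macro one-vs-rest for M > 2 (classes
  without both positives and negatives in the evaluation set are skipped).
* **ROAR**: rebuild the feature spec restricted to the kept set, retrain
  from scratch (fresh seed per repeat, 5 repeats by default), and compare
  test AUC to the full model.
* **Removal test**: rank features per sample by a scoring method, drop the
  top-r latents from the sum for r = 0..max_removed, reclassify.  Removal
  is implemented as subtracting the ranked latents' cumulative sum from the
  aggregate, which for a sum is exactly omission; the r = 0 point equals
  the unmodified accuracy by construction, and the whole curve is
  deterministic given model and data.

## Synthetic tasks

* **Tabular**: features i.i.d. standard normal; class-c logit
  `Σ_{i∈S} w_{c,i} g_i(x_i)` with effect functions from a fixed library
  (identity, quadratic `x²−1`, `sin 3x`, step).  Weights assign each class
  an equally spaced response level (± weight_scale for M = 2) in a random
  per-feature order, so every planted feature discriminates and the Bayes
  posterior is the softmax of the true logits in closed form.  Labels are
  *sampled* from that posterior, so the oracle's own AUC (the Bayes AUC) is
  below 1 and upper-bounds any classifier.  Defaults: n = 4000, N = 20,
  S = {0,1,2,3} with effects (quadratic, sine, quadratic, step),
  weight_scale = 2 — calibrated so a linear model trails the Bayes AUC by
  well over 0.1 while the additive network can close the gap.
* **Sequences**: pairs bind iff a planted 3-mer motif occurs in the
  receptor AND an anchor token occurs in the epitope.  Negatives knock out
  the motif, the anchor, or both (uniformly), so most negatives satisfy one
  condition and sequence length or composition alone carries no signal.  A
  rule evaluator re-derives every label from the raw strings.
* **Images**: 28×28×3 images on a 7×7 grid of 4×4 patches; a fixed 4-patch
  blob is colored by one of M = 4 well-separated class colors (plus noise),
  the background is gray noise, and a 2-patch *distractor* blob is colored
  uniformly at random per sample, independent of the label.  The distractor
  gives input-magnitude-driven attributions something salient but
  uninformative to latch onto, which is what separates the latent-norm
  ranking from the gradient baselines in the removal test.  The ground-
  truth patch mask is returned for scoring importance maps.

What the generators deliberately do **not** emulate: realistic scRNA-seq
count distributions (no dropout, no library-size variation), realistic
receptor repertoires (no V(D)J structure, uniform letter frequencies) and
natural image statistics.  Passing tests therefore demonstrate that the
architecture recovers *planted additive/localized structure* under its own
assumptions — not performance on real data.

## Reference experiment sizes

The reference experiments (in `flan.benchmarks`, shared by the test suite
and `scripts/acceptance.py`) use desk-scale sizes chosen to keep a full run
in the low minutes on one CPU: tabular 3000 train / 1000 test over 10
seeds; the linear-regime equivalence task 2000/1000 (weight_scale = 8, so
the task is nearly separable and two near-optimal linear classifiers agree
almost everywhere); ROAR over 5 seeds with one retraining per subset;
images 1500 train / 500 test with removal up to r = 5.

## Known limitations

* Training is plain NumPy on one CPU; it is comfortable at these problem
  sizes but not engineered for very large N or deep encoders.
* SMOTE balancing is a minimal nearest-neighbor interpolation and is
  restricted to numeric feature modes.
* The k-mer vocabulary is embedded per token (k embeddings concatenated),
  not per k-mer type; extremely large k would dilute positional precision.
* Removal semantics are tied to sum aggregation; other aggregators (means,
  attention) would not make omission and subtraction equivalent.
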