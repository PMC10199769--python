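# flan-additive

Feature-wise latent additive networks: structurally interpretable neural
classifiers for tabular (single-cell-expression-like), paired-sequence
(receptor–epitope) and patch-based image data.

## The problem

Deep classifiers are accurate but opaque; linear models are interpretable
because they are *separable* — each feature's effect can be examined on its
own.  This package implements a classifier that keeps that separability
while retaining nonlinear capacity:

```
f(x) = ψ( Σᵢ φᵢ(xᵢ) )          i = 1..N features
```

Each feature `xᵢ` (a gene-expression value, an amino-acid token or k-mer, or
an image patch) is mapped by its own encoder `φᵢ` — or by one shared encoder
`φ(·; θ, pᵢ)` with a learned positional embedding `pᵢ` — into a common latent
space `Z` of dimension `D`.  The per-feature latents `zᵢ` are **summed**, and
a predictor head `ψ : Z → ℝᴹ` maps the aggregate to class logits.  Because
`zᵢ` depends on feature `i` alone, the model supports three native
interpretation modalities, with no post-hoc attribution step:

1. **Algorithmic** — predict from a single feature's latent, `ψ(zᵢ)`.
   Writing `z* = Σⱼ≠ᵢ zⱼ`, the estimate's error against the true prediction
   change `ψ(z* + zᵢ) − ψ(z*)` is a first-order Taylor residual that
   vanishes when `ψ` is linear.
2. **Latent-norm importance** — `‖zᵢ‖₂` per sample per feature: a feature
   mapped near zero contributes nothing to the sum.  A group-lasso-style
   penalty `λ · mean Σᵢ‖zᵢ‖₂` is available during training to sparsify these
   importances.
3. **Example-based** — K-Medoids prototypes per predicted class and nearest
   neighbors under Euclidean distance in `Z`.

Faithfulness of the importances is testable with two protocols: **ROAR**
(remove-and-retrain on a kept feature subset) and an inference-time
**removal test** (drop the top-ranked latents from the sum and reclassify),
with saliency, input×gradient and integrated-gradients baselines included
for comparison.

## Worked example

Train on a synthetic tabular task where only features {0, 1, 2, 3} carry
label signal, through nonlinear effects, and the exact Bayes posterior is
known in closed form:

```python
import numpy as np
from flan import FLAN, TrainConfig
from flan.synthetic import SyntheticTabularSpec, gen_tabular
from flan.evaluate import roc_auc

task = gen_tabular(SyntheticTabularSpec(seed=1))          # n=4000, N=20, |S|=4
train, test = np.arange(3000), np.arange(3000, 4000)
ds_train, ds_test = task.encoded(train), task.encoded(test)

model = FLAN(ds_train, latent_dim=16, encoder_hidden=(32, 32),
             predictor_hidden=(32, 32))
results = model.fit(TrainConfig(epochs=100, batch_size=128, seed=1,
                                sparsity_weight=0.03, patience=15))
print(results.summary())
print(f"test ROC-AUC:  {results.score_auc(ds_test):.3f}")
print(f"Bayes ROC-AUC: {roc_auc(task.posterior(task.X[test]), task.y[test]):.3f}")
imp = results.feature_importance(ds_train).scores.mean(axis=0)
print("top features by mean latent norm:", np.argsort(-imp)[:4].tolist())
```

Output:

```
Feature-wise Latent Additive Network
====================================================
mode:             per_column
features (N):     20
latent dim (D):   16
classes (M):      2
encoder:          per-feature MLP hidden=(32, 32)
predictor:        mlp hidden=(32, 32)
parameters:       34626
----------------------------------------------------
trained: epochs=70 (best=54), seed=1, lambda=0.03
final train loss: 0.1738
best val loss:    0.1707  val accuracy: 0.8733
test ROC-AUC:  0.972
Bayes ROC-AUC: 0.988
top features by mean latent norm: [3, 0, 2, 1]
```

The trained model lands within 0.016 AUC of the Bayes ceiling (a linear
model reaches only ≈ 0.74 here), and the four planted informative features
are exactly the four largest mean latent norms.

## Command line

```bash
flan generate --task tabular --out-dir run/ --seed 1 --n 4000
flan train    --config config.yaml --out-dir run/
flan explain  --checkpoint run/checkpoint.npz --data run/tabular.csv --modality global
flan evaluate --checkpoint run/checkpoint.npz --data run/tabular.csv --protocol auc
```

Every run writes a `manifest.json` with the config snapshot, seed, data
fingerprints and metric summaries.

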