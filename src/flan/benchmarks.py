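"""Reference experiments on the synthetic tasks.

These functions pin down the canonical desk-scale study conditions —
generator settings, architecture and training configuration — used to
validate the additive model's approximation power and the faithfulness of
its native importances.  Keeping them in the library (rather than in test
code) makes the numbers reproducible from a script or shell with one call.

Conditions (tabular): n = 4000 samples (3000 train / 1000 test), N = 20
features, |S| = 4 informative with nonlinear effects, M = 2 classes; the
model trains with the latent-norm sparsity regularizer (lambda = 0.03),
which is the architecture's own mechanism for driving uninformative
feature latents toward zero.

Conditions (images): n = 2000 (1500 train / 500 test) 28x28x3 images, 4x4
patches (49 features), a 4-patch class-colored blob and a 2-patch
label-independent distractor, M = 4 classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from . import interpret
from .evaluate import removal_test, roar, roc_auc
from .model import FLAN, FLANResults, TrainConfig
from .synthetic import (
    SyntheticImageSpec,
    SyntheticTabularSpec,
    gen_images,
    gen_tabular,
)

TABULAR_TRAIN = 3000
TABULAR_MODEL = dict(latent_dim=16, encoder_hidden=(32, 32), predictor_hidden=(32, 32))
TABULAR_CONFIG = TrainConfig(
    epochs=100, batch_size=128, patience=15, sparsity_weight=0.03
)

IMAGE_TRAIN = 1500
IMAGE_MODEL = dict(latent_dim=32, encoder_hidden=(64, 64), predictor_hidden=(32,))
IMAGE_CONFIG = TrainConfig(epochs=40, batch_size=64, patience=10, sparsity_weight=0.01)


@dataclass
class TabularBenchmark:
    """One seed of the tabular approximation/importance experiment."""

    seed: int
    bayes_auc: float
    flan_auc: float
    logreg_auc: float
    top_features: tuple  # top-|S| features by mean latent norm on train data
    informative: tuple
    results: FLANResults

    @property
    def bayes_gap(self) -> float:
        return self.bayes_auc - self.flan_auc

    @property
    def margin_over_logreg(self) -> float:
        return self.flan_auc - self.logreg_auc

    @property
    def recovered(self) -> bool:
        return set(self.top_features) == set(self.informative)


def run_tabular_benchmark(seed: int) -> TabularBenchmark:
    """Train on the planted-structure tabular task and score against the
    closed-form Bayes posterior and a multinomial logistic regression."""
    from sklearn.linear_model import LogisticRegression

    task = gen_tabular(SyntheticTabularSpec(seed=seed))
    tr = np.arange(TABULAR_TRAIN)
    te = np.arange(TABULAR_TRAIN, task.spec.n_samples)
    ds_tr, ds_te = task.encoded(tr), task.encoded(te)
    res = FLAN(ds_tr, **TABULAR_MODEL).fit(replace(TABULAR_CONFIG, seed=seed))
    bayes = roc_auc(task.posterior(task.X[te]), task.y[te])
    flan_auc = res.score_auc(ds_te)
    lr = LogisticRegression(max_iter=1000).fit(task.X[tr], task.y[tr])
    lr_auc = roc_auc(lr.predict_proba(task.X[te]), task.y[te])
    mean_imp = res.feature_importance(ds_tr).scores.mean(axis=0)
    top = tuple(np.argsort(-mean_imp)[: len(task.spec.informative)].tolist())
    return TabularBenchmark(
        seed=seed,
        bayes_auc=bayes,
        flan_auc=flan_auc,
        logreg_auc=lr_auc,
        top_features=top,
        informative=tuple(task.spec.informative),
        results=res,
    )


EQUIVALENCE_SPEC = dict(
    n_samples=3000,
    n_features=10,
    informative=(0, 1, 2, 3),
    effects=("identity",) * 4,
    weight_scale=8.0,
)
EQUIVALENCE_CONFIG = TrainConfig(
    epochs=300,
    batch_size=256,
    learning_rate=0.05,
    class_balance="none",
    patience=0,
    val_fraction=0.0,
)


@dataclass
class EquivalenceBenchmark:
    """Label agreement between a linearly constrained additive model and
    multinomial logistic regression on a (near-)separable linear task."""

    seed: int
    agreement: float
    flan_accuracy: float
    logreg_accuracy: float


def run_equivalence_benchmark(seed: int) -> EquivalenceBenchmark:
    """With scalar affine encoders into D = M and an identity-logit head the
    additive model *is* a multinomial logistic regression; trained on the
    same data, the two decision functions should coincide almost everywhere.
    """
    from sklearn.linear_model import LogisticRegression

    task = gen_tabular(SyntheticTabularSpec(seed=seed, **EQUIVALENCE_SPEC))
    tr, te = np.arange(2000), np.arange(2000, task.spec.n_samples)
    ds_tr, ds_te = task.encoded(tr), task.encoded(te)
    res = FLAN(ds_tr, latent_dim=2, encoder_hidden=(), predictor="identity").fit(
        replace(EQUIVALENCE_CONFIG, seed=seed)
    )
    lr = LogisticRegression(max_iter=2000, C=1e6).fit(task.X[tr], task.y[tr])
    pred_flan = res.predict(ds_te)
    pred_lr = lr.predict(task.X[te])
    return EquivalenceBenchmark(
        seed=seed,
        agreement=float((pred_flan == pred_lr).mean()),
        flan_accuracy=float((pred_flan == task.y[te]).mean()),
        logreg_accuracy=float((pred_lr == task.y[te]).mean()),
    )


@dataclass
class RoarBenchmark:
    """ROAR on the tabular task: informative vs random uninformative subset."""

    seed: int
    reference_auc: float
    informative_auc: float
    random_auc: float

    @property
    def informative_drop(self) -> float:
        return self.reference_auc - self.informative_auc

    @property
    def random_drop(self) -> float:
        return self.reference_auc - self.random_auc


def run_roar_benchmark(seed: int) -> RoarBenchmark:
    """Retrain on the planted set S, and on an equal-sized random subset
    disjoint from S, comparing test AUC against the full model."""
    task = gen_tabular(SyntheticTabularSpec(seed=seed))
    tr = np.arange(TABULAR_TRAIN)
    te = np.arange(TABULAR_TRAIN, task.spec.n_samples)
    ds_tr, ds_te = task.encoded(tr), task.encoded(te)
    cfg = replace(TABULAR_CONFIG, seed=seed)
    S = list(task.spec.informative)
    rng = np.random.default_rng(seed)
    others = [i for i in range(task.spec.n_features) if i not in S]
    random_set = sorted(rng.choice(others, size=len(S), replace=False).tolist())
    full = FLAN(ds_tr, **TABULAR_MODEL).fit(cfg)
    reference = full.score_auc(ds_te)
    r_inf = roar(ds_tr, ds_te, S, cfg, model_kwargs=TABULAR_MODEL,
                 reference_auc=reference, repeats=1)
    r_rand = roar(ds_tr, ds_te, random_set, cfg, model_kwargs=TABULAR_MODEL,
                  reference_auc=reference, repeats=1)
    return RoarBenchmark(
        seed=seed,
        reference_auc=reference,
        informative_auc=r_inf.retrained_auc,
        random_auc=r_rand.retrained_auc,
    )


@dataclass
class ImageBenchmark:
    """Removal-test comparison of latent-norm vs post-hoc attributions."""

    seed: int
    test_accuracy: float
    curves: Dict[str, np.ndarray]  # method -> accuracies for r = 0..max_removed
    blob_feature_ids: np.ndarray
    top_features: tuple  # by mean latent norm

    def accuracy_at(self, method: str, r: int) -> float:
        return float(self.curves[method][r])


def run_image_benchmark(seed: int, max_removed: int = 5) -> ImageBenchmark:
    """Train on the blob-image task, then remove top-ranked patches per
    scoring method (latent norm, saliency, input x gradient, integrated
    gradients, random) and reclassify."""
    task = gen_images(SyntheticImageSpec(seed=seed))
    tr = np.arange(IMAGE_TRAIN)
    te = np.arange(IMAGE_TRAIN, task.spec.n_samples)
    ds_tr, ds_te = task.encoded(tr), task.encoded(te)
    res = FLAN(ds_tr, **IMAGE_MODEL).fit(replace(IMAGE_CONFIG, seed=seed))
    imp = interpret.latent_norm_scores(res, ds_te)
    scorers = {"latent_norm": imp}
    for method in interpret.POSTHOC_METHODS:
        scorers[method] = res.posthoc_scores(ds_te, method)
    rng = np.random.default_rng(seed)
    scorers["random"] = rng.uniform(size=imp.shape)
    curves = removal_test(res, ds_te, scorers, max_removed=max_removed)
    return ImageBenchmark(
        seed=seed,
        test_accuracy=res.accuracy(ds_te),
        curves={name: c.accuracies for name, c in curves.items()},
        blob_feature_ids=task.blob_feature_ids,
        top_features=tuple(np.argsort(-imp.mean(axis=0))[:4].tolist()),
    )
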