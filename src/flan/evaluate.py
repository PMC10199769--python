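"""Metrics and faithfulness protocols.

Two protocols probe whether purportedly important features really carry the
label information:

* *Remove-and-retrain (ROAR)* — retrain the model from scratch using only a
  kept feature subset and compare test AUC to the full model.  A small drop
  means the kept features were genuinely informative.
* *Removal test* — rank features per sample by some scoring method, drop the
  top-r latents from the summation at inference (no retraining), and
  reclassify.  A faithful scorer produces the steepest accuracy decline.

Removing a feature means omitting its latent from the sum, which for a sum
is identical to subtracting it from the aggregate; each sample may drop a
different feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np

from .exceptions import SpecValidationError, UndefinedMetricError
from .grouping import EncodedDataset
from .model import FLAN, FLANResults, TrainConfig


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC: standard binary AUC for two classes, macro one-vs-rest for
    more.  Classes absent from ``labels`` (or present without a complement)
    are skipped in the macro average; ties are handled by midranks."""
    from sklearn.metrics import roc_auc_score

    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise UndefinedMetricError("ROC-AUC is undefined for a single class")
    m = probabilities.shape[1]
    if m == 2:
        return float(roc_auc_score(labels, probabilities[:, 1]))
    aucs = []
    for c in range(m):
        y_bin = (labels == c).astype(int)
        if 0 < y_bin.sum() < len(y_bin):
            aucs.append(roc_auc_score(y_bin, probabilities[:, c]))
    return float(np.mean(aucs))


def accuracy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    return float((np.asarray(probabilities).argmax(axis=1) == np.asarray(labels)).mean())


# ---------------------------------------------------------------------- #
# remove-and-retrain


@dataclass
class RoarResult:
    """Outcome of retraining on a kept feature subset."""

    kept_feature_ids: tuple
    retrained_aucs: np.ndarray  # one per repeat
    reference_aucs: np.ndarray  # full-model AUCs (same seeds) or given scalar
    seeds: tuple

    @property
    def retrained_auc(self) -> float:
        return float(self.retrained_aucs.mean())

    @property
    def retrained_auc_sd(self) -> float:
        return float(self.retrained_aucs.std(ddof=1)) if len(self.retrained_aucs) > 1 else 0.0

    @property
    def reference_auc(self) -> float:
        return float(np.mean(self.reference_aucs))

    @property
    def drop(self) -> float:
        return self.reference_auc - self.retrained_auc


def roar(
    train_data: EncodedDataset,
    test_data: EncodedDataset,
    kept_features: Sequence[int],
    config: TrainConfig,
    model_kwargs: Optional[dict] = None,
    reference_auc: Optional[float] = None,
    repeats: int = 5,
) -> RoarResult:
    """Retrain from scratch on ``kept_features`` only and measure test AUC.

    Each repeat uses a fresh seed (``config.seed + r``).  If
    ``reference_auc`` is not given, a full-feature model is trained with the
    same seeds to provide the reference.
    """
    kept = tuple(int(i) for i in kept_features)
    if not kept:
        raise SpecValidationError("ROAR requires a non-empty kept feature set")
    model_kwargs = dict(model_kwargs or {})
    train_r = train_data.restrict_features(kept)
    test_r = test_data.restrict_features(kept)
    retrained, reference, seeds = [], [], []
    for r in range(repeats):
        cfg = replace(config, seed=config.seed + r)
        seeds.append(cfg.seed)
        res = FLAN(train_r, **model_kwargs).fit(cfg)
        retrained.append(res.score_auc(test_r))
        if reference_auc is None:
            full = FLAN(train_data, **model_kwargs).fit(cfg)
            reference.append(full.score_auc(test_data))
    if reference_auc is not None:
        reference = [reference_auc]
    return RoarResult(
        kept_feature_ids=kept,
        retrained_aucs=np.asarray(retrained),
        reference_aucs=np.asarray(reference),
        seeds=tuple(seeds),
    )


# ---------------------------------------------------------------------- #
# inference-time removal test


@dataclass
class RemovalCurve:
    """Accuracy after deleting the r top-ranked features per sample."""

    method: str
    removed_counts: np.ndarray  # r = 0..max_removed
    accuracies: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"removed": self.removed_counts, "accuracy": self.accuracies}
        )


Scorer = Union[np.ndarray, Callable[[FLANResults, EncodedDataset], np.ndarray]]


def removal_test(
    results: FLANResults,
    test_data: EncodedDataset,
    scorers: Dict[str, Scorer],
    max_removed: int,
) -> Dict[str, RemovalCurve]:
    """For each scoring method, remove the r highest-scored features of each
    sample from the latent summation (r = 0..max_removed) and record the
    reclassification accuracy.  Deterministic given model and data."""
    if test_data.labels is None:
        raise UndefinedMetricError("removal test requires labels")
    N = test_data.spec.n_features
    if max_removed >= N:
        warnings.warn(f"max_removed={max_removed} >= N={N}; truncating to {N - 1}")
        max_removed = N - 1
    latent = results.encode(test_data)
    y = results.model._encode_labels(test_data.labels)
    n = len(test_data)
    curves = {}
    for name, scorer in scorers.items():
        scores = scorer if isinstance(scorer, np.ndarray) else scorer(results, test_data)
        if scores.shape != (n, N):
            raise SpecValidationError(
                f"scorer {name!r} returned shape {scores.shape}, expected {(n, N)}"
            )
        order = np.argsort(-scores, axis=1, kind="stable")
        # latents of each sample ordered by descending score, cumulatively summed
        gathered = np.take_along_axis(latent.per_feature, order[:, :, None], axis=1)
        cum = np.cumsum(gathered[:, :max_removed, :], axis=1)
        accs = []
        for r in range(max_removed + 1):
            agg = latent.aggregate if r == 0 else latent.aggregate - cum[:, r - 1, :]
            logits = results.network.psi_logits(agg)
            accs.append(float((logits.argmax(axis=1) == y).mean()))
        curves[name] = RemovalCurve(
            method=name,
            removed_counts=np.arange(max_removed + 1),
            accuracies=np.asarray(accs),
        )
    return curves
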