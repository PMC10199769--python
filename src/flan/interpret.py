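"""Native interpretation of additive networks, plus post-hoc baselines.

Three modalities come directly from the architecture:

1. *Algorithmic interpretation* — the effect of feature i is estimated by
   predicting on its latent alone, psi(z_i).  Writing z_* for the sum of the
   other latents, the estimate's error against the true prediction change
   Delta = psi(z_* + z_i) - psi(z_*) is the first-order Taylor residual; it
   vanishes when psi is linear with zero bias.  We report the residual on
   logits, where the statement is exact.
2. *Latent-norm importance* — ||z_i||_2 per sample per feature; a feature
   mapped to (near) zero contributes nothing to the sum.  Class-level views
   mean-aggregate over samples and normalize each feature column by its max.
3. *Example-based* — K-Medoids prototypes per predicted class, and nearest
   neighbors under Euclidean distance between aggregate latents.

For comparison studies, three standard gradient attributions (saliency,
input x gradient, integrated gradients) are implemented on the same
network; element scores are reduced to per-feature scores by taking the
maximum within the feature.  For token inputs the gradients are taken at
the embedding layer, since token ids are discrete.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .exceptions import InputShapeError
from .grouping import EncodedDataset
from .model import FLANResults, LatentBatch

logger = logging.getLogger(__name__)

POSTHOC_METHODS = ("saliency", "input_x_gradient", "integrated_gradients")


# ---------------------------------------------------------------------- #
# latent-norm importance


@dataclass
class ImportanceMatrix:
    """Per-sample, per-feature non-negative latent-norm scores."""

    scores: np.ndarray  # (n, N), >= 0
    feature_names: tuple

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.scores, columns=list(self.feature_names))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


@dataclass
class GlobalImportance:
    """Class-by-feature mean importances, optionally column-normalized."""

    table: np.ndarray  # (C, N); NaN rows mark empty classes
    classes: np.ndarray
    feature_names: tuple
    normalization: str
    empty_classes: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.table, index=list(self.classes), columns=list(self.feature_names)
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="class")


def feature_importance(results: FLANResults, data: EncodedDataset) -> ImportanceMatrix:
    """Euclidean norms ||z_i||_2 of the per-feature latents."""
    latent = results.encode(data)
    return ImportanceMatrix(scores=latent.norms(), feature_names=data.spec.names())


def global_importance(
    results: FLANResults,
    data: EncodedDataset,
    grouping: str = "true_label",
    normalization: str = "per_feature_max",
) -> GlobalImportance:
    """Mean importance per class, grouped by true or predicted label.

    With ``per_feature_max`` normalization every non-zero feature column is
    divided by its maximum, so column maxima are exactly 1.  Classes with no
    samples yield NaN rows and are listed in ``empty_classes``.
    """
    if grouping not in ("true_label", "predicted_label"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if normalization not in ("per_feature_max", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    imp = feature_importance(results, data)
    if grouping == "true_label":
        if data.labels is None:
            raise InputShapeError("true_label grouping requires labels")
        labels = np.asarray(data.labels)
    else:
        labels = results.predict(data)
    classes = results.classes_
    table = np.full((len(classes), data.spec.n_features), np.nan)
    empty = []
    for ci, c in enumerate(classes):
        mask = labels == c
        if mask.any():
            table[ci] = imp.scores[mask].mean(axis=0)
        else:
            empty.append(c)
            logger.warning("class %r has no samples; importance row is NaN", c)
    if normalization == "per_feature_max":
        with np.errstate(invalid="ignore"):
            col_max = np.nanmax(table, axis=0)
        nonzero = col_max > 0
        table[:, nonzero] = table[:, nonzero] / col_max[nonzero]
    return GlobalImportance(table, classes, data.spec.names(), normalization, empty)


# ---------------------------------------------------------------------- #
# algorithmic interpretation


@dataclass
class AlgorithmicInterpretation:
    """Single-feature effect estimate and its first-order residual."""

    feature: int
    feature_name: str
    single_feature_probs: np.ndarray  # softmax(psi(z_i))
    delta_probs: np.ndarray  # softmax(psi(z_* + z_i)) - softmax(psi(z_*))
    residual: float  # ||(psi(z_*+z_i) - psi(z_*)) - psi(z_i)|| on logits


def single_feature_prediction(
    results: FLANResults, data: EncodedDataset, sample: int, feature: int
) -> AlgorithmicInterpretation:
    """Predict from feature ``feature``'s latent alone for one sample."""
    N = data.spec.n_features
    if not 0 <= feature < N:
        raise IndexError(f"feature {feature} out of range 0..{N - 1}")
    latent = results.encode(data.subset(np.asarray([sample])))
    z_i = latent.per_feature[0, feature]
    z_star = latent.aggregate[0] - z_i
    net = results.network
    logit_i = net.psi_logits(z_i[None])[0]
    logit_full = net.psi_logits((z_star + z_i)[None])[0]
    logit_star = net.psi_logits(z_star[None])[0]
    residual = float(np.linalg.norm((logit_full - logit_star) - logit_i))
    return AlgorithmicInterpretation(
        feature=feature,
        feature_name=data.spec.names()[feature],
        single_feature_probs=nn.softmax(logit_i[None])[0],
        delta_probs=nn.softmax(logit_full[None])[0] - nn.softmax(logit_star[None])[0],
        residual=residual,
    )


def _pad_feature_mask(data: EncodedDataset) -> np.ndarray:
    """(n, N) bool mask: True where a token feature consists of PAD only."""
    if data.spec.kind != "token":
        return np.zeros(data.features.shape[:2], dtype=bool)
    return (data.features == data.spec.pad_id).all(axis=2)


def interpretation_report(
    results: FLANResults,
    data: EncodedDataset,
    sample: int,
    top_features: int = 7,
    top_classes: int = 3,
    exclude_pad: bool = True,
) -> dict:
    """Per-sample report: the full prediction's top classes, then the top
    classes predicted from each of the highest-norm features alone.

    PAD-only features are excluded from the ranking by default (they carry
    no information and are assigned low scores anyway).
    """
    latent = results.encode(data.subset(np.asarray([sample])))
    norms = latent.norms()[0]
    if exclude_pad:
        norms = np.where(_pad_feature_mask(data)[sample], -np.inf, norms)
    probs_full = results.predict_proba_from_latent(latent.aggregate)[0]
    classes = [str(c) for c in results.classes_]
    names = data.spec.names()

    def top(p):
        order = np.argsort(-p)[:top_classes]
        return [{"class": classes[j], "probability": float(p[j])} for j in order]

    order = np.argsort(-norms)[:top_features]
    report = {
        "sample": int(sample),
        "predicted_class": classes[int(np.argmax(probs_full))],
        "full": top(probs_full),
        "features": [],
    }
    for i in order:
        probs_i = results.predict_proba_from_latent(latent.per_feature[0, i][None])[0]
        report["features"].append(
            {
                "feature": int(i),
                "name": names[i],
                "importance": float(latent.norms()[0, i]),
                "top_classes": top(probs_i),
            }
        )
    return report


# ---------------------------------------------------------------------- #
# example-based interpretation


@dataclass
class PrototypeSet:
    """K-Medoids prototypes per predicted class (real training samples)."""

    medoid_ids: dict  # class label -> np.ndarray of dataset indices
    latents: dict  # class label -> (k, D) medoid latent vectors
    k_per_class: int


def pam_kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Partitioning-around-medoids on a precomputed distance matrix.

    Greedy BUILD followed by best-improvement SWAP until convergence.
    Returns sorted medoid indices.  For n <= k all points are returned.
    """
    n = len(dist)
    if n <= k:
        return np.arange(n)
    medoids: list = []
    # BUILD: repeatedly add the point that most reduces total distance
    nearest = np.full(n, np.inf)
    for _ in range(k):
        # cost if candidate j were added: sum_p min(nearest[p], dist[p, j])
        costs = np.minimum(dist, nearest[:, None]).sum(axis=0)
        costs[medoids] = np.inf
        j = int(np.argmin(costs))
        medoids.append(j)
        nearest = np.minimum(nearest, dist[:, j])
    medoids = list(medoids)
    # SWAP
    improved = True
    while improved:
        improved = False
        current = dist[:, medoids].min(axis=1).sum()
        best = (current, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in med_set:
                    continue
                cost = np.minimum(base, dist[:, h]).sum()
                if cost < best[0] - 1e-12:
                    best = (cost, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            improved = True
    return np.sort(np.asarray(medoids))


def prototypes(
    results: FLANResults,
    data: EncodedDataset,
    k_per_class: int = 6,
    seed: int = 0,
) -> PrototypeSet:
    """Split samples by *predicted* class and select K-Medoids prototypes in
    the aggregate latent space under Euclidean distance.

    Groups with at most ``k_per_class`` members are returned whole; empty
    groups yield empty prototype lists (logged, not an error).
    """
    rng = np.random.default_rng(seed)
    latent = results.encode(data)
    predicted = results.predict(data)
    medoid_ids, latents = {}, {}
    for c in results.classes_:
        idx = np.flatnonzero(predicted == c)
        if len(idx) == 0:
            logger.warning("no samples predicted as class %r; no prototypes", c)
            medoid_ids[c] = np.asarray([], dtype=int)
            latents[c] = np.zeros((0, latent.aggregate.shape[1]))
            continue
        Z = latent.aggregate[idx]
        dist = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
        local = pam_kmedoids(dist, k_per_class, rng)
        medoid_ids[c] = idx[local]
        latents[c] = Z[local]
    return PrototypeSet(medoid_ids=medoid_ids, latents=latents, k_per_class=k_per_class)


def nearest_neighbors(
    results: FLANResults, data: EncodedDataset, query: int, k: int = 3
):
    """The ``k`` samples closest to ``query`` in the aggregate latent space.

    Distances are Euclidean; ties break deterministically by sample id.  A
    query that is itself in ``data`` ranks first at distance 0.
    """
    latent = results.encode(data)
    z_q = latent.aggregate[query]
    dist = np.linalg.norm(latent.aggregate - z_q[None], axis=1)
    if k > len(dist):
        warnings.warn(f"k={k} exceeds dataset size {len(dist)}; returning all")
        k = len(dist)
    order = np.lexsort((np.arange(len(dist)), dist))[:k]
    return order, dist[order]


# ---------------------------------------------------------------------- #
# post-hoc attribution baselines


def _embedded_logits(net, x_emb: np.ndarray):
    """Forward from the differentiable input space (see module docstring)."""
    n, N, d = x_emb.shape
    if net.kind == "numeric" and not net.shared:
        z_i, enc_cache = net.encoder.forward(x_emb)
    else:
        out, enc_cache = net.encoder.forward(x_emb.reshape(n * N, d))
        z_i = out.reshape(n, N, net.latent_dim)
    z = z_i.sum(axis=1)
    logits, psi_cache = net.psi_logits(z, with_cache=True)
    return logits, (enc_cache, psi_cache, (n, N))


def _embedded_gradient(net, x_emb: np.ndarray, class_idx: np.ndarray):
    """d logits[s, class_idx[s]] / d x_emb[s]."""
    logits, (enc_cache, psi_cache, (n, N)) = _embedded_logits(net, x_emb)
    grad_logits = np.zeros_like(logits)
    grad_logits[np.arange(n), class_idx] = 1.0
    if net.psi is not None:
        dz, _ = net.psi.backward(grad_logits, psi_cache)
    else:
        dz = grad_logits
    dz_i = np.broadcast_to(dz[:, None, :], (n, N, net.latent_dim))
    if net.kind == "numeric" and not net.shared:
        dx, _ = net.encoder.backward(dz_i.copy(), enc_cache)
    else:
        dx_flat, _ = net.encoder.backward(dz_i.reshape(n * N, -1).copy(), enc_cache)
        dx = dx_flat.reshape(n, N, -1)
    return dx, logits


def posthoc_scores(
    results: FLANResults,
    data: EncodedDataset,
    method: str,
    steps: int = 32,
    chunk: int = 256,
) -> np.ndarray:
    """Per-sample per-feature attribution scores, shape (n, N).

    ``saliency`` is the magnitude of the gradient of the predicted-class
    logit; ``input_x_gradient`` multiplies the (embedded) input elementwise
    by that gradient; ``integrated_gradients`` is the Riemann-sum path
    integral from a zero baseline.  Element scores are reduced per feature
    by taking the maximum within the feature.
    """
    if method not in POSTHOC_METHODS:
        raise ValueError(f"method must be one of {POSTHOC_METHODS}, got {method!r}")
    if method == "integrated_gradients" and steps < 1:
        raise ValueError("integrated_gradients requires steps >= 1")
    net = results.network
    out = []
    for start in range(0, len(data), chunk):
        feats = data.features[start : start + chunk]
        x = net.embedded_inputs(feats)
        logits, _ = _embedded_logits(net, x)
        target = logits.argmax(axis=1)
        if method == "saliency":
            grad, _ = _embedded_gradient(net, x, target)
            elem = np.abs(grad)
        elif method == "input_x_gradient":
            grad, _ = _embedded_gradient(net, x, target)
            elem = x * grad
        else:
            total = np.zeros_like(x)
            for j in range(steps):
                alpha = (j + 0.5) / steps  # midpoint rule; exact for linear nets
                grad, _ = _embedded_gradient(net, alpha * x, target)
                total += grad
            elem = x * total / steps
        out.append(elem.max(axis=2))
    return np.concatenate(out)


def latent_norm_scores(results: FLANResults, data: EncodedDataset) -> np.ndarray:
    """Native importance scores in the same (n, N) shape as posthoc_scores."""
    return results.encode(data).norms()
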