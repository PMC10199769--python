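"""Feature-wise latent additive network: model and results objects.

The classifier has the form

    f(x) = softmax( psi( sum_i phi_i(x_i) ) )

where each feature x_i (a column, column group, k-mer or image patch) is
mapped by its own encoder phi_i — or by one shared encoder phi(.; theta, p_i)
with a learned positional embedding p_i — into a common latent space of
dimension D, the per-feature latents are summed, and a predictor head psi
maps the sum to class logits.  Because each latent depends on one feature
only, the latents support native interpretation: per-feature predictions
psi(z_i), latent-norm importances ||z_i||, and example-based retrieval in
the latent space.

The public surface follows the model/results convention: build a
:class:`FLAN` from an :class:`~flan.grouping.EncodedDataset`, call
:meth:`FLAN.fit` with a :class:`TrainConfig`, and use the returned
:class:`FLANResults` for prediction, interpretation and evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .exceptions import (
    CheckpointError,
    DegenerateLabelsError,
    DivergenceError,
    InputShapeError,
    SpecValidationError,
)
from .grouping import EncodedDataset, FeatureSpec

CHECKPOINT_FORMAT_VERSION = "flan-checkpoint-1"

BALANCE_MODES = ("none", "class_weights", "smote")
PREDICTOR_KINDS = ("mlp", "linear", "identity")


@dataclass
class TrainConfig:
    """End-to-end training settings.

    ``sparsity_weight`` is the coefficient of the group-lasso style penalty
    ``mean_s sum_i ||z_i||_2`` that sparsifies the latent-norm feature
    importances; 0 recovers plain cross-entropy training.
    """

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0
    sparsity_weight: float = 0.0
    class_balance: str = "class_weights"
    seed: int = 0
    patience: int = 15
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.sparsity_weight < 0:
            raise SpecValidationError("sparsity_weight must be >= 0")
        if not 0.0 <= self.val_fraction <= 0.5:
            raise SpecValidationError("val_fraction must lie in [0, 0.5]")
        if self.class_balance not in BALANCE_MODES:
            raise SpecValidationError(
                f"class_balance must be one of {BALANCE_MODES}, got {self.class_balance!r}"
            )
        if self.optimizer not in nn.OPTIMIZERS:
            raise SpecValidationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class LatentBatch:
    """Per-feature latents z_i and their sum z for a batch of samples."""

    per_feature: np.ndarray  # (n, N, D)
    aggregate: np.ndarray  # (n, D)

    def partial_aggregate(self, i: int) -> np.ndarray:
        """z_* = sum over j != i of z_j."""
        return self.aggregate - self.per_feature[:, i, :]

    def norms(self) -> np.ndarray:
        """Euclidean norm of each per-feature latent, shape (n, N)."""
        return np.linalg.norm(self.per_feature, axis=2)


def aggregate(latent: LatentBatch) -> np.ndarray:
    """Feature-axis sum of the per-feature latents (permutation invariant)."""
    return latent.per_feature.sum(axis=1)


class FlanNetwork:
    """Parameter container and differentiable forward/backward pass.

    Three encoder layouts are supported:

    * ``independent`` — one :class:`~flan.nn.StackedMLP` holding N per-feature
      encoders (tabular modes);
    * ``shared-numeric`` — one shared MLP plus a learned positional table
      added to the raw feature vector (image patches);
    * ``token`` — a token-embedding table, a positional table added to the
      concatenated token embeddings of each feature, and a shared MLP.
    """

    def __init__(
        self,
        spec: FeatureSpec,
        latent_dim: int,
        n_classes: int,
        rng: np.random.Generator,
        encoder_hidden=(64, 64),
        predictor_hidden=(64, 64),
        predictor: str = "mlp",
        predictor_bias: bool = True,
        shared_encoder: Optional[bool] = None,
        embed_dim: int = 16,
    ):
        if predictor not in PREDICTOR_KINDS:
            raise SpecValidationError(f"predictor must be one of {PREDICTOR_KINDS}")
        if predictor == "identity" and latent_dim != n_classes:
            raise SpecValidationError(
                "identity predictor requires latent_dim == n_classes"
            )
        self.spec = spec
        self.latent_dim = int(latent_dim)
        self.n_classes = int(n_classes)
        self.embed_dim = int(embed_dim)
        self.predictor_kind = predictor
        if shared_encoder is None:
            shared_encoder = spec.uses_positions
        self.shared = bool(shared_encoder)
        self.kind = spec.kind

        N = spec.n_features
        d_in = max(spec.feature_input_dims)
        self.embed = None
        self.pos = None
        if self.kind == "token":
            V = len(spec.vocabulary)
            self.embed = rng.normal(0.0, 0.1, size=(V, self.embed_dim))
            feat_dim = spec.k * self.embed_dim
            self.pos = rng.normal(0.0, 0.1, size=(N, feat_dim))
            self.encoder = nn.MLP((feat_dim, *encoder_hidden, latent_dim), rng)
        elif self.shared:
            self.pos = rng.normal(0.0, 0.1, size=(N, d_in))
            self.encoder = nn.MLP((d_in, *encoder_hidden, latent_dim), rng)
        else:
            self.encoder = nn.StackedMLP(N, (d_in, *encoder_hidden, latent_dim), rng)

        if predictor == "identity":
            self.psi = None
        elif predictor == "linear":
            self.psi = nn.MLP((latent_dim, n_classes), rng, bias=predictor_bias)
        else:
            self.psi = nn.MLP(
                (latent_dim, *predictor_hidden, n_classes), rng, bias=predictor_bias
            )

    # ------------------------------------------------------------------ #
    # parameter plumbing

    @property
    def params(self) -> list:
        out = []
        if self.embed is not None:
            out.append(self.embed)
        if self.pos is not None:
            out.append(self.pos)
        out.extend(self.encoder.params)
        if self.psi is not None:
            out.extend(self.psi.params)
        return out

    def set_params(self, params: list) -> None:
        params = list(params)
        i = 0
        if self.embed is not None:
            self.embed = params[i]
            i += 1
        if self.pos is not None:
            self.pos = params[i]
            i += 1
        n_enc = len(self.encoder.params)
        self.encoder.set_params(params[i : i + n_enc])
        i += n_enc
        if self.psi is not None:
            self.psi.set_params(params[i:])

    def copy_params(self) -> list:
        return [p.copy() for p in self.params]

    # ------------------------------------------------------------------ #
    # forward

    def _check(self, ds: EncodedDataset) -> None:
        if ds.spec.mode != self.spec.mode or ds.spec.n_features != self.spec.n_features:
            raise InputShapeError(
                f"dataset spec ({ds.spec.mode}, N={ds.spec.n_features}) does not match "
                f"model spec ({self.spec.mode}, N={self.spec.n_features})"
            )

    def encode(self, features: np.ndarray, with_cache: bool = False):
        """Per-feature latents z_i, shape (n, N, D)."""
        n, N, d = features.shape
        cache = {}
        if self.kind == "token":
            ids = features.astype(np.int64)
            emb = self.embed[ids]  # (n, N, k, E)
            x = emb.reshape(n, N, -1) + self.pos[None]
            cache["token_ids"] = ids
            cache["emb_in"] = x
            out, enc_cache = self.encoder.forward(x.reshape(n * N, -1))
            z_i = out.reshape(n, N, self.latent_dim)
        elif self.shared:
            x = features + self.pos[None]
            cache["emb_in"] = x
            out, enc_cache = self.encoder.forward(x.reshape(n * N, -1))
            z_i = out.reshape(n, N, self.latent_dim)
        else:
            z_i, enc_cache = self.encoder.forward(features)
        cache["enc"] = enc_cache
        cache["shape"] = (n, N)
        return (z_i, cache) if with_cache else z_i

    def psi_logits(self, z: np.ndarray, with_cache: bool = False):
        """Predictor head on an aggregate (or single-feature) latent."""
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[None, :]
        if z.shape[-1] != self.latent_dim:
            raise InputShapeError(
                f"latent width {z.shape[-1]} does not match D={self.latent_dim}"
            )
        if self.psi is None:
            return (z, None) if with_cache else z
        out, cache = self.psi.forward(z)
        return (out, cache) if with_cache else out

    def forward(self, features: np.ndarray):
        """Full pass; returns (logits, cache) for use by :meth:`backward`."""
        z_i, cache = self.encode(features, with_cache=True)
        z = z_i.sum(axis=1)
        logits, psi_cache = self.psi_logits(z, with_cache=True)
        cache.update(z_i=z_i, z=z, psi=psi_cache)
        return logits, cache

    # ------------------------------------------------------------------ #
    # backward

    def backward(self, grad_logits: np.ndarray, cache, extra_grad_zi=None):
        """Gradients of a scalar loss w.r.t. params and inputs.

        ``extra_grad_zi`` (n, N, D) adds a direct gradient on the per-feature
        latents (used by the latent-norm sparsity penalty).

        Returns ``(grad_input, grads)`` where ``grad_input`` is the gradient
        w.r.t. the numeric feature array — for token models, w.r.t. the
        position-augmented embedded features — and ``grads`` aligns with
        :attr:`params`.
        """
        n, N = cache["shape"]
        if self.psi is not None:
            dz, psi_grads = self.psi.backward(grad_logits, cache["psi"])
        else:
            dz, psi_grads = grad_logits, []
        dz_i = np.broadcast_to(dz[:, None, :], cache["z_i"].shape).copy()
        if extra_grad_zi is not None:
            dz_i += extra_grad_zi

        grads = []
        if self.kind == "token":
            dx_flat, enc_grads = self.encoder.backward(
                dz_i.reshape(n * N, -1), cache["enc"]
            )
            dx = dx_flat.reshape(n, N, -1)
            pos_grad = dx.sum(axis=0)
            demb = dx.reshape(n, N, self.spec.k, self.embed_dim)
            embed_grad = np.zeros_like(self.embed)
            np.add.at(embed_grad, cache["token_ids"], demb)
            grads = [embed_grad, pos_grad] + enc_grads + psi_grads
            grad_input = dx
        elif self.shared:
            dx_flat, enc_grads = self.encoder.backward(
                dz_i.reshape(n * N, -1), cache["enc"]
            )
            dx = dx_flat.reshape(n, N, -1)
            pos_grad = dx.sum(axis=0)
            grads = [pos_grad] + enc_grads + psi_grads
            grad_input = dx
        else:
            dx, enc_grads = self.encoder.backward(dz_i, cache["enc"])
            grads = enc_grads + psi_grads
            grad_input = dx
        return grad_input, grads

    def input_gradients(self, features: np.ndarray, class_idx: np.ndarray):
        """d logit[s, class_idx[s]] / d input[s], one target logit per sample.

        For numeric models the gradient is w.r.t. the raw feature values;
        for token models it is taken at the embedding layer (token ids are
        discrete), i.e. w.r.t. the position-augmented embedded features.
        """
        logits, cache = self.forward(features)
        grad_logits = np.zeros_like(logits)
        grad_logits[np.arange(len(class_idx)), class_idx] = 1.0
        grad_input, _ = self.backward(grad_logits, cache)
        return grad_input, logits

    def embedded_inputs(self, features: np.ndarray) -> np.ndarray:
        """The array ``input_gradients`` differentiates against."""
        if self.kind == "token":
            n, N, _ = features.shape
            emb = self.embed[features.astype(np.int64)]
            return emb.reshape(n, N, -1) + self.pos[None]
        if self.shared:
            return features + self.pos[None]
        return features


def _smote(features: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
           k_neighbors: int = 5):
    """Minimal SMOTE: interpolate minority samples toward same-class neighbors
    until every class matches the majority count.  Numeric features only."""
    from sklearn.neighbors import NearestNeighbors

    n, N, d = features.shape
    flat = features.reshape(n, N * d)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    new_X, new_y = [flat], [labels]
    for c, cnt in zip(classes, counts):
        deficit = target - cnt
        if deficit == 0:
            continue
        Xc = flat[labels == c]
        k = min(k_neighbors, len(Xc) - 1)
        if k < 1:
            # single sample in the class: replicate it
            new_X.append(np.repeat(Xc, deficit, axis=0))
            new_y.append(np.full(deficit, c))
            continue
        nbrs = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nbrs.kneighbors(Xc)
        base = rng.integers(0, len(Xc), size=deficit)
        pick = idx[base, rng.integers(1, k + 1, size=deficit)]
        gap = rng.uniform(0, 1, size=(deficit, 1))
        synth = Xc[base] + gap * (Xc[pick] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(deficit, c))
    X = np.concatenate(new_X).reshape(-1, N, d)
    y = np.concatenate(new_y)
    return X, y


class FLAN:
    """Feature-wise latent additive network model.

    Parameters
    ----------
    data : EncodedDataset
        Labeled training data produced by the grouping functions.
    latent_dim : int
        Dimension D of the shared latent space.
    encoder_hidden, predictor_hidden : tuple of int
        Hidden-layer widths of the feature encoders and the predictor head.
        Empty tuples give single affine maps.
    predictor : {"mlp", "linear", "identity"}
        ``linear`` is a single (optionally bias-free) affine map; ``identity``
        uses the aggregate latent directly as logits (requires D == M).
    shared_encoder : bool, optional
        One shared encoder with positional embeddings instead of N
        independent encoders.  Defaults to True for sequence/patch specs and
        False for tabular specs.
    embed_dim : int
        Token-embedding width for sequence specs.
    """

    def __init__(
        self,
        data: EncodedDataset,
        *,
        latent_dim: int = 24,
        encoder_hidden: Sequence[int] = (64, 64),
        predictor_hidden: Sequence[int] = (64, 64),
        predictor: str = "mlp",
        predictor_bias: bool = True,
        shared_encoder: Optional[bool] = None,
        embed_dim: int = 16,
        n_classes: Optional[int] = None,
        seed: int = 0,
    ):
        if data.labels is None and n_classes is None:
            raise DegenerateLabelsError("labeled data or explicit n_classes required")
        self.data = data
        self.spec = data.spec
        if data.labels is not None:
            self.classes_ = np.unique(data.labels)
        else:
            self.classes_ = np.arange(n_classes)
        if n_classes is None:
            n_classes = len(self.classes_)
        self.n_classes = int(n_classes)
        self.hyperparams = dict(
            latent_dim=int(latent_dim),
            encoder_hidden=tuple(encoder_hidden),
            predictor_hidden=tuple(predictor_hidden),
            predictor=predictor,
            predictor_bias=bool(predictor_bias),
            shared_encoder=shared_encoder,
            embed_dim=int(embed_dim),
        )
        self.seed = int(seed)
        self.network = self.build_network(np.random.default_rng(seed))

    @classmethod
    def from_dataframe(cls, df, label_column: str, **kwargs) -> "FLAN":
        """Build a per-column tabular model from a pandas DataFrame."""
        from .grouping import encode_tabular

        cols = [c for c in df.columns if c != label_column]
        spec = FeatureSpec.tabular(len(cols), feature_names=cols)
        ds = encode_tabular(df[cols].to_numpy(float), spec, labels=df[label_column].to_numpy())
        return cls(ds, **kwargs)

    def build_network(self, rng: np.random.Generator) -> FlanNetwork:
        return FlanNetwork(
            self.spec, n_classes=self.n_classes, rng=rng, **self.hyperparams
        )

    def _encode_labels(self, labels: np.ndarray) -> np.ndarray:
        y = np.searchsorted(self.classes_, labels)
        if np.any(self.classes_[y] != labels):
            raise InputShapeError("labels outside the training classes")
        return y

    def as_results(self, network: Optional[FlanNetwork] = None) -> "FLANResults":
        """Wrap the (possibly untrained) network in a results object."""
        return FLANResults(self, network or self.network, config=None, history={})

    # ------------------------------------------------------------------ #

    def fit(self, config: Optional[TrainConfig] = None) -> "FLANResults":
        """Train end-to-end with minibatch cross-entropy (+ optional
        latent-norm sparsity penalty) and return a results object.

        All randomness (initialization, splitting, shuffling, oversampling)
        derives from ``config.seed``; on a single thread the training log is
        reproducible bit for bit.
        """
        cfg = config or TrainConfig()
        labels = self.data.labels
        if labels is None:
            raise DegenerateLabelsError("cannot fit without labels")
        y = self._encode_labels(labels)
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError("training data contains a single class")

        rng = np.random.default_rng(cfg.seed)
        net = self.build_network(rng)

        X = self.data.features
        if cfg.val_fraction > 0:
            from sklearn.model_selection import train_test_split

            idx_tr, idx_val = train_test_split(
                np.arange(len(X)),
                test_size=cfg.val_fraction,
                stratify=y,
                random_state=int(rng.integers(2**31 - 1)),
            )
        else:
            idx_tr, idx_val = np.arange(len(X)), None
        X_tr, y_tr = X[idx_tr], y[idx_tr]

        sample_weight = None
        if cfg.class_balance == "class_weights":
            counts = np.bincount(y_tr, minlength=self.n_classes).astype(float)
            w = np.where(counts > 0, len(y_tr) / (self.n_classes * np.maximum(counts, 1)), 0.0)
            sample_weight = w[y_tr]
        elif cfg.class_balance == "smote":
            if self.spec.kind != "numeric":
                raise SpecValidationError("smote balancing requires numeric features")
            X_tr, y_tr = _smote(X_tr, y_tr, rng)

        opt_cls = nn.OPTIMIZERS[cfg.optimizer]
        opt = opt_cls(net.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

        history = {"train_loss": [], "penalty": [], "val_loss": [], "val_accuracy": []}
        best_val, best_params, best_epoch, since_best = np.inf, None, -1, 0
        n_tr = len(X_tr)
        lam = cfg.sparsity_weight

        for epoch in range(cfg.epochs):
            order = rng.permutation(n_tr)
            ep_loss, ep_pen, n_batches = 0.0, 0.0, 0
            for start in range(0, n_tr, cfg.batch_size):
                b = order[start : start + cfg.batch_size]
                logits, cache = net.forward(X_tr[b])
                sw = None if sample_weight is None else sample_weight[b]
                loss, grad_logits = nn.cross_entropy(logits, y_tr[b], sw)
                extra = None
                if lam > 0:
                    z_i = cache["z_i"]
                    norms = np.linalg.norm(z_i, axis=2)
                    pen = lam * norms.sum(axis=1).mean()
                    safe = np.maximum(norms, 1e-12)[:, :, None]
                    extra = np.where(norms[:, :, None] > 1e-12, lam / len(b) * z_i / safe, 0.0)
                    ep_pen += pen
                    loss_total = loss + pen
                else:
                    loss_total = loss
                if not np.isfinite(loss_total):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}",
                        last_stable_params=best_params or net.copy_params(),
                        epoch=epoch,
                    )
                _, grads = net.backward(grad_logits, cache, extra_grad_zi=extra)
                opt.step(grads)
                ep_loss += loss
                n_batches += 1
            history["train_loss"].append(ep_loss / n_batches)
            history["penalty"].append(ep_pen / n_batches)

            if idx_val is not None and len(idx_val):
                logits_val = _chunked_logits(net, X[idx_val])
                val_loss, _ = nn.cross_entropy(logits_val, y[idx_val])
                val_acc = float((logits_val.argmax(1) == y[idx_val]).mean())
                history["val_loss"].append(float(val_loss))
                history["val_accuracy"].append(val_acc)
                monitor = val_loss
            else:
                monitor = history["train_loss"][-1]
            if monitor < best_val - 1e-9:
                best_val, best_params, best_epoch, since_best = (
                    monitor,
                    net.copy_params(),
                    epoch,
                    0,
                )
            else:
                since_best += 1
                if cfg.patience > 0 and since_best >= cfg.patience:
                    break

        if best_params is not None:
            net.set_params(best_params)
        history["best_epoch"] = best_epoch
        return FLANResults(self, net, config=cfg, history=history)


def _chunked_logits(net: FlanNetwork, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    out = []
    for start in range(0, len(X), chunk):
        z_i = net.encode(X[start : start + chunk])
        out.append(net.psi_logits(z_i.sum(axis=1)))
    return np.concatenate(out)


class FLANResults:
    """A fitted (or explicitly constructed) additive network.

    Carries the trained parameters, the training history and the
    configuration, and exposes prediction, encoding, interpretation and
    evaluation.  Interpretation methods delegate to :mod:`flan.interpret`,
    evaluation to :mod:`flan.evaluate`.
    """

    def __init__(self, model: FLAN, network: FlanNetwork, config, history):
        self.model = model
        self.network = network
        self.config = config
        self.history = history

    # ------------------------------------------------------------------ #
    # prediction

    @property
    def spec(self) -> FeatureSpec:
        return self.model.spec

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def encode(self, data: EncodedDataset) -> LatentBatch:
        """Per-feature latents and their aggregate for a dataset."""
        self.network._check(data)
        parts = []
        for start in range(0, len(data), 512):
            parts.append(self.network.encode(data.features[start : start + 512]))
        z_i = np.concatenate(parts)
        return LatentBatch(per_feature=z_i, aggregate=z_i.sum(axis=1))

    def predict_logits(self, data: EncodedDataset) -> np.ndarray:
        self.network._check(data)
        return _chunked_logits(self.network, data.features)

    def predict_proba(self, data: EncodedDataset) -> np.ndarray:
        """Class probabilities softmax(psi(sum_i phi_i(x_i)))."""
        return nn.softmax(self.predict_logits(data))

    def predict_proba_from_latent(self, z: np.ndarray) -> np.ndarray:
        """softmax(psi(z)) for an arbitrary latent (aggregate, partial sum,
        or a single feature's latent)."""
        return nn.softmax(self.network.psi_logits(z))

    def predict(self, data: EncodedDataset) -> np.ndarray:
        return self.classes_[self.predict_proba(data).argmax(axis=1)]

    def accuracy(self, data: EncodedDataset) -> float:
        if data.labels is None:
            raise DegenerateLabelsError("accuracy requires labels")
        return float((self.predict(data) == data.labels).mean())

    # ------------------------------------------------------------------ #
    # interpretation / evaluation delegates

    def feature_importance(self, data: EncodedDataset):
        from . import interpret

        return interpret.feature_importance(self, data)

    def global_importance(self, data: EncodedDataset, grouping="true_label",
                          normalization="per_feature_max"):
        from . import interpret

        return interpret.global_importance(self, data, grouping, normalization)

    def single_feature_prediction(self, data: EncodedDataset, sample: int, feature: int):
        from . import interpret

        return interpret.single_feature_prediction(self, data, sample, feature)

    def interpretation_report(self, data: EncodedDataset, sample: int, **kw):
        from . import interpret

        return interpret.interpretation_report(self, data, sample, **kw)

    def prototypes(self, data: EncodedDataset, k_per_class: int = 6, seed: int = 0):
        from . import interpret

        return interpret.prototypes(self, data, k_per_class=k_per_class, seed=seed)

    def nearest_neighbors(self, data: EncodedDataset, query: int, k: int = 3):
        from . import interpret

        return interpret.nearest_neighbors(self, data, query, k=k)

    def posthoc_scores(self, data: EncodedDataset, method: str, steps: int = 32):
        from . import interpret

        return interpret.posthoc_scores(self, data, method, steps=steps)

    def score_auc(self, data: EncodedDataset) -> float:
        from .evaluate import roc_auc

        if data.labels is None:
            raise DegenerateLabelsError("AUC requires labels")
        y = self.model._encode_labels(data.labels)
        return roc_auc(self.predict_proba(data), y)

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        """Plain-text summary of the architecture, fit and diagnostics."""
        hp = self.model.hyperparams
        lines = [
            "Feature-wise Latent Additive Network",
            "=" * 52,
            f"mode:             {self.spec.mode}",
            f"features (N):     {self.spec.n_features}",
            f"latent dim (D):   {hp['latent_dim']}",
            f"classes (M):      {self.model.n_classes}",
            f"encoder:          {'shared' if self.network.shared else 'per-feature'} "
            f"MLP hidden={hp['encoder_hidden']}",
            f"predictor:        {hp['predictor']} hidden={hp['predictor_hidden']}",
            f"parameters:       {sum(p.size for p in self.network.params)}",
        ]
        if self.config is not None:
            lines.append("-" * 52)
            lines.append(
                f"trained: epochs={len(self.history['train_loss'])} "
                f"(best={self.history.get('best_epoch')}), "
                f"seed={self.config.seed}, lambda={self.config.sparsity_weight}"
            )
            lines.append(f"final train loss: {self.history['train_loss'][-1]:.4f}")
            if self.history.get("val_loss"):
                lines.append(
                    f"best val loss:    {min(self.history['val_loss']):.4f}  "
                    f"val accuracy: {self.history['val_accuracy'][-1]:.4f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    # persistence

    def save(self, path) -> None:
        """Write a single-archive checkpoint (parameters + spec + config)."""
        meta = {
            "format": CHECKPOINT_FORMAT_VERSION,
            "spec": _spec_to_dict(self.spec),
            "hyperparams": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.model.hyperparams.items()
            },
            "n_classes": self.model.n_classes,
            "classes": np.asarray(self.model.classes_).tolist(),
            "config": None if self.config is None else asdict(self.config),
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.network.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "FLANResults":
        with np.load(path, allow_pickle=False) as archive:
            try:
                meta = json.loads(str(archive["meta"]))
            except KeyError:
                raise CheckpointError(f"{path} is not a flan checkpoint")
            if meta.get("format") != CHECKPOINT_FORMAT_VERSION:
                raise CheckpointError(
                    f"checkpoint format {meta.get('format')!r} is not "
                    f"{CHECKPOINT_FORMAT_VERSION!r}"
                )
            params = [
                archive[f"param_{i}"]
                for i in range(sum(1 for k in archive.files if k.startswith("param_")))
            ]
        spec = _spec_from_dict(meta["spec"])
        hp = meta["hyperparams"]
        hp["encoder_hidden"] = tuple(hp["encoder_hidden"])
        hp["predictor_hidden"] = tuple(hp["predictor_hidden"])
        n, N, d = 0, spec.n_features, max(spec.feature_input_dims)
        dummy = EncodedDataset(
            np.zeros((0, N, d), dtype=np.int64 if spec.kind == "token" else float),
            spec,
        )
        model = FLAN(dummy, n_classes=meta["n_classes"], **hp)
        model.classes_ = np.asarray(meta["classes"])
        model.network.set_params(params)
        cfg = None if meta["config"] is None else TrainConfig(**meta["config"])
        return cls(model, model.network, config=cfg, history={})


def _spec_to_dict(spec: FeatureSpec) -> dict:
    d = asdict(spec)
    return d


def _spec_from_dict(d: dict) -> FeatureSpec:
    d = dict(d)
    for key in ("feature_names", "vocabulary"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("group_definitions") is not None:
        d["group_definitions"] = tuple(tuple(g) for g in d["group_definitions"])
    return FeatureSpec(**d)
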