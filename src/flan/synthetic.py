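"""Synthetic tasks with planted, recoverable structure.

Three generators mirror the structural assumptions an additive network
exploits, one per input family, each with an exact oracle:

* tabular — features i.i.d. standard normal; the class-c logit is an
  additive combination sum_{i in S} w_{c,i} g_i(x_i) of per-feature effect
  functions over a planted informative set S, so the Bayes posterior is the
  softmax of the true logits in closed form;
* paired sequences — binding is a deterministic rule: label 1 iff a planted
  motif occurs in the receptor AND an anchor token occurs in the epitope;
  negatives are generated by knocking out exactly one or both conditions,
  so length-based heuristics carry no signal;
* images — class is determined solely by the mean color of a fixed
  contiguous blob of patches; background pixels are label-independent
  noise, and the ground-truth patch mask is returned for scoring
  importance maps.

Each generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .exceptions import SpecValidationError
from .grouping import (
    AMINO_ACIDS,
    FeatureSpec,
    encode_images,
    encode_sequence_pairs,
    encode_tabular,
)

# ---------------------------------------------------------------------- #
# tabular

#: Per-feature effect functions. ``quadratic`` and ``step`` are even /
#: non-monotone, so a linear model cannot represent them; ``sine`` at this
#: frequency is nearly uncorrelated with x under a standard normal.
EFFECT_LIBRARY = {
    "identity": lambda x: x,
    "quadratic": lambda x: x * x - 1.0,
    "sine": lambda x: np.sin(3.0 * x),
    "step": lambda x: np.sign(x),
}


@dataclass(frozen=True)
class SyntheticTabularSpec:
    """Additive-logit tabular task with known informative set S.

    Class-c logit = sum_{i in S} w_{c,i} g_i(x_i).  The weights assign each
    class an equally spaced response level (scaled by ``weight_scale``) in a
    per-feature random order, so every informative feature discriminates and
    the Bayes posterior is softmax of the true logits.
    """

    n_samples: int = 4000
    n_features: int = 20
    informative: tuple = (0, 1, 2, 3)
    effects: tuple = ("quadratic", "sine", "quadratic", "step")
    n_classes: int = 2
    weight_scale: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if len(self.informative) < 1:
            raise SpecValidationError("informative set S must be non-empty")
        if len(set(self.informative)) != len(self.informative):
            raise SpecValidationError("informative set has duplicates")
        if max(self.informative) >= self.n_features or min(self.informative) < 0:
            raise SpecValidationError("informative feature id out of range")
        if len(self.effects) != len(self.informative):
            raise SpecValidationError("one effect function per informative feature")
        for e in self.effects:
            if e not in EFFECT_LIBRARY:
                raise SpecValidationError(
                    f"unknown effect {e!r}; library: {sorted(EFFECT_LIBRARY)}"
                )
        if self.n_classes < 2:
            raise SpecValidationError("need at least two classes")


@dataclass
class TabularTask:
    """Generated samples plus the exact posterior oracle."""

    X: np.ndarray  # (n, N)
    y: np.ndarray  # (n,)
    weights: np.ndarray  # (M, |S|)
    spec: SyntheticTabularSpec
    posterior: Callable[[np.ndarray], np.ndarray]  # X -> (n, M) exact P(y|x)

    def feature_spec(self) -> FeatureSpec:
        names = [f"f{i}" for i in range(self.spec.n_features)]
        return FeatureSpec.tabular(self.spec.n_features, feature_names=names)

    def encoded(self, idx=None):
        X, y = (self.X, self.y) if idx is None else (self.X[idx], self.y[idx])
        return encode_tabular(X, self.feature_spec(), labels=y)

    def fresh_draw(self, n: int, seed: int) -> "TabularTask":
        """A new draw from the same population (same weights/effects)."""
        from dataclasses import replace

        return gen_tabular(replace(self.spec, n_samples=n, seed=seed), weights=self.weights)

    def write_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.spec.n_features)])
        df["label"] = self.y
        df.to_csv(path, index=False)


def _tabular_logits(X: np.ndarray, spec: SyntheticTabularSpec, weights: np.ndarray):
    logits = np.zeros((len(X), spec.n_classes))
    for j, (i, eff) in enumerate(zip(spec.informative, spec.effects)):
        g = EFFECT_LIBRARY[eff](X[:, i])
        logits += weights[:, j][None, :] * g[:, None]
    return logits


def gen_tabular(spec: SyntheticTabularSpec, weights: Optional[np.ndarray] = None) -> TabularTask:
    """Draw a labeled dataset and its exact Bayes-posterior oracle.

    Labels are sampled from the true posterior, so the Bayes AUC (the AUC of
    the oracle itself) is strictly below 1 and upper-bounds any classifier.
    """
    rng = np.random.default_rng(spec.seed)
    if weights is None:
        levels = np.linspace(-1.0, 1.0, spec.n_classes) * spec.weight_scale
        weights = np.empty((spec.n_classes, len(spec.informative)))
        for j in range(len(spec.informative)):
            weights[:, j] = levels[rng.permutation(spec.n_classes)]
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    logits = _tabular_logits(X, spec, weights)
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    y = (probs.cumsum(axis=1) > rng.uniform(size=(spec.n_samples, 1))).argmax(axis=1)

    def posterior(Xq: np.ndarray) -> np.ndarray:
        lq = _tabular_logits(np.asarray(Xq, dtype=float), spec, weights)
        p = np.exp(lq - lq.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    return TabularTask(X=X, y=y, weights=weights, spec=spec, posterior=posterior)


# ---------------------------------------------------------------------- #
# paired sequences


@dataclass(frozen=True)
class SyntheticSequenceSpec:
    """Paired-sequence binding task with a planted motif rule.

    A pair binds (label 1) iff ``motif`` occurs in the receptor AND the
    ``anchor`` token occurs in the epitope.  Negatives are drawn by knocking
    out the motif, the anchor, or both (uniformly), so roughly two thirds of
    the negatives still satisfy one of the two conditions.
    """

    n_samples: int = 1000
    receptor_length: Tuple[int, int] = (10, 18)  # inclusive range
    epitope_length: Tuple[int, int] = (8, 12)
    motif: str = "WKV"
    anchor: str = "H"
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.motif) > self.receptor_length[0] - 2:
            raise SpecValidationError(
                "motif must fit in the shortest receptor with room to spare"
            )
        if len(self.anchor) != 1:
            raise SpecValidationError("anchor must be a single token")
        for c in self.motif + self.anchor:
            if c not in AMINO_ACIDS:
                raise SpecValidationError(f"{c!r} is not an amino-acid letter")


@dataclass
class SequenceTask:
    receptors: list
    epitopes: list
    y: np.ndarray
    spec: SyntheticSequenceSpec

    def rule(self, receptor: str, epitope: str) -> int:
        """The planted ground-truth rule, evaluable on raw sequences."""
        return int(self.spec.motif in receptor and self.spec.anchor in epitope)

    def feature_spec(self, k: int = 1) -> FeatureSpec:
        max_a = self.spec.receptor_length[1] + 2
        max_b = self.spec.epitope_length[1] + 2
        return FeatureSpec.sequence_pair(max_length_a=max_a, max_length_b=max_b, k=k)

    def encoded(self, k: int = 1, idx=None):
        fs = self.feature_spec(k)
        if idx is None:
            a, b, y = self.receptors, self.epitopes, self.y
        else:
            a = [self.receptors[i] for i in idx]
            b = [self.epitopes[i] for i in idx]
            y = self.y[idx]
        return encode_sequence_pairs(a, b, fs, labels=y)

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"seq_a": self.receptors, "seq_b": self.epitopes, "label": self.y}
        ).to_csv(path, sep="\t", index=False)

    def write_fasta(self, path_a, path_b, path_labels) -> None:
        import pandas as pd

        with open(path_a, "w") as fa, open(path_b, "w") as fb:
            for i, (a, b) in enumerate(zip(self.receptors, self.epitopes)):
                fa.write(f">pair{i}\n{a}\n")
                fb.write(f">pair{i}\n{b}\n")
        pd.DataFrame(
            {"id": [f"pair{i}" for i in range(len(self.y))], "label": self.y}
        ).to_csv(path_labels, sep="\t", index=False)


def _random_seq(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))


def _knockout(seq: str, token_or_motif: str, rng) -> str:
    """Mutate characters until the pattern no longer occurs."""
    while token_or_motif in seq:
        pos = seq.index(token_or_motif) + len(token_or_motif) // 2
        replacement = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        while replacement == seq[pos]:
            replacement = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        seq = seq[:pos] + replacement + seq[pos + 1 :]
    return seq


def gen_sequences(spec: SyntheticSequenceSpec) -> SequenceTask:
    """Generate labeled receptor/epitope pairs consistent with the rule."""
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_samples * spec.positive_fraction))
    receptors, epitopes, labels = [], [], []
    for s in range(spec.n_samples):
        positive = s < n_pos
        la = rng.integers(spec.receptor_length[0], spec.receptor_length[1] + 1)
        lb = rng.integers(spec.epitope_length[0], spec.epitope_length[1] + 1)
        a, b = _random_seq(rng, la), _random_seq(rng, lb)
        if positive:
            p = rng.integers(0, la - len(spec.motif) + 1)
            a = a[:p] + spec.motif + a[p + len(spec.motif) :]
            if spec.anchor not in b:
                q = rng.integers(0, lb)
                b = b[:q] + spec.anchor + b[q + 1 :]
        else:
            mode = rng.integers(0, 3)  # 0: kill motif, 1: kill anchor, 2: kill both
            if mode in (0, 2):
                a = _knockout(a, spec.motif, rng)
            else:  # ensure motif present so the negative is non-trivial
                if spec.motif not in a:
                    p = rng.integers(0, la - len(spec.motif) + 1)
                    a = a[:p] + spec.motif + a[p + len(spec.motif) :]
            if mode in (1, 2):
                b = _knockout(b, spec.anchor, rng)
            else:
                if spec.anchor not in b:
                    q = rng.integers(0, lb)
                    b = b[:q] + spec.anchor + b[q + 1 :]
        receptors.append(a)
        epitopes.append(b)
        labels.append(int(spec.motif in a and spec.anchor in b))
    order = rng.permutation(spec.n_samples)
    task = SequenceTask(
        receptors=[receptors[i] for i in order],
        epitopes=[epitopes[i] for i in order],
        y=np.asarray(labels)[order],
        spec=spec,
    )
    return task


# ---------------------------------------------------------------------- #
# images


#: Well separated RGB class colors (supports up to 8 classes).
CLASS_COLORS = np.array(
    [
        [0.95, 0.15, 0.15],
        [0.15, 0.95, 0.15],
        [0.15, 0.15, 0.95],
        [0.90, 0.90, 0.10],
        [0.90, 0.10, 0.90],
        [0.10, 0.90, 0.90],
        [0.90, 0.55, 0.10],
        [0.65, 0.65, 0.65],
    ]
)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Blob-classification task: class = color of a fixed patch blob.

    ``distractor_patches`` hold a second, visually salient blob whose color
    is drawn uniformly at random *per sample*, independent of the label —
    structure that input-magnitude-driven attribution can mistake for
    evidence while carrying no class information.
    """

    n_samples: int = 2000
    height: int = 28
    width: int = 28
    channels: int = 3
    patch_side: int = 4
    blob_patches: tuple = ((2, 2), (2, 3), (3, 2), (3, 3))  # (row, col) in patch grid
    distractor_patches: tuple = ((5, 4), (5, 5))
    n_classes: int = 4
    noise: float = 0.10
    background: float = 0.5
    seed: int = 0

    def __post_init__(self):
        gh, gw = self.height // self.patch_side, self.width // self.patch_side
        if self.height % self.patch_side or self.width % self.patch_side:
            raise SpecValidationError("image dimensions must be divisible by patch_side")
        for r, c in self.blob_patches + self.distractor_patches:
            if not (0 <= r < gh and 0 <= c < gw):
                raise SpecValidationError(
                    f"blob patch {(r, c)} outside the {gh}x{gw} patch grid"
                )
        if set(self.blob_patches) & set(self.distractor_patches):
            raise SpecValidationError("blob and distractor patches overlap")
        if self.n_classes > len(CLASS_COLORS):
            raise SpecValidationError(f"at most {len(CLASS_COLORS)} classes supported")
        if self.channels != 3:
            raise SpecValidationError("color-coded classes require 3 channels")


@dataclass
class ImageTask:
    images: np.ndarray  # (n, H, W, C) in [0, 1] before noise clipping
    y: np.ndarray
    blob_feature_ids: np.ndarray  # flat patch indices of the blob
    pixel_mask: np.ndarray  # (H, W) bool
    spec: SyntheticImageSpec

    def feature_spec(self) -> FeatureSpec:
        s = self.spec
        return FeatureSpec.image(s.height, s.width, s.channels, s.patch_side)

    def encoded(self, idx=None):
        imgs, y = (self.images, self.y) if idx is None else (self.images[idx], self.y[idx])
        return encode_images(imgs, self.feature_spec(), labels=y)

    def rule_classify(self, images: np.ndarray) -> np.ndarray:
        """Oracle: nearest class color to the blob's mean color."""
        blob = images[:, self.pixel_mask, :]  # (n, npix, C)
        means = blob.mean(axis=1)  # (n, C)
        colors = CLASS_COLORS[: self.spec.n_classes]
        d = np.linalg.norm(means[:, None, :] - colors[None], axis=2)
        return d.argmin(axis=1)

    def write_png_dir(self, directory, manifest_name="labels.tsv") -> None:
        import os

        import pandas as pd
        from PIL import Image

        os.makedirs(directory, exist_ok=True)
        names = []
        for i, img in enumerate(self.images):
            arr = np.clip(img * 255, 0, 255).astype(np.uint8)
            name = f"img{i:05d}.png"
            Image.fromarray(arr).save(os.path.join(directory, name))
            names.append(name)
        pd.DataFrame({"file": names, "label": self.y}).to_csv(
            os.path.join(directory, manifest_name), sep="\t", index=False
        )

    def write_npz(self, path) -> None:
        np.savez(path, images=self.images, labels=self.y)


def gen_images(spec: SyntheticImageSpec) -> ImageTask:
    """Generate blob-coded images, their labels and the ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    n, h, w, c = spec.n_samples, spec.height, spec.width, spec.channels
    ps = spec.patch_side
    gw = w // ps
    y = rng.integers(0, spec.n_classes, size=n)
    images = np.full((n, h, w, c), spec.background)
    images += spec.noise * rng.standard_normal((n, h, w, c))
    pixel_mask = np.zeros((h, w), dtype=bool)
    for r, col in spec.blob_patches:
        pixel_mask[r * ps : (r + 1) * ps, col * ps : (col + 1) * ps] = True
    colors = CLASS_COLORS[y]  # (n, C)
    blob_noise = spec.noise * rng.standard_normal((n, pixel_mask.sum(), c))
    images[:, pixel_mask, :] = colors[:, None, :] + blob_noise
    if spec.distractor_patches:
        dmask = np.zeros((h, w), dtype=bool)
        for r, col in spec.distractor_patches:
            dmask[r * ps : (r + 1) * ps, col * ps : (col + 1) * ps] = True
        dcolors = rng.uniform(0.0, 1.0, size=(n, c))  # label-independent
        dnoise = spec.noise * rng.standard_normal((n, dmask.sum(), c))
        images[:, dmask, :] = dcolors[:, None, :] + dnoise
    np.clip(images, 0.0, 1.0, out=images)
    blob_ids = np.asarray([r * gw + col for r, col in spec.blob_patches])
    return ImageTask(
        images=images, y=y, blob_feature_ids=blob_ids, pixel_mask=pixel_mask, spec=spec
    )
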