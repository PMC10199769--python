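"""Decomposition of raw inputs into ordered, non-overlapping features.

A feature-wise additive network acts on an *ordered list of N disjoint
features* rather than on a monolithic input.  This module owns that
decomposition for the three supported input families:

* tabular rows — one feature per column (``per_column``) or one feature per
  declared column group (``column_groups``);
* token sequences — amino-acid strings encoded with START/STOP markers and
  PAD-padding to a fixed length, optionally re-grouped into non-overlapping
  k-mers (stride k);
* images — split into non-overlapping square patches, ordered row-major
  from the top-left corner.

Every grouping is lossless: the inverse ``ungroup_*`` functions reassemble
the raw input exactly (up to PAD completion of a trailing partial k-mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    InputShapeError,
    SequenceTooLongError,
    SpecValidationError,
    VocabularyError,
)

PAD, START, STOP = "<PAD>", "<START>", "<STOP>"
RESERVED_TOKENS = (PAD, START, STOP)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Default sequence vocabulary: reserved tokens first, so PAD always has id 0.
AA_VOCAB = RESERVED_TOKENS + AMINO_ACIDS

MODES = ("per_column", "column_groups", "kmer", "image_patch")


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of how a raw input decomposes into features.

    Use the constructors :meth:`tabular`, :meth:`grouped`,
    :meth:`sequence_pair` and :meth:`image` rather than ``__init__``.
    """

    mode: str
    n_features: int
    feature_names: tuple = ()
    # tabular modes
    group_definitions: Optional[tuple] = None  # tuple of tuples of column ids
    n_columns: Optional[int] = None
    # sequence modes
    k: int = 1
    max_length_a: Optional[int] = None
    max_length_b: Optional[int] = None
    vocabulary: Optional[tuple] = None
    # image mode
    patch_side: Optional[int] = None
    height: Optional[int] = None
    width: Optional[int] = None
    channels: Optional[int] = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise SpecValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.n_features < 1:
            raise SpecValidationError("spec must declare at least one feature")
        if self.feature_names and len(self.feature_names) != self.n_features:
            raise SpecValidationError(
                f"{len(self.feature_names)} feature names for {self.n_features} features"
            )
        if self.mode == "column_groups":
            self._validate_groups()
        if self.mode == "kmer":
            if self.k < 1:
                raise SpecValidationError(f"k must be a positive integer, got {self.k}")
            self._validate_vocab()
        if self.mode == "image_patch":
            ps = self.patch_side
            if ps is None or ps < 1:
                raise SpecValidationError("image_patch requires a positive patch_side")
            if self.height % ps or self.width % ps:
                raise SpecValidationError(
                    f"image dimensions {self.height}x{self.width} not divisible by "
                    f"patch_side {ps}; silent padding would change patch semantics"
                )

    def _validate_groups(self):
        groups = self.group_definitions
        if not groups:
            raise SpecValidationError("column_groups mode requires group_definitions")
        seen = set()
        for g in groups:
            if not g:
                raise SpecValidationError("empty column group")
            overlap = seen.intersection(g)
            if overlap:
                raise SpecValidationError(f"overlapping column groups: columns {sorted(overlap)}")
            seen.update(g)
        if seen != set(range(self.n_columns)):
            missing = sorted(set(range(self.n_columns)) - seen)
            raise SpecValidationError(
                f"group_definitions must cover all {self.n_columns} columns; missing {missing}"
            )

    def _validate_vocab(self):
        vocab = self.vocabulary
        if vocab is None:
            raise SpecValidationError("sequence specs require a vocabulary")
        for tok in RESERVED_TOKENS:
            if list(vocab).count(tok) != 1:
                raise SpecValidationError(f"vocabulary must contain {tok} exactly once")
        if len(set(vocab)) != len(vocab):
            raise SpecValidationError("vocabulary contains duplicate tokens")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def tabular(cls, n_columns: int, feature_names: Sequence[str] = ()) -> "FeatureSpec":
        """One scalar feature per column, in column order."""
        return cls(
            mode="per_column",
            n_features=n_columns,
            n_columns=n_columns,
            feature_names=tuple(feature_names),
        )

    @classmethod
    def grouped(
        cls,
        group_definitions: Sequence[Sequence[int]],
        n_columns: int,
        feature_names: Sequence[str] = (),
    ) -> "FeatureSpec":
        """One vector feature per declared group of columns."""
        groups = tuple(tuple(int(i) for i in g) for g in group_definitions)
        return cls(
            mode="column_groups",
            n_features=len(groups),
            group_definitions=groups,
            n_columns=n_columns,
            feature_names=tuple(feature_names),
        )

    @classmethod
    def sequence_pair(
        cls,
        max_length_a: int = 150,
        max_length_b: int = 50,
        k: int = 1,
        vocabulary: Sequence[str] = AA_VOCAB,
    ) -> "FeatureSpec":
        """Paired sequences (receptor then epitope), each START/STOP-marked and
        PAD-padded to its fixed length, concatenated into one feature list with
        a single global position index, then grouped into k-mers (stride k)."""
        total = max_length_a + max_length_b
        n = -(-max_length_a // k) + -(-max_length_b // k)  # ceil-div per sequence
        spec = cls(
            mode="kmer",
            n_features=n,
            k=k,
            max_length_a=max_length_a,
            max_length_b=max_length_b,
            vocabulary=tuple(vocabulary),
            feature_names=tuple(f"pos{j * k}" for j in range(n)),
        )
        assert total >= 0
        return spec

    @classmethod
    def image(
        cls, height: int, width: int, channels: int, patch_side: int
    ) -> "FeatureSpec":
        gh, gw = height // patch_side, width // patch_side
        names = tuple(f"patch_r{r}c{c}" for r in range(gh) for c in range(gw))
        return cls(
            mode="image_patch",
            n_features=gh * gw,
            patch_side=patch_side,
            height=height,
            width=width,
            channels=channels,
            feature_names=names,
        )

    # ------------------------------------------------------------------ #

    @property
    def kind(self) -> str:
        """'numeric' (float vector features) or 'token' (integer token ids)."""
        return "token" if self.mode == "kmer" else "numeric"

    @property
    def feature_input_dims(self) -> tuple:
        """Raw input width of each feature (before any embedding)."""
        if self.mode == "per_column":
            return (1,) * self.n_features
        if self.mode == "column_groups":
            return tuple(len(g) for g in self.group_definitions)
        if self.mode == "image_patch":
            return (self.patch_side * self.patch_side * self.channels,) * self.n_features
        return (self.k,) * self.n_features  # token ids per k-mer

    @property
    def uses_positions(self) -> bool:
        return self.mode in ("kmer", "image_patch")

    def token_id(self, token: str) -> int:
        try:
            return self.vocabulary.index(token)
        except ValueError:
            raise VocabularyError(f"token {token!r} not in vocabulary") from None

    @property
    def pad_id(self) -> int:
        return self.token_id(PAD)

    def names(self) -> tuple:
        if self.feature_names:
            return self.feature_names
        return tuple(f"f{i}" for i in range(self.n_features))

    def restrict(self, kept: Sequence[int]) -> "FeatureSpec":
        """Spec covering only the features in ``kept`` (tabular modes).

        Used by remove-and-retrain: the restricted model sees a fresh
        contiguous column layout.
        """
        kept = list(kept)
        if not kept:
            raise SpecValidationError("kept feature set must be non-empty")
        if sorted(set(kept)) != sorted(kept):
            raise SpecValidationError("kept feature ids must be unique")
        if min(kept) < 0 or max(kept) >= self.n_features:
            raise SpecValidationError("kept feature id out of range")
        names = [self.names()[i] for i in kept]
        if self.mode == "per_column":
            return FeatureSpec.tabular(len(kept), feature_names=names)
        if self.mode == "column_groups":
            dims = [len(self.group_definitions[i]) for i in kept]
            groups, start = [], 0
            for d in dims:
                groups.append(tuple(range(start, start + d)))
                start += d
            return FeatureSpec.grouped(groups, n_columns=start, feature_names=names)
        raise SpecValidationError(
            f"restrict is defined for tabular modes, not {self.mode!r}"
        )


@dataclass
class EncodedSample:
    """One input decomposed into its ordered feature list.

    ``features`` is a list of N numpy arrays: float vectors for numeric
    modes, integer token-id vectors for token modes.  ``positions`` are the
    flat positional indices 0..N-1 for ordered modes, None for per-column
    tabular data.
    """

    features: list
    positions: Optional[np.ndarray]
    label: Optional[int] = None
    spec: Optional[FeatureSpec] = None


@dataclass
class EncodedDataset:
    """A batch of encoded samples in dense layout.

    ``features`` has shape (n, N, d): float for numeric specs (features
    whose raw width is below d are zero-padded on the right; the true
    widths live in ``spec.feature_input_dims``), integer token ids for
    token specs (d == k).
    """

    features: np.ndarray
    spec: FeatureSpec
    labels: Optional[np.ndarray] = None
    positions: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.features.ndim != 3:
            raise InputShapeError(f"features must be (n, N, d); got {self.features.shape}")
        if self.features.shape[1] != self.spec.n_features:
            raise InputShapeError(
                f"dataset has {self.features.shape[1]} features, spec declares "
                f"{self.spec.n_features}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.features):
                raise InputShapeError("labels and features disagree on sample count")
        if self.positions is None and self.spec.uses_positions:
            self.positions = np.arange(self.spec.n_features)

    def __len__(self):
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.spec.n_features

    def subset(self, idx) -> "EncodedDataset":
        labels = None if self.labels is None else self.labels[idx]
        return EncodedDataset(self.features[idx], self.spec, labels, self.positions)

    def restrict_features(self, kept: Sequence[int]) -> "EncodedDataset":
        """Keep only the listed features (tabular modes), renumbering them."""
        new_spec = self.spec.restrict(kept)
        feats = self.features[:, list(kept), :]
        return EncodedDataset(feats, new_spec, self.labels)


# ---------------------------------------------------------------------- #
# single-sample grouping operations


def group_tabular(row: np.ndarray, spec: FeatureSpec) -> EncodedSample:
    """Split a numeric row into per-column or per-group features."""
    row = np.asarray(row, dtype=float).ravel()
    if spec.mode not in ("per_column", "column_groups"):
        raise SpecValidationError(f"group_tabular expects a tabular spec, got {spec.mode!r}")
    if row.shape[0] != spec.n_columns:
        raise InputShapeError(f"row has {row.shape[0]} columns, spec covers {spec.n_columns}")
    if spec.mode == "per_column":
        feats = [row[i : i + 1].copy() for i in range(spec.n_columns)]
    else:
        feats = [row[list(g)].copy() for g in spec.group_definitions]
    return EncodedSample(features=feats, positions=None, spec=spec)


def ungroup_tabular(sample: EncodedSample, spec: FeatureSpec) -> np.ndarray:
    """Inverse of :func:`group_tabular`: reassemble the raw row."""
    if spec.mode == "per_column":
        return np.concatenate(sample.features)
    row = np.empty(spec.n_columns)
    for g, f in zip(spec.group_definitions, sample.features):
        row[list(g)] = f
    return row


def encode_sequence(seq: str, max_length: int, vocab: Sequence[str] = AA_VOCAB) -> list:
    """Encode an amino-acid string as ``[START] + tokens + [STOP] + PAD...``.

    The output has length exactly ``max_length``; a sequence longer than
    ``max_length - 2`` is an error, never a silent truncation.
    """
    vocab = list(vocab)
    if len(seq) > max_length - 2:
        raise SequenceTooLongError(
            f"sequence of length {len(seq)} does not fit in {max_length} "
            f"positions with START/STOP markers"
        )
    index = {t: i for i, t in enumerate(vocab)}
    try:
        body = [index[c] for c in seq]
    except KeyError as e:
        raise VocabularyError(f"character {e.args[0]!r} not in vocabulary") from None
    ids = [index[START]] + body + [index[STOP]]
    ids += [index[PAD]] * (max_length - len(ids))
    return ids


def decode_sequence(ids: Sequence[int], vocab: Sequence[str] = AA_VOCAB) -> str:
    """Inverse of :func:`encode_sequence` (drops markers and padding)."""
    vocab = list(vocab)
    toks = [vocab[i] for i in ids]
    out = []
    for t in toks:
        if t in (START, PAD):
            continue
        if t == STOP:
            break
        out.append(t)
    return "".join(out)


def group_kmers(token_ids: Sequence[int], k: int, pad_id: int = 0) -> EncodedSample:
    """Group a token-id list into non-overlapping k-mers (stride k).

    A trailing remainder shorter than k is completed with PAD so the
    grouping stays lossless and N is deterministic.
    """
    if k < 1:
        raise SpecValidationError(f"k must be a positive integer, got {k}")
    ids = list(token_ids)
    if len(ids) < k:
        raise InputShapeError(f"token list of length {len(ids)} is shorter than k={k}")
    n = -(-len(ids) // k)
    ids += [pad_id] * (n * k - len(ids))
    feats = [np.array(ids[j * k : (j + 1) * k], dtype=np.int64) for j in range(n)]
    return EncodedSample(features=feats, positions=np.arange(n))


def ungroup_kmers(sample: EncodedSample, original_length: Optional[int] = None) -> list:
    """Concatenate k-mer features back into a flat token list."""
    ids = list(np.concatenate(sample.features))
    if original_length is not None:
        ids = ids[:original_length]
    return ids


def group_patches(image: np.ndarray, patch_side: int) -> EncodedSample:
    """Split an H×W×C image into flattened non-overlapping square patches.

    Patches are ordered row-major with the origin at the top-left; each
    feature is the patch flattened to length ``patch_side**2 * C``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise InputShapeError(f"expected an H×W×C image, got shape {image.shape}")
    h, w, c = image.shape
    if h % patch_side or w % patch_side:
        raise SpecValidationError(
            f"image {h}x{w} not divisible by patch_side {patch_side}"
        )
    gh, gw = h // patch_side, w // patch_side
    # (gh, ps, gw, ps, c) -> (gh, gw, ps, ps, c) -> (gh*gw, ps*ps*c)
    patches = (
        image.reshape(gh, patch_side, gw, patch_side, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(gh * gw, patch_side * patch_side * c)
    )
    feats = [patches[i].copy() for i in range(gh * gw)]
    return EncodedSample(features=feats, positions=np.arange(gh * gw))


def ungroup_patches(
    sample: EncodedSample, height: int, width: int, channels: int, patch_side: int
) -> np.ndarray:
    """Inverse of :func:`group_patches`."""
    gh, gw = height // patch_side, width // patch_side
    patches = np.stack(sample.features).reshape(gh, gw, patch_side, patch_side, channels)
    return patches.transpose(0, 2, 1, 3, 4).reshape(height, width, channels)


# ---------------------------------------------------------------------- #
# dataset-level encoders (dense layout)


def encode_tabular(X: np.ndarray, spec: FeatureSpec, labels=None) -> EncodedDataset:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_columns:
        raise InputShapeError(
            f"expected (n, {spec.n_columns}) matrix, got {X.shape}"
        )
    dims = spec.feature_input_dims
    d = max(dims)
    n = X.shape[0]
    feats = np.zeros((n, spec.n_features, d))
    if spec.mode == "per_column":
        feats[:, :, 0] = X
    else:
        for i, g in enumerate(spec.group_definitions):
            feats[:, i, : len(g)] = X[:, list(g)]
    return EncodedDataset(feats, spec, labels)


def encode_sequence_pairs(
    seqs_a: Sequence[str], seqs_b: Sequence[str], spec: FeatureSpec, labels=None
) -> EncodedDataset:
    """Encode paired sequences: receptor then epitope, one global position index."""
    if len(seqs_a) != len(seqs_b):
        raise InputShapeError("paired sequence lists differ in length")
    pad = spec.pad_id
    rows = []
    for a, b in zip(seqs_a, seqs_b):
        ids = encode_sequence(a, spec.max_length_a, spec.vocabulary) + encode_sequence(
            b, spec.max_length_b, spec.vocabulary
        )
        # k-mers are taken within each sequence (ceil-div per sequence in the
        # spec constructor); since both fixed lengths are padded, grouping the
        # concatenation is equivalent when k divides max_length_a.
        sample = group_kmers(ids, spec.k, pad_id=pad)
        if len(sample.features) != spec.n_features:
            # k does not divide max_length_a: group each sequence separately
            sa = group_kmers(ids[: spec.max_length_a], spec.k, pad_id=pad)
            sb = group_kmers(ids[spec.max_length_a :], spec.k, pad_id=pad)
            feats = sa.features + sb.features
        else:
            feats = sample.features
        rows.append(np.stack(feats))
    features = np.stack(rows).astype(np.int64)
    return EncodedDataset(features, spec, labels)


def encode_images(images: np.ndarray, spec: FeatureSpec, labels=None) -> EncodedDataset:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[..., None]
    n, h, w, c = images.shape
    if (h, w, c) != (spec.height, spec.width, spec.channels):
        raise InputShapeError(
            f"images of shape {(h, w, c)} do not match spec "
            f"{(spec.height, spec.width, spec.channels)}"
        )
    ps = spec.patch_side
    gh, gw = h // ps, w // ps
    feats = (
        images.reshape(n, gh, ps, gw, ps, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, gh * gw, ps * ps * c)
    )
    return EncodedDataset(feats, spec, labels)
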