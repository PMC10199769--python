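"""Readers for the supported on-disk formats, and run manifests.

Formats:

* tabular — CSV/TSV with a header row of feature names and a designated
  label column;
* paired sequences — TSV with columns ``seq_a``, ``seq_b``, ``label``, or
  two FASTA files plus a label TSV keyed by record id;
* images — a directory of PNGs with a label manifest TSV (columns ``file``,
  ``label``), or a single ``.npz`` archive with ``images`` and ``labels``.

Feature names from tabular headers are carried through to importance
reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import InputShapeError
from .grouping import (
    FeatureSpec,
    EncodedDataset,
    encode_images,
    encode_sequence_pairs,
    encode_tabular,
)


def read_tabular(path, label_column: str = "label", sep=None) -> EncodedDataset:
    """Read a CSV/TSV table into a per-column encoded dataset."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise InputShapeError(f"label column {label_column!r} not in {list(df.columns)}")
    cols = [c for c in df.columns if c != label_column]
    spec = FeatureSpec.tabular(len(cols), feature_names=cols)
    return encode_tabular(df[cols].to_numpy(float), spec, labels=df[label_column].to_numpy())


def read_sequence_tsv(path, spec: Optional[FeatureSpec] = None, k: int = 1,
                      max_length_a: Optional[int] = None,
                      max_length_b: Optional[int] = None) -> EncodedDataset:
    """Read paired sequences from a TSV with columns seq_a, seq_b, label."""
    df = pd.read_csv(path, sep="\t")
    for col in ("seq_a", "seq_b", "label"):
        if col not in df.columns:
            raise InputShapeError(f"sequence TSV must have a {col!r} column")
    if spec is None:
        la = max_length_a or int(df.seq_a.str.len().max()) + 2
        lb = max_length_b or int(df.seq_b.str.len().max()) + 2
        spec = FeatureSpec.sequence_pair(max_length_a=la, max_length_b=lb, k=k)
    return encode_sequence_pairs(
        df.seq_a.tolist(), df.seq_b.tolist(), spec, labels=df.label.to_numpy()
    )


def _read_fasta(path) -> dict:
    records, rid, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if rid is not None:
                    records[rid] = "".join(chunks)
                rid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if rid is not None:
        records[rid] = "".join(chunks)
    return records


def read_sequence_fasta(path_a, path_b, labels_tsv,
                        spec: Optional[FeatureSpec] = None, k: int = 1) -> EncodedDataset:
    """Read paired sequences from two FASTA files and a label TSV (id, label)."""
    rec_a, rec_b = _read_fasta(path_a), _read_fasta(path_b)
    labels = pd.read_csv(labels_tsv, sep="\t")
    ids = labels["id"].astype(str).tolist()
    missing = [i for i in ids if i not in rec_a or i not in rec_b]
    if missing:
        raise InputShapeError(f"records missing from FASTA files: {missing[:5]}")
    seqs_a = [rec_a[i] for i in ids]
    seqs_b = [rec_b[i] for i in ids]
    if spec is None:
        la = max(map(len, seqs_a)) + 2
        lb = max(map(len, seqs_b)) + 2
        spec = FeatureSpec.sequence_pair(max_length_a=la, max_length_b=lb, k=k)
    return encode_sequence_pairs(seqs_a, seqs_b, spec, labels=labels["label"].to_numpy())


def read_images(path, patch_side: int = 4, manifest: str = "labels.tsv") -> EncodedDataset:
    """Read images from an ``.npz`` archive or a PNG directory with manifest."""
    if str(path).endswith(".npz"):
        with np.load(path) as archive:
            images, labels = archive["images"], archive["labels"]
    else:
        from PIL import Image

        table = pd.read_csv(os.path.join(path, manifest), sep="\t")
        images = np.stack(
            [
                np.asarray(Image.open(os.path.join(path, f)), dtype=float) / 255.0
                for f in table["file"]
            ]
        )
        labels = table["label"].to_numpy()
    if images.ndim == 3:
        images = images[..., None]
    n, h, w, c = images.shape
    spec = FeatureSpec.image(h, w, c, patch_side)
    return encode_images(images, spec, labels=labels)


# ---------------------------------------------------------------------- #
# run manifests


def file_fingerprint(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            digest.update(block)
    return digest.hexdigest()


def write_manifest(path, *, command: str, config: dict, seed: int,
                   data_files: dict, outputs: dict, metrics: dict) -> None:
    """One manifest per CLI run: config snapshot, seeds, data hashes, metrics."""
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "data_fingerprints": {
            name: file_fingerprint(p) for name, p in data_files.items() if os.path.exists(p)
        },
        "outputs": outputs,
        "metrics": metrics,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
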