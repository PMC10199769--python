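"""Optional matplotlib views of importances and removal curves."""

from __future__ import annotations

import numpy as np


def plot_global_importance(gi, ax=None):
    """Class-by-feature heatmap (darker = more important)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.3 * len(gi.feature_names)), max(2, 0.4 * len(gi.classes)))
        )
    im = ax.imshow(gi.table, aspect="auto", cmap="Blues")
    ax.set_xticks(range(len(gi.feature_names)), gi.feature_names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(gi.classes)), [str(c) for c in gi.classes], fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="mean latent norm")
    return ax


def plot_importance_heatmap(scores: np.ndarray, grid_shape, ax=None):
    """Per-feature scores of one sample reshaped onto a 2-D grid (patches)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    im = ax.imshow(np.asarray(scores).reshape(grid_shape), cmap="Blues")
    ax.figure.colorbar(im, ax=ax)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_removal_curves(curves: dict, ax=None):
    """Accuracy-vs-removed-features curves, one line per scoring method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for name, curve in curves.items():
        ax.plot(curve.removed_counts, curve.accuracies, marker="o", label=name)
    ax.set_xlabel("features removed per sample")
    ax.set_ylabel("accuracy")
    ax.legend(fontsize=8)
    return ax
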