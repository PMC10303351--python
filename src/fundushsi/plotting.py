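"""Plot helpers: principal-component score plots and mean spectra."""

from __future__ import annotations

import numpy as np

from .classification import NormalizedScores
from .synthetic import ARTERY, VEIN


def plot_score_scatter(scores: NormalizedScores, labels: np.ndarray, ax=None,
                       threshold: float | None = None):
    """Red/blue PC1-PC2 score scatter with the decision threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = scores.scores
    for cls, color, name in ((ARTERY, "red", "artery"), (VEIN, "blue", "vein")):
        sel = labels == cls
        ax.scatter(s[sel, 0], s[sel, 1], s=4, c=color, label=name, alpha=0.5)
    if threshold is not None:
        ax.axvline(threshold, color="k", ls="--", lw=1)
    ax.set_xlabel("normalized PC1 score")
    ax.set_ylabel("normalized PC2 score")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_mean_spectra(grid, curves: dict[str, np.ndarray], ax=None):
    """Overlay labelled mean reflectance curves over wavelength."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, vals in curves.items():
        ax.plot(grid.values, vals, label=name)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.legend()
    return ax
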