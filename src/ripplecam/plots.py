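"""Figure rendering: similarity heatmaps, Grad-CAM overlays, R histograms.

All figures are written straight to file with the Agg backend; nothing here
feeds back into the numerics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gradcam import Heatmap
from .preprocess import SimilarityMatrix
from .waveforms import RippleError

PathLike = Union[str, Path]


def render_similarity_matrix(
    matrix: SimilarityMatrix, path: PathLike, threshold: float = 0.6
) -> None:
    """Similarity table as an image: diagonal and above-threshold cells stand out."""
    v = matrix.values
    fig, ax = plt.subplots(figsize=(6, 5))
    shown = np.where(v > threshold, 1.0, 0.0)
    np.fill_diagonal(shown, 2.0)  # distinguish the diagonal
    im = ax.imshow(shown, cmap="coolwarm", interpolation="nearest")
    ax.set_xlabel("ripple j")
    ax.set_ylabel("ripple i (reference)")
    ax.set_title(f"normalized cross-correlation > {threshold}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_heatmap_overlay(
    waveform: np.ndarray,
    heatmaps: Sequence[Heatmap],
    path: PathLike,
    conv_stride: int = 10,
    window: int = 500,
    cmap: str = "viridis",
) -> None:
    """Waveform with vertically enlarged class heatmaps on a shared time axis.

    Each length-S heatmap is stretched so pixel i spans the receptive field
    starting at ``conv_stride * i``; one horizontal band per class, in
    category order.
    """
    waveform = np.asarray(waveform, dtype=float).ravel()
    if not heatmaps:
        raise RippleError("no heatmaps supplied")
    n = waveform.size
    fig, axes = plt.subplots(
        1 + len(heatmaps), 1, figsize=(10, 2 + 0.6 * len(heatmaps)),
        sharex=True, gridspec_kw={"height_ratios": [3] + [1] * len(heatmaps)},
    )
    axes[0].plot(np.arange(n), waveform, lw=0.5, color="k")
    axes[0].set_ylabel("amplitude")
    axes[0].set_xlim(0, n)
    for ax, hm in zip(axes[1:], heatmaps):
        # resample pixels to sample resolution over their receptive fields
        band = np.zeros(n)
        counts = np.zeros(n)
        for i, val in enumerate(hm.values):
            lo = conv_stride * i
            hi = min(n, lo + window)
            band[lo:hi] += val
            counts[lo:hi] += 1
        band = np.divide(band, np.maximum(counts, 1))
        ax.imshow(band[None, :], aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0,
                  extent=(0, n, 0, 1))
        ax.set_yticks([])
        ax.set_ylabel(f"k={hm.class_index}", rotation=0, labelpad=18, va="center")
    axes[-1].set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_r_histograms(
    values_by_category: Dict[str, np.ndarray], path: PathLike, bins: int = 60
) -> None:
    """Per-category frequency distributions of the pairwise R statistic."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for cat, vals in values_by_category.items():
        ax.hist(np.asarray(vals), bins=bins, histtype="step", label=cat, density=True)
    ax.set_xlabel("pairwise R")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
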