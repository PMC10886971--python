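"""Grad-CAM saliency for the 1D ripple classifier.

For class k, the importance of conv filter l is the spatial mean of the
gradient of the pre-softmax class score with respect to that filter's
feature map,

    alpha_l^k = (1/S) sum_i  d y_k / d A_{i,l},        S = 171,

and the heatmap is the ReLU of the importance-weighted sum of feature maps,

    L^k = ReLU( sum_l alpha_l^k A^l ),

normalized to a peak of 1.  Each heatmap pixel i corresponds to the conv
receptive field starting at input sample 10*i, so the 500-sample window
anchored at the peak pixel is the part of the waveform the network used —
the *partial waveform*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cnn import CNNResults
from .waveforms import RippleError

logger = logging.getLogger(__name__)


@dataclass
class Heatmap:
    """Length-S non-negative class heatmap for one input event."""

    class_index: int
    values: np.ndarray
    normalized: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise RippleError("heatmap must be 1D")
        if np.any(self.values < 0):
            raise RippleError("heatmap values must be non-negative (post-ReLU)")
        if self.normalized and self.values.max() > 0 and not np.isclose(
            self.values.max(), 1.0
        ):
            raise RippleError("normalized heatmap must peak at 1.0")


@dataclass
class PartialWaveform:
    """The 500-sample input window selected by a heatmap peak."""

    source_id: str
    start: int
    samples: np.ndarray
    peak_pixel: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def compute_importance(results: CNNResults, x: np.ndarray, k: int) -> np.ndarray:
    """Filter importances alpha^k: spatially averaged score gradients."""
    A, dA = results.feature_maps_and_grad(x, k)
    S = results.arch.conv_out_len
    return np.asarray(dA, dtype=float).sum(axis=0) / S


def compute_heatmap(
    alpha: np.ndarray, feature_maps: np.ndarray,
    class_index: int = 0, source_id: str = "",
) -> Heatmap:
    """Importance-weighted, ReLU'd, peak-normalized class heatmap."""
    alpha = np.asarray(alpha, dtype=float)
    A = np.asarray(feature_maps, dtype=float)
    if A.ndim != 2 or A.shape[1] != alpha.shape[0]:
        raise RippleError(
            f"feature maps {A.shape} incompatible with alpha {alpha.shape}"
        )
    L = np.maximum(A @ alpha, 0.0)
    peak = L.max()
    if peak > 0:
        L = L / peak
    else:
        logger.info("all-zero heatmap for %s class %d", source_id or "<input>",
                    class_index)
    return Heatmap(class_index=class_index, values=L, normalized=True,
                   source_id=source_id)


def gradcam_heatmap(results: CNNResults, x: np.ndarray, k: int,
                    source_id: str = "") -> Heatmap:
    """Convenience: importance + heatmap for input ``x`` and class ``k``."""
    A, dA = results.feature_maps_and_grad(x, k)
    alpha = np.asarray(dA, dtype=float).sum(axis=0) / results.arch.conv_out_len
    return compute_heatmap(alpha, A, class_index=k, source_id=source_id)


def extract_partial(
    x: np.ndarray,
    heatmap: Heatmap,
    conv_stride: int = 10,
    window: int = 500,
) -> Optional[PartialWaveform]:
    """Cut the receptive-field window of the earliest peak-valued pixel.

    The window length equals the conv kernel (500 samples = 20 ms at
    25 kHz) and starts at ``conv_stride * peak_pixel``.  Returns ``None``
    (a "no focus" result) for an all-zero heatmap.
    """
    if not heatmap.normalized:
        raise RippleError("extract_partial requires a normalized heatmap")
    x = np.asarray(x, dtype=float).ravel()
    L = heatmap.values
    if L.max() == 0:
        logger.warning("no-focus heatmap for %s; nothing to extract",
                       heatmap.source_id or "<input>")
        return None
    peak = int(np.flatnonzero(L == L.max())[0])
    start = conv_stride * peak
    if start + window > x.size:
        raise RippleError("receptive field exceeds input extent")
    return PartialWaveform(
        source_id=heatmap.source_id,
        start=start,
        samples=x[start : start + window].copy(),
        peak_pixel=peak,
    )
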