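"""Waveform preprocessing and cross-correlation similarity selection.

The selection pipeline is: remove events shorter than 15 ms, z-score each
event over its own extent (removes per-animal amplitude scale), compress
large spikes with a sign-symmetric log transform, score every ordered pair
with an autocorrelation-normalized cross-correlation, and keep only events
that have at least one partner scoring above a threshold (default 0.6).
Selected events are then zero-padded to the fixed network input length.

The similarity score of waveform j against reference i is

    max_tau sum_t z_i(t) z_j(t - tau)  /  sum_t z_i(t)^2

i.e. the peak lagged inner product divided by the reference's zero-lag
self inner product.  The normalization is deliberately asymmetric (the
matrix rows use their own autocorrelation), and values may exceed 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.fft import irfft, next_fast_len, rfft

from .waveforms import PAD_LENGTH, RippleError, RippleWaveform

logger = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, Sequence[float]]


# ---------------------------------------------------------------------------
# Elementwise transforms
# ---------------------------------------------------------------------------

def _standardize_array(x: np.ndarray) -> np.ndarray:
    if x.size < 2:
        raise RippleError("standardize requires at least 2 samples")
    sd = x.std()  # population SD
    if sd == 0:
        raise RippleError("constant waveform: population SD is zero")
    return (x - x.mean()) / sd


def standardize(x):
    """Z-score a waveform over its own extent (population SD).

    Output has mean 0 and SD 1; invariant under positive affine rescaling
    of the input, which is what removes per-animal amplitude differences.
    Accepts a :class:`RippleWaveform` (returns a ``standardized``-stage copy)
    or a plain array.
    """
    if isinstance(x, RippleWaveform):
        try:
            y = _standardize_array(x.samples)
        except RippleError as e:
            raise RippleError(f"waveform {x.id!r}: {e}") from None
        return x.with_samples(y, stage="standardized")
    return _standardize_array(np.asarray(x, dtype=float))


def _log_transform_array(y: np.ndarray) -> np.ndarray:
    return np.sign(y) * np.log10(np.abs(y) + 1.0)


def log_transform(y):
    """Sign-symmetric logarithmic compression: z = sign(y) log10(|y| + 1).

    Maps 0 to 0, 9 to 1, -9 to -1; odd, strictly monotone, and contractive
    (|z| <= |y|), so one large spike can no longer dominate the
    cross-correlation between two waveforms.
    """
    if isinstance(y, RippleWaveform):
        return y.with_samples(_log_transform_array(y.samples), stage="logtransformed")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise RippleError("log_transform: non-finite input")
    return _log_transform_array(y)


# ---------------------------------------------------------------------------
# Cross-correlation similarity
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    if isinstance(x, RippleWaveform):
        return x.samples
    return np.asarray(x, dtype=float)


def xcorr_max(a, b) -> Tuple[float, int]:
    """Peak unnormalized cross-correlation over all integer lags.

    Returns ``(value, lag)`` where ``value = max_tau sum_t a(t) b(t - tau)``,
    every alignment with at least one overlapping sample is considered, and
    out-of-range samples count as zero.  Ties are broken toward the smallest
    ``|tau|``, negative lag first.
    """
    a, b = _as_array(a), _as_array(b)
    if a.size == 0 or b.size == 0:
        raise RippleError("xcorr_max: empty input")
    c = _signal.correlate(a, b, mode="full", method="auto")
    lags = np.arange(-(b.size - 1), a.size)
    peak = c.max()
    cand = np.flatnonzero(c == peak)
    best = min(cand, key=lambda k: (abs(int(lags[k])), lags[k] > 0))
    return float(peak), int(lags[best])


def normalized_similarity(zi, zj) -> float:
    """Similarity of ``zj`` against ``zi``'s autocorrelation.

    ``xcorr_max(zi, zj) / xcorr_max(zi, zi)``; exactly 1.0 for identical
    inputs.  Not symmetric and not bounded by 1.
    """
    ai, aj = _as_array(zi), _as_array(zj)
    auto = float(np.dot(ai, ai))  # autocorrelation peaks at lag 0
    if auto == 0.0:
        raise RippleError("normalized_similarity: zero autocorrelation reference")
    if ai.size == aj.size and np.array_equal(ai, aj):
        return 1.0
    return xcorr_max(ai, aj)[0] / auto


# ---------------------------------------------------------------------------
# Duration filter and padding
# ---------------------------------------------------------------------------

def filter_min_duration(
    events: Sequence[RippleWaveform], min_ms: float = 15.0
) -> List[RippleWaveform]:
    """Drop events shorter than ``min_ms`` (events exactly at the bound kept)."""
    kept = []
    for ev in events:
        min_n = math.ceil(min_ms * ev.fs / 1000.0)
        if ev.n >= min_n:
            kept.append(ev)
        else:
            logger.info(
                "removing %s: %d samples < %d (%.1f ms at %.0f Hz)",
                ev.id, ev.n, min_n, min_ms, ev.fs,
            )
    return kept


def zero_pad(y: RippleWaveform, target_len: int = PAD_LENGTH) -> RippleWaveform:
    """Append trailing zeros to the fixed network input length.

    The original extent is recorded in ``n_orig`` so that downstream overlap
    computations can exclude the padding.
    """
    if y.n > target_len:
        raise RippleError(
            f"waveform {y.id!r}: {y.n} samples exceed pad target {target_len}"
        )
    out = np.zeros(target_len)
    out[: y.n] = y.samples
    return y.with_samples(out, stage="padded", n_orig=y.extent)


# ---------------------------------------------------------------------------
# Similarity matrix and selection
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Autocorrelation-normalized cross-correlation table.

    ``values[i, j]`` scores event ``j`` against event ``i``'s
    autocorrelation; the diagonal is exactly 1.  The matrix is generally
    asymmetric and entries may exceed 1.
    """

    values: np.ndarray
    ids: List[str]
    threshold: float = 0.6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RippleError("similarity matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise RippleError("similarity matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class SelectionResult:
    """Events kept by the mutual-similarity rule, with per-event evidence."""

    report: pd.DataFrame  # columns: id, best_partner, best_similarity, selected

    @property
    def selected_ids(self) -> List[str]:
        return list(self.report.loc[self.report["selected"], "id"])


def build_similarity_matrix(events: Sequence[RippleWaveform]) -> SimilarityMatrix:
    """All-pairs normalized similarity of log-transformed events.

    FFT-based: equivalent to calling :func:`normalized_similarity` on every
    ordered pair, but batched (one forward transform per event and one
    inverse transform per row).
    """
    if len(events) < 2:
        raise RippleError("build_similarity_matrix needs at least 2 events")
    for ev in events:
        if ev.stage != "logtransformed":
            raise RippleError(
                f"waveform {ev.id!r} is stage {ev.stage!r}; log-transform first"
            )
    n_ev = len(events)
    lengths = np.array([ev.n for ev in events])
    nfft = next_fast_len(2 * int(lengths.max()) - 1)
    padded = np.zeros((n_ev, nfft))
    for r, ev in enumerate(events):
        padded[r, : ev.n] = ev.samples
    spectra = rfft(padded, n=nfft, axis=1)
    autos = np.einsum("ij,ij->i", padded, padded)
    if np.any(autos == 0.0):
        raise RippleError("zero autocorrelation event in similarity matrix")

    idx = np.arange(nfft)
    values = np.empty((n_ev, n_ev))
    for i in range(n_ev):
        # circular correlation row: index tau for tau >= 0, nfft+tau for tau < 0
        row = irfft(spectra[i] * np.conj(spectra), n=nfft, axis=1)
        valid = (idx[None, :] < lengths[i]) | (idx[None, :] > nfft - lengths[:, None])
        row[~valid] = -np.inf
        values[i] = row.max(axis=1) / autos[i]
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, ids=[ev.id for ev in events])


def select_similar(
    matrix: SimilarityMatrix, threshold: float = 0.6
) -> SelectionResult:
    """Keep event i iff some j != i has max(values[i,j], values[j,i]) > threshold.

    The symmetric max is used because the similarity table is asymmetric;
    the comparison is strict.
    """
    v = matrix.values
    n = v.shape[0]
    sym = np.maximum(v, v.T).astype(float)
    np.fill_diagonal(sym, -np.inf)
    rows = []
    for i in range(n):
        j = int(np.argmax(sym[i]))
        best = float(sym[i, j])
        rows.append(
            {
                "id": matrix.ids[i],
                "best_partner": matrix.ids[j],
                "best_similarity": best,
                "selected": bool(best > threshold),
            }
        )
    return SelectionResult(report=pd.DataFrame(rows))
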