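"""Core domain types for ripple-firing waveform analysis.

A *ripple firing* is a brief (~20-90 ms) synchronized multi-unit burst of
hippocampal CA1 neurons, recorded extracellularly in the 300 Hz - 10 kHz band
and sampled at 25 kHz.  Each event carries an episode-category label: the rat
was either experiencing one of four episodes (restraint stress, contact with a
female rat, contact with a male rat, contact with a novel object) or had not
yet experienced any episode ("Before").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Episode categories in annotation order (one-hot index order).
CATEGORIES = ("Restraint", "Female", "Male", "Object", "Before")

#: Default sampling rate of the recordings, Hz.
DEFAULT_FS = 25_000.0

#: Fixed CNN input length in samples (88.2 ms at 25 kHz).
PAD_LENGTH = 2205

#: Minimum event duration kept by the preprocessing filter, ms.
MIN_DURATION_MS = 15.0

#: Processing stages a waveform can be in.
STAGES = ("raw", "standardized", "logtransformed", "padded")


class RippleError(ValueError):
    """Raised for invalid ripple-waveform inputs or configurations."""


def category_index(category: str) -> int:
    """Return the one-hot index of an episode category label."""
    try:
        return CATEGORIES.index(category)
    except ValueError:
        raise RippleError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        ) from None


@dataclass
class RippleWaveform:
    """One extracted ripple-firing event.

    Parameters
    ----------
    id : str
        Unique event identifier.
    rat_id : int
        Animal the event was recorded from (amplitude scale nuisance source).
    category : str
        Episode label, one of :data:`CATEGORIES`.
    fs : float
        Sampling rate in Hz.
    samples : ndarray
        Amplitude sequence; finite floats.
    stage : str
        Processing stage, one of :data:`STAGES`.
    motif_start : int, optional
        Ground-truth start sample of the planted category motif
        (synthetic data only; absent for "Before" events).
    n_orig : int, optional
        Original (pre-padding) extent; set when the waveform is padded so
        later overlap computations can exclude the padding.
    """

    id: str
    rat_id: int
    category: str
    fs: float
    samples: np.ndarray
    stage: str = "raw"
    motif_start: Optional[int] = None
    n_orig: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise RippleError(f"waveform {self.id!r}: samples must be a non-empty 1D array")
        if not np.all(np.isfinite(self.samples)):
            raise RippleError(f"waveform {self.id!r}: non-finite samples")
        if self.category not in CATEGORIES:
            raise RippleError(
                f"waveform {self.id!r}: unknown category {self.category!r}"
            )
        if self.stage not in STAGES:
            raise RippleError(f"waveform {self.id!r}: unknown stage {self.stage!r}")
        if self.fs <= 0:
            raise RippleError(f"waveform {self.id!r}: fs must be positive")

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Event duration in milliseconds (original extent if padded)."""
        n = self.n_orig if self.n_orig is not None else self.n
        return 1000.0 * n / self.fs

    @property
    def extent(self) -> int:
        """Original (pre-padding) number of samples."""
        return self.n_orig if self.n_orig is not None else self.n

    def with_samples(self, samples: np.ndarray, stage: str, **kw) -> "RippleWaveform":
        """Copy carrying new samples at a new processing stage."""
        return replace(self, samples=np.asarray(samples, dtype=float), stage=stage, **kw)


def as_matrix(events: Sequence[RippleWaveform]) -> np.ndarray:
    """Stack equal-length waveforms into an (n_events, n_samples) matrix."""
    lengths = {e.n for e in events}
    if len(lengths) != 1:
        raise RippleError(f"waveforms have unequal lengths {sorted(lengths)}; pad first")
    return np.stack([e.samples for e in events])


def labels_of(events: Sequence[RippleWaveform]) -> np.ndarray:
    """Integer category labels (annotation order) for a list of events."""
    return np.array([category_index(e.category) for e in events], dtype=int)
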