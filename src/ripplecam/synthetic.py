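"""Synthetic ripple-firing generator.

The real recordings behind this analysis are not publicly distributable, so
this module emulates their statistical structure: short multi-spike burst
events riding on noise, per-animal amplitude scale differences (the nuisance
that z-scoring removes), durations of a few tens of milliseconds, and — for
the four episode categories — a fixed 20 ms category-specific spike motif
embedded at a random position.  "Before" events carry no motif, so the
classifier must learn both motif identity and motif absence.

Every draw is keyed off ``(config.seed, dataset seed, category, event index)``
through :class:`numpy.random.SeedSequence`, so datasets are bit-reproducible
and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .waveforms import (
    CATEGORIES,
    DEFAULT_FS,
    PAD_LENGTH,
    RippleError,
    RippleWaveform,
    category_index,
)

# Biphasic extracellular spike kernel parameters, in samples at 25 kHz.
# A difference of two Gaussians gives the familiar sharp negative deflection
# followed by a slower positive rebound (~1 ms total).
_SPIKE_SIGMA_1 = 5.0
_SPIKE_SIGMA_2 = 9.0
_SPIKE_PHASE_OFFSET = 12.0
_SPIKE_SUPPORT = 60  # samples either side of the spike center


@dataclass
class GeneratorConfig:
    """Conditions under which synthetic ripple firings are generated.

    Parameters
    ----------
    sampling_rate : float
        Hz; recordings are sampled at 25 kHz.
    duration_range_ms : (float, float)
        Event durations are drawn uniformly from this range.  Must lie within
        [15, 88.2] ms: shorter events are removed by the preprocessing filter
        and longer ones would not fit the fixed 2205-sample network input.
    n_rats : int
        Number of animals; each has its own amplitude scale factor.
    amplitude_scale_range : (float, float)
        Per-rat multiplicative scale factors are drawn log-uniformly from
        this range — the across-animal amplitude nuisance.
    spike_rate : float
        Mean number of background spikes per event (Poisson).
    noise_sd : float
        Background Gaussian noise SD relative to the unit spike amplitude.
    motif_length : int
        Length of the planted category motif in samples (20 ms = 500).
    motif_snr : float
        Amplitude of the motif template relative to the unit spike amplitude.
        The default is strong enough that a matched filter recovers the
        planted position in essentially every event.
    seed : int
        Seeds the per-rat scale factors and the per-category motif templates.
    """

    sampling_rate: float = DEFAULT_FS
    duration_range_ms: Tuple[float, float] = (20.0, 85.0)
    n_rats: int = 8
    amplitude_scale_range: Tuple[float, float] = (0.2, 5.0)
    spike_rate: float = 40.0
    noise_sd: float = 0.3
    motif_length: int = 500
    motif_snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_ms
        if not (15.0 <= lo < hi <= PAD_LENGTH / self.sampling_rate * 1000.0 + 1e-9):
            raise RippleError(
                f"duration_range_ms {self.duration_range_ms} must lie within "
                f"[15, {PAD_LENGTH / self.sampling_rate * 1000.0:.1f}] ms"
            )
        slo, shi = self.amplitude_scale_range
        if not (0 < slo <= shi):
            raise RippleError("amplitude_scale_range must be positive and ordered")
        for name in ("sampling_rate", "spike_rate", "noise_sd", "motif_snr"):
            if getattr(self, name) <= 0:
                raise RippleError(f"{name} must be strictly positive")
        if self.n_rats < 1 or self.motif_length < 1:
            raise RippleError("n_rats and motif_length must be >= 1")
        min_n = int(round(lo / 1000.0 * self.sampling_rate))
        if self.motif_length > min_n:
            raise RippleError(
                "motif_length exceeds the shortest possible event; motifs must fit"
            )


def _spike_kernel() -> np.ndarray:
    """Biphasic difference-of-Gaussians spike shape, peak amplitude 1."""
    t = np.arange(-_SPIKE_SUPPORT, _SPIKE_SUPPORT + 1, dtype=float)
    k = np.exp(-0.5 * (t / _SPIKE_SIGMA_1) ** 2) - 0.6 * np.exp(
        -0.5 * ((t - _SPIKE_PHASE_OFFSET) / _SPIKE_SIGMA_2) ** 2
    )
    return k / np.max(np.abs(k))


_KERNEL = _spike_kernel()


def _add_spikes(signal: np.ndarray, centers: np.ndarray, amps: np.ndarray) -> None:
    """Add biphasic spikes in place at the given sample centers."""
    n = signal.size
    half = _SPIKE_SUPPORT
    for c, a in zip(centers, amps):
        c = int(c)
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        signal[lo:hi] += a * _KERNEL[lo - (c - half) : hi - (c - half)]


def rat_scales(config: GeneratorConfig) -> np.ndarray:
    """Per-rat amplitude scale factors, log-uniform, fixed by ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    lo, hi = config.amplitude_scale_range
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=config.n_rats)


def category_motif(config: GeneratorConfig, category: str) -> Optional[np.ndarray]:
    """Fixed motif template for one episode category (``None`` for "Before").

    Each of the four episode categories gets a distinct spike-timing/shape
    template of ``motif_length`` samples, drawn once per ``config.seed``:
    a burst of spikes at category-specific positions and polarities, with
    peak absolute amplitude 1 before scaling by ``motif_snr``.
    """
    idx = category_index(category)
    if category == "Before":
        return None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, idx]))
    m = np.zeros(config.motif_length)
    n_spikes = 12
    margin = _SPIKE_SUPPORT
    centers = np.sort(
        rng.uniform(margin, config.motif_length - margin, size=n_spikes)
    )
    amps = rng.uniform(0.6, 1.0, size=n_spikes) * rng.choice([-1.0, 1.0], size=n_spikes)
    _add_spikes(m, centers, amps)
    return m / np.max(np.abs(m))


def generate_ripple(
    config: GeneratorConfig,
    category: str,
    rat_id: int,
    rng: np.random.Generator,
    event_id: str = "ripple",
) -> RippleWaveform:
    """Generate one raw-stage synthetic ripple-firing event.

    The event is ``scale_rat × (noise + burst ± motif)``: Gaussian background
    noise, a Gaussian burst envelope modulating a Poisson train of biphasic
    spikes, and — for episode categories — the category motif added at a
    uniformly drawn position recorded in ``motif_start``.
    """
    if category not in CATEGORIES:
        raise RippleError(f"unknown category {category!r}")
    if not (0 <= rat_id < config.n_rats):
        raise RippleError(f"rat_id {rat_id} out of range [0, {config.n_rats})")

    fs = config.sampling_rate
    lo, hi = config.duration_range_ms
    n = int(round(rng.uniform(lo, hi) / 1000.0 * fs))

    signal = rng.normal(0.0, config.noise_sd, size=n)

    # Burst: spikes locked to a ~200 Hz ripple rhythm (1-3 spikes per cycle
    # with sub-millisecond jitter), amplitudes shaped by a Gaussian envelope
    # so the event waxes and wanes like a real burst.  The shared rhythm is
    # what makes events of different categories mutually similar under the
    # lag-maximized cross-correlation.
    period = fs / 200.0  # samples per ripple cycle
    cycle_starts = np.arange(period / 2.0, n, period)
    mean_per_cycle = max(config.spike_rate * period / n, 0.1)
    centers: List[float] = []
    for c0 in cycle_starts:
        for _ in range(rng.poisson(mean_per_cycle)):
            centers.append(c0 + rng.normal(0.0, 0.08 * period))
    if not centers:
        centers.append(n / 2.0)
    centers = np.clip(np.asarray(centers), 0, n - 1)
    envelope = np.exp(-0.5 * ((centers - n / 2.0) / (n / 4.0)) ** 2)
    amps = rng.uniform(0.5, 1.5, size=centers.size) * envelope
    _add_spikes(signal, centers, amps)

    motif_start: Optional[int] = None
    motif = category_motif(config, category)
    if motif is not None:
        motif_start = int(rng.integers(0, n - config.motif_length + 1))
        signal[motif_start : motif_start + config.motif_length] += (
            config.motif_snr * motif
        )

    scale = rat_scales(config)[rat_id]
    return RippleWaveform(
        id=event_id,
        rat_id=rat_id,
        category=category,
        fs=fs,
        samples=scale * signal,
        stage="raw",
        motif_start=motif_start,
    )


def generate_dataset(
    config: GeneratorConfig,
    n_per_category: Mapping[str, int],
    seed: Optional[int] = None,
) -> Tuple[List[RippleWaveform], pd.DataFrame]:
    """Generate a labeled dataset plus its manifest.

    Parameters
    ----------
    n_per_category : mapping
        Event counts per category label.  The study's selected dataset had
        counts {Restraint: 196, Female: 173, Male: 131, Object: 93,
        Before: 267} — 860 events total.
    seed : int, optional
        Dataset draw seed; defaults to ``config.seed``.  Rat scale factors
        and motif templates always come from ``config.seed``.

    Returns
    -------
    (events, manifest) where manifest has one row per event with columns
    id, rat_id, category, fs_hz, n_samples, motif_start, path.
    """
    if not n_per_category:
        raise RippleError("n_per_category must name at least one category")
    for cat, cnt in n_per_category.items():
        if cat not in CATEGORIES:
            raise RippleError(f"unknown category {cat!r}")
        if cnt <= 0:
            raise RippleError(f"count for {cat!r} must be positive")
    if seed is None:
        seed = config.seed

    events: List[RippleWaveform] = []
    rows = []
    rat_cursor = 0
    for cat in CATEGORIES:
        if cat not in n_per_category:
            continue
        ci = category_index(cat)
        for i in range(n_per_category[cat]):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, i]))
            rat_id = rat_cursor % config.n_rats
            rat_cursor += 1
            ev = generate_ripple(config, cat, rat_id, rng, event_id=f"{cat}_{i:04d}")
            events.append(ev)
            rows.append(
                {
                    "id": ev.id,
                    "rat_id": ev.rat_id,
                    "category": ev.category,
                    "fs_hz": ev.fs,
                    "n_samples": ev.n,
                    "motif_start": -1 if ev.motif_start is None else ev.motif_start,
                    "path": "",
                }
            )
    manifest = pd.DataFrame(rows)
    return events, manifest


def matched_filter_locate(
    event: RippleWaveform, template: np.ndarray
) -> int:
    """Brute-force matched filter: start index maximizing template correlation.

    Used to verify planted-motif recoverability against ground truth; operates
    on the z-scored event so per-rat scale cannot help.
    """
    x = event.samples
    x = (x - x.mean()) / x.std()
    m = template.size
    if event.n < m:
        raise RippleError("event shorter than template")
    scores = np.correlate(x, template, mode="valid")
    return int(np.argmax(scores))
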