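"""Pairwise cross-correlation statistics and group comparisons.

Within each episode category, every ordered pair of standardized waveforms
(i != j) is scored with an overlap-normalized peak cross-correlation

    R_ij = max_tau (1/L(tau)) sum_t y_i(t) y_j(t - tau),

where L(tau) counts the overlapping non-padding samples at shift tau.  A
category with n events therefore yields n^2 - n values (R is symmetric, so
each unordered pair contributes two equal values).  Group means are compared
across the five categories with a one-way ANOVA and Scheffé's post-hoc
method, exactly the analysis behind the published group tables.

Note the ANOVA treats the pairwise values as independent observations; pairs
sharing a ripple are in fact dependent, so the test is anti-conservative.
This replicates the published analysis and is documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.fft import irfft, next_fast_len, rfft

from .waveforms import RippleError, RippleWaveform

#: Minimum overlap, as a fraction of the shorter waveform's extent, admitted
#: in the R maximization; prevents spurious maxima from tiny overlaps.
MIN_OVERLAP_FRAC = 0.25


def pair_count(n: int) -> int:
    """Number of ordered pairs, n^2 - n (e.g. 196 -> 38,220)."""
    if n < 0:
        raise RippleError("pair_count: n must be non-negative")
    return n * n - n


@dataclass
class PairwiseRSet:
    """All ordered-pair R values for one category."""

    category: str
    values: np.ndarray
    n_ripples: int

    @property
    def n_pairs(self) -> int:
        return pair_count(self.n_ripples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_pairs:
            raise RippleError(
                f"expected {self.n_pairs} ordered-pair values, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise RippleError("non-finite R values")


def r_max_pair(
    yi: np.ndarray, yj: np.ndarray, min_overlap_frac: float = MIN_OVERLAP_FRAC
) -> float:
    """Overlap-normalized peak cross-correlation of two standardized waveforms.

    Direct (non-FFT) reference implementation; :func:`pairwise_R` computes
    the same quantity batched.
    """
    yi = np.asarray(yi, dtype=float)
    yj = np.asarray(yj, dtype=float)
    ni, nj = yi.size, yj.size
    min_L = max(1, int(np.ceil(min_overlap_frac * min(ni, nj))))
    best = -np.inf
    for tau in range(-(nj - 1), ni):
        lo = max(0, tau)
        hi = min(ni - 1, nj - 1 + tau)
        L = hi - lo + 1
        if L < min_L:
            continue
        s = float(np.dot(yi[lo : hi + 1], yj[lo - tau : hi - tau + 1]))
        best = max(best, s / L)
    if not np.isfinite(best):
        raise RippleError("no admissible overlap between waveforms")
    return best


def pairwise_R(
    events: Sequence[RippleWaveform], min_overlap_frac: float = MIN_OVERLAP_FRAC
) -> PairwiseRSet:
    """All ordered-pair R values within one category (FFT-batched).

    Events must be standardized; padded events are truncated to their
    original extent so zero-padding never enters the overlap.
    """
    if len(events) < 2:
        raise RippleError("pairwise_R needs at least 2 waveforms")
    cats = {ev.category for ev in events}
    if len(cats) != 1:
        raise RippleError(f"pairwise_R expects one category, got {sorted(cats)}")
    for ev in events:
        if ev.stage not in ("standardized", "padded"):
            raise RippleError(
                f"waveform {ev.id!r} is stage {ev.stage!r}; standardize first"
            )
    ys = [ev.samples[: ev.extent] for ev in events]
    n_ev = len(ys)
    lengths = np.array([y.size for y in ys])
    nfft = next_fast_len(2 * int(lengths.max()) - 1)
    padded = np.zeros((n_ev, nfft))
    for r, y in enumerate(ys):
        padded[r, : y.size] = y
    spectra = rfft(padded, n=nfft, axis=1)

    idx = np.arange(nfft)
    R = np.zeros((n_ev, n_ev))
    for i in range(n_ev):
        ni = lengths[i]
        js = np.arange(i + 1, n_ev)
        if js.size == 0:
            break
        c = irfft(spectra[i] * np.conj(spectra[js]), n=nfft, axis=1)
        nj = lengths[js][:, None]
        pos = idx[None, :] < ni                      # tau = idx
        neg = idx[None, :] > nfft - nj               # tau = idx - nfft
        L = np.where(
            pos, np.minimum(ni - idx[None, :], nj),
            np.where(neg, np.minimum(ni, nj + idx[None, :] - nfft), 0),
        ).astype(float)
        min_L = np.maximum(1, np.ceil(min_overlap_frac * np.minimum(ni, nj)))
        ratio = np.where(L >= min_L, c / np.where(L > 0, L, 1.0), -np.inf)
        R[i, i + 1 :] = ratio.max(axis=1)
    R = R + R.T  # symmetric by the tau <-> -tau bijection
    mask = ~np.eye(n_ev, dtype=bool)
    return PairwiseRSet(
        category=events[0].category, values=R[mask], n_ripples=n_ev
    )


def group_summary(values: Sequence[float]) -> Tuple[float, float, int]:
    """(mean, SEM, count); SEM uses the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise RippleError("group_summary: empty input")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem, int(v.size)


def f_critical(df1: int, df2: int, alpha: float) -> float:
    """Upper-alpha quantile of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise RippleError("degrees of freedom must be >= 1")
    if not (0 < alpha < 1):
        raise RippleError("alpha must lie in (0, 1)")
    return float(sps.f.isf(alpha, df1, df2))


@dataclass
class AnovaResult:
    """One-way ANOVA with optional Scheffé pairwise decisions."""

    F: float
    df1: int
    df2: int
    p_value: float
    group_means: pd.Series
    group_sems: pd.Series
    group_counts: pd.Series
    ms_within: float
    scheffe: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        lines = [
            "One-way ANOVA",
            "=" * 40,
            f"F({self.df1}, {self.df2}) = {self.F:.4g}, p = {self.p_value:.4g}",
            "",
            "group        mean       SEM        n",
        ]
        for g in self.group_means.index:
            lines.append(
                f"{g:<10} {self.group_means[g]:9.4f} {self.group_sems[g]:9.4f} "
                f"{int(self.group_counts[g]):8d}"
            )
        if self.scheffe is not None:
            lines += ["", "Scheffé post-hoc", "-" * 40]
            for _, r in self.scheffe.iterrows():
                mark = "*" if r["significant"] else " "
                lines.append(
                    f"{r['group_1']:>9} vs {r['group_2']:<9} p = {r['p_value']:.3g} {mark}"
                )
        return "\n".join(lines)


def one_way_anova(groups: Dict[str, Sequence[float]]) -> AnovaResult:
    """Standard between/within variance decomposition across named groups."""
    if len(groups) < 2:
        raise RippleError("ANOVA needs at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise RippleError(f"group {g!r} needs at least 2 values")
    N = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, N - k
    msb = ssb / df1
    msw = ssw / df2
    F = 0.0 if msw == 0 and msb == 0 else (np.inf if msw == 0 else msb / msw)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    summaries = [group_summary(a) for a in arrays]
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p_value=p,
        group_means=pd.Series({g: s[0] for g, s in zip(names, summaries)}),
        group_sems=pd.Series({g: s[1] for g, s in zip(names, summaries)}),
        group_counts=pd.Series({g: s[2] for g, s in zip(names, summaries)}),
        ms_within=float(msw),
    )


def scheffe_posthoc(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA plus Scheffé's all-pairs post-hoc decisions.

    For pair (i, j) the statistic is

        F_ij = (mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j) (k - 1)),

    declared significant iff F_ij exceeds the F critical value at
    (k-1, N-k); its p-value is the upper tail of that F distribution.
    """
    if not (0 < alpha < 1):
        raise RippleError("alpha must lie in (0, 1)")
    result = one_way_anova(groups)
    names = list(groups)
    k = len(names)
    crit = f_critical(result.df1, result.df2, alpha)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            denom = result.ms_within * (1.0 / a.size + 1.0 / b.size) * (k - 1)
            Fij = (a.mean() - b.mean()) ** 2 / denom if denom > 0 else np.inf
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": float(a.mean() - b.mean()),
                    "F": float(Fij),
                    "p_value": float(sps.f.sf(Fij, result.df1, result.df2)),
                    "significant": bool(Fij > crit),
                }
            )
    result.scheffe = pd.DataFrame(rows)
    return result
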