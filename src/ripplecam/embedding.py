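"""t-SNE embedding and centroid-distance analysis.

Waveform collections (full 2205-sample inputs or 500-sample Grad-CAM
partial waveforms) are mapped to a 2D feature space with t-SNE; category
structure is then summarized by each category's centroid, the mean
point-to-centroid distance within the category (spread), and the matrix of
between-centroid Euclidean distances.  Comparing these tables between full
and partial waveforms quantifies whether the windows the classifier focuses
on separate the categories better than the raw inputs do.

t-SNE coordinates are seed- and implementation-dependent, so only relative
statements (partial vs full, between vs within) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .waveforms import RippleError


@dataclass
class Embedding2D:
    """2D t-SNE coordinates with per-point category labels."""

    points: np.ndarray
    labels: List[str]
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise RippleError("embedding must be n x 2")
        if len(self.labels) != len(self.points):
            raise RippleError("labels length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise RippleError("non-finite embedding coordinates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.labels, "x": self.points[:, 0], "y": self.points[:, 1]}
        )


@dataclass
class CentroidSummary:
    """Per-category centroids, within-category spreads, between distances."""

    categories: List[str]
    centroids: np.ndarray            # (k, 2)
    within_mean: pd.Series           # mean point-to-centroid distance
    between: pd.DataFrame            # symmetric k x k distance table

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "centroids": self.centroids.tolist(),
            "within_mean_distance": self.within_mean.to_dict(),
            "between_centroid_distance": self.between.to_dict(),
        }


def embed(
    X: np.ndarray,
    labels: Sequence[str],
    perplexity: float = 30.0,
    max_iter: int = 1000,
    init: str = "pca",
    seed: int = 0,
) -> Embedding2D:
    """Map an (n, d) waveform matrix to 2D with t-SNE.

    Exact (non-approximate) t-SNE is used for n <= 1000; deterministic for a
    fixed seed and parameter set.  Requires ``perplexity < n``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise RippleError("embedding needs at least 5 points")
    if perplexity >= n:
        raise RippleError(
            f"perplexity {perplexity} must be below n={n}; pass a smaller perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        init=init,
        random_state=seed,
        method="exact" if n <= 1000 else "barnes_hut",
        metric="euclidean",
    )
    pts = tsne.fit_transform(X)
    return Embedding2D(
        points=pts,
        labels=list(labels),
        params={"perplexity": perplexity, "max_iter": max_iter, "init": init,
                "seed": seed},
    )


def summarize_centroids(embedding: Embedding2D) -> CentroidSummary:
    """Exact centroid / spread / distance arithmetic for an embedding."""
    labels = np.asarray(embedding.labels)
    cats = [c for c in pd.unique(labels)]
    if not cats:
        raise RippleError("no categories present")
    centroids = []
    within = {}
    for c in cats:
        pts = embedding.points[labels == c]
        cen = pts.mean(axis=0)
        centroids.append(cen)
        within[c] = float(np.linalg.norm(pts - cen, axis=1).mean())
    centroids = np.vstack(centroids)
    diff = centroids[:, None, :] - centroids[None, :, :]
    between = pd.DataFrame(
        np.linalg.norm(diff, axis=-1), index=cats, columns=cats
    )
    return CentroidSummary(
        categories=list(cats),
        centroids=centroids,
        within_mean=pd.Series(within),
        between=between,
    )


@dataclass
class SeparationComparison:
    """Full-vs-partial centroid geometry, the two qualitative observations.

    ``increased`` flags, per category pair, whether the partial-waveform
    between-centroid distance exceeds the full-waveform one;
    ``partial_between_exceeds_within`` states whether every partial
    between-centroid distance exceeds every partial within-category spread.
    """

    increased: pd.DataFrame
    n_pairs: int
    n_increased: int
    full_between_exceeds_within: bool
    partial_between_exceeds_within: bool

    def to_dict(self) -> dict:
        return {
            "increased": self.increased.to_dict(),
            "n_pairs": self.n_pairs,
            "n_increased": self.n_increased,
            "full_between_exceeds_within": self.full_between_exceeds_within,
            "partial_between_exceeds_within": self.partial_between_exceeds_within,
        }


def _between_exceeds_within(s: CentroidSummary) -> bool:
    """Every between-centroid distance exceeds the mean within-category spread.

    The mean spread (rather than the per-category maximum) is the reading
    under which the published tables support the claim.
    """
    k = len(s.categories)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if not pairs:
        return False
    min_between = min(s.between.iloc[i, j] for i, j in pairs)
    return bool(min_between > s.within_mean.mean())


def compare_separation(
    full: CentroidSummary, partial: CentroidSummary
) -> SeparationComparison:
    """Compare category separation of full-input vs partial-waveform embeddings."""
    if set(full.categories) != set(partial.categories):
        raise RippleError("summaries cover different categories")
    cats = full.categories
    inc = pd.DataFrame(False, index=cats, columns=cats)
    n_pairs = 0
    n_inc = 0
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            n_pairs += 1
            flag = bool(partial.between.loc[a, b] > full.between.loc[a, b])
            inc.loc[a, b] = inc.loc[b, a] = flag
            n_inc += flag
    return SeparationComparison(
        increased=inc,
        n_pairs=n_pairs,
        n_increased=n_inc,
        full_between_exceeds_within=_between_exceeds_within(full),
        partial_between_exceeds_within=_between_exceeds_within(partial),
    )
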