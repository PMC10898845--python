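"""Similarity and overlap of group-level maps.

Confusion between bodily maps is quantified as the cosine similarity of
their unthresholded group-level t-value vectors — no mean-centering, so
the activation/deactivation sign structure enters the comparison — and
spatial commonality as per-pixel counts of how many group-level maps are
significant at that pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pixel_stats import TMap


@dataclass
class SimilarityMatrix:
    """Pairwise cosine similarities of a set of labelled maps."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n), symmetric, entries in [-1, 1]
    source: str = "group_tmaps"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def mean_offdiagonal(self, subset: tuple[str, ...] | None = None) -> float:
        """Mean of the off-diagonal entries, optionally within a label subset."""
        if subset is None:
            idx = np.arange(len(self.labels))
        else:
            pos = {lab: i for i, lab in enumerate(self.labels)}
            idx = np.array([pos[lab] for lab in subset])
        sub = self.values[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        return float(sub[off].mean())


@dataclass
class OverlapMap:
    """Per-pixel count of significant group-level maps."""

    counts: np.ndarray  # integer vector over in-mask pixels
    subset: str  # all | emotions | physiological
    group: str


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity ``sum(a*b) / (||a|| ||b||)`` without centering."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def similarity_matrix(
    group_tmaps: dict[str, TMap] | dict[str, np.ndarray],
    labels: tuple[str, ...] | None = None,
    use: str = "t",
) -> SimilarityMatrix:
    """Cosine-similarity matrix of a set of group-level maps.

    Parameters
    ----------
    group_tmaps
        Mapping from stimulus label to its group-level :class:`TMap` (or
        directly to a map vector).
    labels
        Order of the output; defaults to the mapping's insertion order.
    use
        ``"t"`` takes each map's unthresholded t-value vector (the
        default); ``"mean"`` takes the group mean map instead, as a
        sensitivity variant.
    """
    if labels is None:
        labels = tuple(group_tmaps.keys())
    vecs = []
    length = None
    for lab in labels:
        m = group_tmaps[lab]
        if isinstance(m, TMap):
            v = m.t if use == "t" else m.mean
        else:
            v = np.asarray(m, dtype=float)
        v = np.where(np.isfinite(v), v, 0.0)  # degenerate pixels carry no weight
        if length is None:
            length = v.size
        elif v.size != length:
            raise ValueError("maps are not on the same template")
        vecs.append(v)
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = cosine_similarity(vecs[i], vecs[j])
    return SimilarityMatrix(labels=tuple(labels), values=values)


def matrix_difference(m_high: SimilarityMatrix, m_low: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise high-minus-low difference of two similarity matrices."""
    if m_high.labels != m_low.labels:
        raise ValueError("similarity matrices have different label orders")
    return SimilarityMatrix(
        labels=m_high.labels,
        values=m_high.values - m_low.values,
        source=f"{m_high.source} - {m_low.source}",
    )


def overlap_counts(
    sig_masks: dict[str, np.ndarray],
    subset_labels: tuple[str, ...],
    subset_name: str = "all",
    group: str = "",
) -> OverlapMap:
    """Per-pixel count of significant maps within a stimulus subset.

    Each mask is a boolean significance vector (FDR-thresholded, sign
    ignored); the count at a pixel is the number of subset maps
    significant there.
    """
    if len(subset_labels) == 0:
        raise ValueError("empty stimulus subset")
    length = None
    total = None
    for lab in subset_labels:
        mask = np.asarray(sig_masks[lab], dtype=bool)
        if length is None:
            length = mask.size
            total = np.zeros(length, dtype=int)
        elif mask.size != length:
            raise ValueError("significance masks are not on the same template")
        total += mask.astype(int)
    return OverlapMap(counts=total, subset=subset_name, group=group)


def overlap_difference(high: OverlapMap, low: OverlapMap) -> np.ndarray:
    """Subtraction map: per-pixel high-group count minus low-group count."""
    if high.counts.size != low.counts.size:
        raise ValueError("overlap maps are not on the same template")
    if high.subset != low.subset:
        warnings.warn("subtracting overlap maps of different subsets", stacklevel=2)
    return high.counts - low.counts
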