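"""Unsupervised segmentation by hierarchical (bisecting) K-means.

Starting from one cluster holding every pixel spectrum, the cluster with the
largest within-cluster sum of squares (WCSS) is repeatedly split in two by a
seeded 2-means with 10 restarts, until K clusters exist.  The greedy
WCSS-first order makes the hierarchy deterministic given the seed, and total
WCSS is non-increasing in K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .hsio import HyperCube

__all__ = ["SegmentationMap", "hierarchical_kmeans", "cluster_sizes"]

DEFAULT_K = 24


@dataclass
class SegmentationMap:
    """Per-pixel cluster ids in 0..K-1; every id is non-empty."""

    cluster_id: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=np.int32)
        if self.cluster_id.ndim != 2:
            raise ValueError("segmentation map must be 2-D")
        present = np.unique(self.cluster_id)
        if present.min() < 0 or present.max() >= self.K:
            raise ValueError(f"cluster ids outside 0..{self.K - 1}")
        if len(present) != self.K:
            raise ValueError("every cluster id 0..K-1 must be non-empty")


def _wcss(X: np.ndarray) -> float:
    if len(X) < 2:
        return 0.0
    return float(np.sum((X - X.mean(axis=0)) ** 2))


def hierarchical_kmeans(cube: HyperCube, K: int = DEFAULT_K, seed: int = 0,
                        n_restarts: int = 10) -> SegmentationMap:
    """Segment the cube's pixel spectra into K clusters by bisecting K-means.

    Each bisection runs 2-means with ``n_restarts`` seeded restarts and keeps
    the best.  Clusters of identical spectra (zero WCSS) are only split when
    nothing with spread remains, in which case they are halved by pixel order
    so all K clusters stay non-empty.  Deterministic given ``seed``.
    """
    n_pixels = cube.rows * cube.cols
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_pixels:
        raise ValueError(f"K={K} exceeds pixel count {n_pixels}")
    X = cube.flatten_spectra().astype(float)
    assignments = np.zeros(n_pixels, dtype=np.int32)
    members: list[np.ndarray] = [np.arange(n_pixels)]
    wcss = [_wcss(X)]
    seeds = np.random.SeedSequence(seed).generate_state(max(K, 2) * 2) % (2**31)
    split_i = 0
    while len(members) < K:
        splittable = [i for i, m in enumerate(members) if len(m) > 1]
        target = max(splittable, key=lambda i: (wcss[i], -i))
        idx = members[target]
        if wcss[target] > 0:
            km = KMeans(n_clusters=2, n_init=n_restarts,
                        random_state=int(seeds[split_i]))
            side = km.fit_predict(X[idx])
            if len(np.unique(side)) < 2:  # duplicates collapsed a centre
                side = np.zeros(len(idx), dtype=int)
                side[len(idx) // 2:] = 1
        else:
            side = np.zeros(len(idx), dtype=int)
            side[len(idx) // 2:] = 1
        split_i += 1
        left, right = idx[side == 0], idx[side == 1]
        members[target] = left
        wcss[target] = _wcss(X[left])
        members.append(right)
        wcss.append(_wcss(X[right]))
    for cid, m in enumerate(members):
        assignments[m] = cid
    return SegmentationMap(assignments.reshape(cube.rows, cube.cols), K=len(members))


def cluster_sizes(seg: SegmentationMap) -> np.ndarray:
    """Pixel count per cluster id; sums to rows*cols."""
    return np.bincount(seg.cluster_id.ravel(), minlength=seg.K)
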