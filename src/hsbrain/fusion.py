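"""Majority-voting fusion of the supervised and unsupervised maps, and the
three-maximum-density (TMD) rendering.

Each unsupervised cluster collects the filtered supervised labels of its
pixels into a four-class density vector.  Majority voting assigns the
cluster its densest class (ties resolved conservatively in favour of tumor).
The TMD map renders, per cluster, the convex blend of the class colours of
its three largest densities — so a cluster that is 60% normal, 30% tumor,
10% vessel appears as a red-tinged green rather than a hard label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ProbabilityMap
from .cluster import SegmentationMap
from .constants import CLASS_CODES, CLASS_COLORS, TIE_PRIORITY
from .hsio import RGBImage

__all__ = ["ClusterDensities", "TMDMap", "class_densities", "majority_vote",
           "render_tmd"]


@dataclass
class ClusterDensities:
    """Per-cluster class-density vectors, K x 4 in canonical class order."""

    densities: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 2 or self.densities.shape[1] != len(CLASS_CODES):
            raise ValueError(f"densities must be K x {len(CLASS_CODES)}")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        if not np.allclose(self.densities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each cluster's densities must sum to 1")

    @property
    def K(self) -> int:
        return len(self.densities)


@dataclass
class TMDMap:
    """The final blended RGB map shown to the surgeon."""

    rgb: RGBImage
    votes: np.ndarray  # per-cluster majority class code
    densities: ClusterDensities


def class_densities(
    seg: SegmentationMap, probs: ProbabilityMap, soft: bool = False
) -> ClusterDensities:
    """Fraction of each cluster's pixels whose filtered argmax is each class.

    With ``soft=True`` the per-pixel probability vectors are averaged instead
    of hard argmax counts (config alternative; default follows the hard
    classification map).
    """
    if seg.cluster_id.shape != probs.shape:
        raise ValueError("segmentation and probability maps differ in shape")
    flat_ids = seg.cluster_id.ravel()
    if soft:
        flat = probs.probs.reshape(-1, len(CLASS_CODES))
        dens = np.zeros((seg.K, len(CLASS_CODES)))
        np.add.at(dens, flat_ids, flat)
        dens /= dens.sum(axis=1, keepdims=True)
        return ClusterDensities(dens)
    arg = probs.argmax_classes().ravel()
    dens = np.zeros((seg.K, len(CLASS_CODES)))
    for j, code in enumerate(CLASS_CODES):
        np.add.at(dens[:, j], flat_ids[arg == code], 1.0)
    dens /= np.bincount(flat_ids, minlength=seg.K)[:, None]
    return ClusterDensities(dens)


def majority_vote(dens: ClusterDensities) -> np.ndarray:
    """Assign each cluster its maximum-density class code.

    Exact ties go to the clinically conservative priority
    tumor > vessel > normal > background.
    """
    votes = np.empty(dens.K, dtype=np.int32)
    prio = {code: rank for rank, code in enumerate(TIE_PRIORITY)}
    for k, row in enumerate(dens.densities):
        best = max(CLASS_CODES,
                   key=lambda c: (row[CLASS_CODES.index(c)], -prio[c]))
        votes[k] = best
    return votes


def render_tmd(
    seg: SegmentationMap,
    dens: ClusterDensities,
    colors: dict[int, tuple[float, float, float]] | None = None,
) -> TMDMap:
    """Render the TMD map: per cluster, blend the three largest densities.

    The top three densities are renormalized to sum 1 and the cluster colour
    is their convex combination of class colours; every pixel of the cluster
    receives that colour, so rendered colours always lie in the convex hull
    of the class colours.
    """
    if colors is None:
        colors = CLASS_COLORS
    missing = [c for c in CLASS_CODES if c not in colors]
    if missing:
        raise ValueError(f"color table missing class codes {missing}")
    if dens.K != seg.K:
        raise ValueError("densities and segmentation disagree on K")
    palette = np.array([colors[c] for c in CLASS_CODES], dtype=float)
    cluster_rgb = np.zeros((dens.K, 3))
    for k, row in enumerate(dens.densities):
        top3 = np.sort(np.argsort(-row, kind="stable")[:3])
        weights = row[top3]
        total = weights.sum()
        if total > 0:
            weights = weights / total
        else:  # degenerate all-zero top-3 cannot occur for valid densities
            weights = np.full(3, 1.0 / 3.0)
        cluster_rgb[k] = weights @ palette[top3]
    rgb = cluster_rgb[seg.cluster_id]
    return TMDMap(RGBImage(rgb), majority_vote(dens), dens)
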