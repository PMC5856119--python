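"""End-to-end in-situ pipeline: calibrate -> preprocess -> {PCA + SVM + k-NN
filtering || hierarchical K-means} -> majority voting -> TMD map.

The supervised branch (PCA, SVM, k-NN filtering) and the unsupervised branch
(hierarchical K-means) are independent stages joined at the majority-voting
fusion; they are executed sequentially here but kept as a logical fork so
per-stage wall times can be reported separately.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import yaml

from .calibration import CalibrationResult, ReferenceFrames, calibrate
from .classify import (ClassifierConfig, ClassifierModel, OneBandImage,
                       ProbabilityMap, knn_filter, pca_first_component,
                       predict_probabilities)
from .cluster import SegmentationMap, hierarchical_kmeans
from .constants import CLASS_COLORS
from .fusion import ClusterDensities, TMDMap, class_densities, render_tmd
from .hsio import HyperCube
from .preprocess import PreprocessConfig, preprocess

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "STAGE_NAMES"]

logger = logging.getLogger(__name__)

#: Per-stage timing keys always present in a result's timing log.
STAGE_NAMES = ("preprocessing", "pca_svm", "knn", "hkm", "mv")


def _dataclass_from_mapping(cls, mapping):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


@dataclass
class PipelineConfig:
    """Configuration for the full TMD pipeline; unknown keys are rejected."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_clusters: int = 24
    knn_k: int = 40
    spatial_weight: float = 1.0
    soft_densities: bool = False
    colors: dict = field(default_factory=lambda: dict(CLASS_COLORS))
    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        if "preprocess" in mapping:
            mapping["preprocess"] = _dataclass_from_mapping(
                PreprocessConfig, dict(mapping["preprocess"]))
        if "classifier" in mapping:
            mapping["classifier"] = _dataclass_from_mapping(
                ClassifierConfig, dict(mapping["classifier"]))
        if "colors" in mapping:
            mapping["colors"] = {int(k): tuple(v)
                                 for k, v in dict(mapping["colors"]).items()}
        return _dataclass_from_mapping(cls, mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    """All stage artifacts of one pipeline run plus the per-stage timing log."""

    calibration: CalibrationResult
    preprocessed: HyperCube
    pc1: OneBandImage
    probabilities: ProbabilityMap
    filtered: ProbabilityMap
    segmentation: SegmentationMap
    densities: ClusterDensities
    tmd: TMDMap
    timings_s: dict

    @property
    def fused_class_map(self) -> np.ndarray:
        """Per-pixel class code after fusion (each cluster's majority vote)."""
        return self.tmd.votes[self.segmentation.cluster_id]


def run_pipeline(
    raw: HyperCube,
    refs: ReferenceFrames,
    model: ClassifierModel,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full in-situ chain on one raw capture.

    Stage order: calibration, pre-processing, then the supervised branch
    (PCA one-band image, SVM probabilities, k-NN filtering) and the
    unsupervised branch (hierarchical K-means), joined by majority voting
    and TMD rendering.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = PipelineConfig()
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-13s %7.3f s", name, timings[name])
        return out

    cal = _stage("calibration", lambda: calibrate(raw, refs))
    pp = _stage("preprocessing", lambda: preprocess(cal.cube, config.preprocess))

    def _supervised():
        pc1 = pca_first_component(pp)
        probs = predict_probabilities(model, pp)
        return pc1, probs

    pc1, probs = _stage("pca_svm", _supervised)
    filtered = _stage("knn", lambda: knn_filter(
        probs, pc1, K=config.knn_k, spatial_weight=config.spatial_weight))
    seg = _stage("hkm", lambda: hierarchical_kmeans(
        pp, K=config.n_clusters, seed=config.seed))

    def _fuse():
        dens = class_densities(seg, filtered, soft=config.soft_densities)
        return dens, render_tmd(seg, dens, config.colors)

    dens, tmd = _stage("mv", _fuse)
    return PipelineResult(
        calibration=cal, preprocessed=pp, pc1=pc1, probabilities=probs,
        filtered=filtered, segmentation=seg, densities=dens, tmd=tmd,
        timings_s=timings,
    )
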