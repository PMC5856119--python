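"""Spatial-spectral supervised stage: probabilistic SVM, PCA one-band image,
and k-NN filtering of the probability maps.

The pixel-wise classifier is a four-class SVM with calibrated probabilities.
Its per-pixel probability vectors are then homogenized spatially: each pixel
is embedded in a three-dimensional feature space built from its image
coordinates and the value of a one-band representation of the cube (the
first principal component), and its probability vector is replaced by the
mean over its K nearest neighbours in that space.  Pixels that are close on
the image plane AND look alike spectrally therefore receive coherent labels,
while edges in the PC1 guide stop smoothing across tissue boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .constants import CLASS_CODES
from .hsio import HyperCube
from .labeling import TrainingDataset

__all__ = [
    "ClassifierConfig",
    "ClassifierModel",
    "ProbabilityMap",
    "OneBandImage",
    "train_classifier",
    "predict_probabilities",
    "pca_first_component",
    "knn_filter",
    "training_fraction_curve",
]


@dataclass
class ClassifierConfig:
    """SVM configuration: linear kernel, C=1, one-vs-one with pairwise-coupled
    Platt probabilities (the sklearn SVC default probability machinery)."""

    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0


@dataclass
class ClassifierModel:
    """A trained probabilistic classifier over the four tissue classes.

    ``predict_proba`` output is re-indexed to the canonical class-code order
    (normal, tumor, vessel, background); classes absent from training get
    probability zero.
    """

    svc: SVC
    n_bands: int
    config: ClassifierConfig
    class_codes: tuple = CLASS_CODES

    def predict_proba(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.asarray(spectra, dtype=float)
        if spectra.shape[1] != self.n_bands:
            raise ValueError(
                f"model trained on {self.n_bands} bands, got {spectra.shape[1]}"
            )
        raw = self.svc.predict_proba(spectra)
        out = np.zeros((len(spectra), len(self.class_codes)))
        for j, cls in enumerate(self.svc.classes_):
            out[:, self.class_codes.index(int(cls))] = raw[:, j]
        return out


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, rows x cols x 4 in canonical class order."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(CLASS_CODES):
            raise ValueError(
                f"probability map must be rows x cols x {len(CLASS_CODES)}"
            )
        if np.any(self.probs < 0):
            raise ValueError("negative probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("pixel probabilities must sum to 1 within 1e-6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]

    def argmax_classes(self) -> np.ndarray:
        """Per-pixel most probable class code (ties -> lowest code)."""
        codes = np.asarray(CLASS_CODES)
        return codes[np.argmax(self.probs, axis=2)]


@dataclass
class OneBandImage:
    """A single-band surrogate of the cube, used to guide spatial filtering."""

    values: np.ndarray
    explained_variance_ratio: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("one-band image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("one-band image contains non-finite values")


def _canonical_order(spectra: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row permutation sorting by label then lexicographically by spectrum.

    Training through this ordering makes the fitted model independent of the
    order rows happened to arrive in (Platt calibration's internal CV folds
    otherwise depend on it).
    """
    keys = [spectra[:, j] for j in range(spectra.shape[1] - 1, -1, -1)]
    keys.append(labels)
    return np.lexsort(keys)


def train_classifier(
    ds: TrainingDataset, config: ClassifierConfig | None = None
) -> ClassifierModel:
    """Fit the probabilistic SVM on a training dataset.

    Deterministic given ``config.seed`` and invariant to training-row order.
    Requires at least two classes with at least two samples each.
    """
    if config is None:
        config = ClassifierConfig()
    labels = np.asarray(ds.labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes {small} have fewer than two samples")
    order = _canonical_order(ds.spectra, labels)
    X, y = ds.spectra[order], labels[order]
    svc = SVC(kernel=config.kernel, C=config.C, probability=True,
              random_state=config.seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of
        # CalibratedClassifierCV; the built-in pairwise-coupled Platt
        # probabilities are exactly what this stage wants, so keep them.
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, y)
    return ClassifierModel(svc=svc, n_bands=ds.spectra.shape[1], config=config)


def predict_probabilities(model: ClassifierModel, cube: HyperCube) -> ProbabilityMap:
    """Pixel-wise class probabilities for a pre-processed cube.

    The cube must have been pushed through the same pre-processing chain as
    the training spectra (band counts are checked; the chain itself cannot
    be).
    """
    flat = cube.flatten_spectra()
    probs = model.predict_proba(flat)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return ProbabilityMap(probs.reshape(cube.rows, cube.cols, -1))


def pca_first_component(cube: HyperCube) -> OneBandImage:
    """Project each pixel spectrum onto the first principal axis.

    The axis is the leading eigenvector of the mean-centred pixel-spectra
    covariance, fitted per image.  Sign convention: the loading vector's
    largest-magnitude entry is positive, so the projection is reproducible
    across runs and pixel duplication.
    """
    if cube.bands < 2:
        raise ValueError("PCA needs at least 2 bands")
    X = cube.flatten_spectra().astype(float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("constant cube: first principal component undefined")
    # economy SVD: leading right-singular vector == leading covariance eigenvector
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    proj = Xc @ loading
    evr = float(s[0] ** 2 / np.sum(s**2))
    return OneBandImage(proj.reshape(cube.rows, cube.cols), evr)


def knn_filter(
    probs: ProbabilityMap,
    guide: OneBandImage,
    K: int = 40,
    spatial_weight: float = 1.0,
) -> ProbabilityMap:
    """Replace each pixel's probability vector by the mean over its K nearest
    neighbours in (scaled row, scaled col, guide value) feature space.

    The guide is min-max scaled to [0, 1]; row and column are scaled by
    1/max(rows, cols) and multiplied by ``spatial_weight`` (lambda).  With
    lambda -> infinity the filter becomes a purely spatial mean; with
    lambda = 0 it averages over pixels of similar guide value regardless of
    position.  Each pixel is its own neighbour, so K=1 is the identity.
    """
    rows, cols = probs.shape
    if guide.values.shape != (rows, cols):
        raise ValueError("guide shape does not match probability map")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > rows * cols:
        raise ValueError(f"K={K} exceeds pixel count {rows * cols}")
    if spatial_weight < 0:
        raise ValueError("spatial_weight must be >= 0")
    g = guide.values.astype(float)
    lo, hi = g.min(), g.max()
    g = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)
    scale = 1.0 / max(rows, cols)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    feats = np.column_stack([
        spatial_weight * rr.ravel() * scale,
        spatial_weight * cc.ravel() * scale,
        g.ravel(),
    ])
    nn = NearestNeighbors(n_neighbors=K).fit(feats)
    _, idx = nn.kneighbors(feats)
    flat = probs.probs.reshape(-1, probs.probs.shape[2])
    out = flat[idx].mean(axis=1)
    out = out / out.sum(axis=1, keepdims=True)
    return ProbabilityMap(out.reshape(rows, cols, -1))


def training_fraction_curve(
    ds: TrainingDataset,
    fractions: list[float],
    folds: int = 10,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> list[tuple[float, float]]:
    """Mean k-fold CV overall accuracy as a function of training-set fraction.

    For each fraction a stratified subsample of the dataset is drawn, then
    ``folds``-fold stratified CV is run with the configured SVM and the mean
    overall accuracy recorded.  Fraction 1.0 is plain k-fold CV on the whole
    dataset.  A fraction so small that a class drops below ``folds`` samples
    is skipped with a warning.  Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if config is None:
        config = ClassifierConfig(seed=seed)
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.labels, dtype=int)
    results = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        if frac == 1.0:
            sel = np.arange(len(ds))
        else:
            sel = []
            for cls in np.unique(labels):
                members = np.nonzero(labels == cls)[0]
                k = int(round(frac * len(members)))
                sel.append(rng.choice(members, size=k, replace=False))
            sel = np.concatenate(sel)
        sub_y = labels[sel]
        present, counts = np.unique(sub_y, return_counts=True)
        if len(present) < len(np.unique(labels)) or counts.min() < folds:
            warnings.warn(
                f"fraction {frac}: a class has fewer than {folds} samples; skipped",
                stacklevel=2,
            )
            continue
        sub_X = ds.spectra[sel]
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for train_idx, test_idx in cv.split(sub_X, sub_y):
            svc = SVC(kernel=config.kernel, C=config.C, random_state=config.seed)
            svc.fit(sub_X[train_idx], sub_y[train_idx])
            accs.append(accuracy_score(sub_y[test_idx], svc.predict(sub_X[test_idx])))
        results.append((float(frac), float(np.mean(accs))))
    return results
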