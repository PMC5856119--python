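"""SAM-based gold-standard labeling and training-dataset assembly.

A gold-standard map assigns each pixel one of five codes: 0 unlabeled,
1 normal tissue, 2 tumor tissue, 3 blood vessel / hypervascularized tissue,
4 background.  Labels are grown from trusted reference pixels by spectral
angle mapper (SAM) thresholding: a pixel joins the class when the angle
between its spectrum and the reference spectrum is below a tolerance.  SAM is
scale-invariant, so the selection is robust to illumination amplitude.

Labeled pixels from many captures are stacked into a TrainingDataset whose
``groups`` column carries subject identity for leakage-free grouped CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CLASS_CODES, CLASS_NAMES, UNLABELED
from .hsio import HyperCube

__all__ = [
    "GoldStandardMap",
    "TrainingDataset",
    "sam_angle",
    "sam_select",
    "assign_class",
    "assemble_dataset",
    "dataset_summary",
    "save_dataset",
    "load_dataset",
]


@dataclass
class GoldStandardMap:
    """Per-pixel class labels plus free-text provenance per labeled region."""

    labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        valid = set(CLASS_CODES) | {UNLABELED}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"illegal label codes {sorted(present - valid)}")

    @classmethod
    def empty(cls, rows: int, cols: int) -> "GoldStandardMap":
        return cls(np.zeros((rows, cols), dtype=np.int32))

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_CODES}

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels != UNLABELED))


@dataclass
class TrainingDataset:
    """Labeled spectra pooled across captures.

    spectra : (N, bands) pre-processed signatures
    labels  : (N,) class codes in {1, 2, 3, 4}
    groups  : (N,) subject identifiers, for grouped cross-validation
    subtypes: optional (N,) free-text annotation (e.g. tumor histology)
    """

    spectra: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    subtypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n = len(self.spectra)
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("spectra, labels and groups must have equal length")
        if self.subtypes is not None and len(self.subtypes) != n:
            raise ValueError("subtypes length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_CODES}


def sam_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians within [0, pi].

    arccos of the cosine similarity; invariant to positive scaling of either
    argument.  Zero vectors have no direction and are rejected.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"spectra lengths differ: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("SAM undefined for a zero spectrum")
    cos = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(np.arccos(cos))


def sam_select(
    cube: HyperCube, ref: tuple[int, int], threshold: float
) -> np.ndarray:
    """Boolean mask of pixels within ``threshold`` radians of the reference pixel.

    The reference pixel itself is always selected; all-zero pixels never are
    (their angle is undefined).
    """
    row, col = ref
    if not (0 <= row < cube.rows and 0 <= col < cube.cols):
        raise ValueError(f"reference pixel {ref} outside {cube.rows}x{cube.cols}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    r = cube.data[row, col, :].astype(float)
    nr = np.linalg.norm(r)
    if nr == 0:
        raise ValueError("reference pixel has an all-zero spectrum")
    flat = cube.flatten_spectra()
    norms = np.linalg.norm(flat, axis=1)
    nonzero = norms > 0
    cos = np.zeros(len(flat))
    cos[nonzero] = flat[nonzero] @ r / (norms[nonzero] * nr)
    angles = np.arccos(np.clip(cos, -1.0, 1.0))
    mask = nonzero & (angles <= threshold)
    mask = mask.reshape(cube.rows, cube.cols)
    mask[row, col] = True
    return mask


def assign_class(
    gold: GoldStandardMap,
    mask: np.ndarray,
    class_code: int,
    overwrite: bool = False,
    note: str = "",
) -> GoldStandardMap:
    """Set masked pixels to ``class_code``, returning a new map.

    Overwriting pixels that already carry a different non-zero label requires
    ``overwrite=True``; otherwise the conflict is an error (labels are meant
    to be small sets of very reliable pixels, so silent overwrites are a bug).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gold.labels.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {gold.labels.shape}")
    if class_code not in CLASS_CODES:
        raise ValueError(f"class_code must be one of {CLASS_CODES}")
    conflict = mask & (gold.labels != UNLABELED) & (gold.labels != class_code)
    if conflict.any() and not overwrite:
        raise ValueError(
            f"{int(conflict.sum())} pixels already labeled; pass overwrite=True"
        )
    labels = gold.labels.copy()
    labels[mask] = class_code
    prov = list(gold.provenance)
    prov.append(
        f"{CLASS_NAMES[class_code]}: {int(mask.sum())} px"
        + (f" ({note})" if note else "")
    )
    return GoldStandardMap(labels, prov)


def assemble_dataset(
    pairs: list[tuple[HyperCube, GoldStandardMap, object]],
) -> TrainingDataset:
    """Stack the labeled pixels of (cube, map, subject_id) triples into a dataset.

    One row per labeled pixel; unlabeled pixels never appear.  Cubes must all
    share a band count (use the same pre-processing chain throughout).
    """
    spectra, labels, groups = [], [], []
    for cube, gold, subject in pairs:
        if gold.labels.shape != (cube.rows, cube.cols):
            raise ValueError(
                f"map shape {gold.labels.shape} != cube shape "
                f"{(cube.rows, cube.cols)}"
            )
        sel = gold.labels != UNLABELED
        spectra.append(cube.data[sel])
        labels.append(gold.labels[sel])
        groups.append(np.full(int(sel.sum()), subject, dtype=object))
    if not spectra or sum(len(s) for s in spectra) == 0:
        raise ValueError("no labeled pixels in any input pair")
    return TrainingDataset(
        np.concatenate(spectra), np.concatenate(labels), np.concatenate(groups)
    )


def dataset_summary(ds: TrainingDataset) -> pd.DataFrame:
    """Per-class (and per-subtype where annotated) pixel counts with a total row.

    The Total row's count always equals N — labeled pixels are conserved.
    """
    records = []
    for code in CLASS_CODES:
        in_class = ds.labels == code
        n = int(in_class.sum())
        if n == 0:
            continue
        if ds.subtypes is not None:
            subs = np.asarray(ds.subtypes)[in_class]
            named = subs[subs != ""] if subs.dtype.kind in "UO" else []
            if len(named):
                for sub in sorted(set(named.tolist())):
                    records.append(
                        {"class": CLASS_NAMES[code], "subtype": sub,
                         "pixels": int(np.sum(named == sub))}
                    )
                unnamed = n - len(named)
                if unnamed:
                    records.append({"class": CLASS_NAMES[code], "subtype": "",
                                    "pixels": unnamed})
                continue
        records.append({"class": CLASS_NAMES[code], "subtype": "", "pixels": n})
    records.append({"class": "total", "subtype": "", "pixels": len(ds)})
    return pd.DataFrame.from_records(records)


def save_dataset(ds: TrainingDataset, path) -> None:
    """Write a dataset as CSV: columns ``label``, ``group``, ``b000``..``bNNN``."""
    frame = pd.DataFrame(
        ds.spectra,
        columns=[f"b{j:03d}" for j in range(ds.spectra.shape[1])],
    )
    frame.insert(0, "group", ds.groups)
    frame.insert(0, "label", ds.labels)
    frame.to_csv(path, index=False)


def load_dataset(path) -> TrainingDataset:
    """Read a dataset written by :func:`save_dataset`."""
    frame = pd.read_csv(path)
    bands = [c for c in frame.columns if c.startswith("b")]
    return TrainingDataset(
        frame[bands].to_numpy(float),
        frame["label"].to_numpy(int),
        frame["group"].to_numpy(),
    )
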