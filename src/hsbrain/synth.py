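"""Synthetic intraoperative phantom scenes.

Generates raw pushbroom cubes with matching white/dark references and a
ground-truth label map, carrying the statistical structure the pipeline
assumes: four classes (normal parenchyma, a tumor blob, vessel curves, a
background ring) with smooth class-distinct spectral signatures, per-pixel
intra-subject spectral jitter, subject-level offsets, a smooth multiplicative
illumination field (folded into the white reference, as a real flat-field
capture would see it), additive sensor noise on raw digital numbers,
saturated specular pixels, and optional dead reference pixels.

Synthesis happens in the raw domain by inverting the flat-field relation —
raw = dark + (white - dark) * reflectance — so that the calibration stage is
genuinely exercised; with zero noise the calibration round trip is exact.

Ground-truth maps label only region interiors (each region eroded by a
margin), mirroring gold standards built from a few very reliable pixels
rather than exhaustive delineation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .calibration import ReferenceFrames
from .constants import BACKGROUND, NORMAL, TUMOR, UNLABELED, VESSEL
from .hsio import HyperCube
from .labeling import GoldStandardMap, TrainingDataset, sam_angle
from .preprocess import PreprocessConfig

__all__ = ["PhantomSpec", "Scene", "generate_endmembers", "generate_scene",
           "generate_dataset"]


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic scene.

    Spatial/spectral sizes default to a desk-scale analogue of a VNIR
    intraoperative capture: 128 x 128 pixels and 200 bands over 400-1000 nm
    (128 bands after the default pre-processing chain).  Amplitude fields are
    dimensionless reflectance fractions unless noted; sensor quantities are
    raw digital numbers (DN).
    """

    rows: int = 128
    cols: int = 128
    bands: int = 200
    wavelength_range_nm: tuple[float, float] = (400.0, 1000.0)
    # endmembers: sum-of-Gaussians in wavelength, class-specific draws
    n_gaussians: int = 4
    min_sam_separation: float = 0.15  # rad, pairwise, on reflectance spectra
    endmember_max_tries: int = 200
    # variability
    intra_jitter_sd: float = 0.02    # per-pixel smooth spectral jitter
    inter_subject_sd: float = 0.04   # subject-level smooth offset
    sensor_noise_sd: float = 8.0     # DN, additive on the raw scene
    # sensor / illumination
    white_level_dn: float = 3000.0
    dark_level_dn: float = 96.0
    saturation_dn: float = 4095.0
    illumination_amplitude: float = 0.2  # relative swing of the smooth gain field
    specular_fraction: float = 0.002
    dead_pixel_fraction: float = 0.0     # reference columns with white == dark
    # layout (fractions of the image size unless stated)
    background_ring_px: int = 10
    tumor: bool = True
    tumor_center: tuple[float, float] = (0.42, 0.58)
    tumor_radius: float = 0.14
    vessels: bool = True
    vessel_width_px: int = 2
    boundary_margin_px: int = 2

    def __post_init__(self) -> None:
        for name in ("intra_jitter_sd", "inter_subject_sd", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("specular_fraction", "dead_pixel_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.wavelength_range_nm
        if not lo < hi:
            raise ValueError("wavelength range must be increasing")


@dataclass
class Scene:
    """One synthetic capture: raw cube, references, truth, and the clean field."""

    raw: HyperCube
    refs: ReferenceFrames
    truth: GoldStandardMap
    #: noise-free percent-reflectance field the raw cube encodes
    reflectance_percent: np.ndarray
    #: full class layout including boundary pixels left unlabeled in `truth`
    class_map: np.ndarray
    spec: PhantomSpec


def _wavelengths(spec: PhantomSpec) -> np.ndarray:
    lo, hi = spec.wavelength_range_nm
    return np.linspace(lo, hi, spec.bands)


def _smooth_basis(bands: int, n_curves: int) -> np.ndarray:
    """(n_curves, bands) unit-peak Gaussian bumps spread over the axis."""
    t = np.linspace(0.0, 1.0, bands)
    centers = np.linspace(0.1, 0.9, n_curves)
    width = 0.35 / n_curves + 0.06
    return np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * width**2))


def generate_endmembers(spec: PhantomSpec, seed: int = 0) -> np.ndarray:
    """Draw four smooth, non-negative class spectra (reflectance fraction).

    Each endmember is a baseline plus a sum of Gaussian bumps in wavelength;
    draws are rejected until every class pair is at least
    ``spec.min_sam_separation`` radians apart in spectral angle.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, spec.bands)
    for _ in range(spec.endmember_max_tries):
        ems = []
        for _cls in range(4):
            base = rng.uniform(0.05, 0.25)
            curve = np.full(spec.bands, base)
            for _ in range(spec.n_gaussians):
                amp = rng.uniform(0.1, 0.6)
                mean = rng.uniform(0.0, 1.0)
                width = rng.uniform(0.05, 0.25)
                curve = curve + amp * np.exp(-((t - mean) ** 2) / (2 * width**2))
            curve = np.clip(curve, 0.02, None)
            curve = 0.05 + 0.8 * curve / curve.max()
            ems.append(curve)
        ems = np.array(ems)
        angles = [sam_angle(ems[i], ems[j])
                  for i in range(4) for j in range(i + 1, 4)]
        if min(angles) >= spec.min_sam_separation:
            return ems
    raise RuntimeError(
        f"could not draw endmembers {spec.min_sam_separation} rad apart in "
        f"{spec.endmember_max_tries} tries"
    )


def _class_layout(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.rows, spec.cols
    layout = np.full((rows, cols), NORMAL, dtype=np.int32)
    ring = spec.background_ring_px
    if ring > 0:
        layout[:ring, :] = BACKGROUND
        layout[-ring:, :] = BACKGROUND
        layout[:, :ring] = BACKGROUND
        layout[:, -ring:] = BACKGROUND
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.vessels:
        # two sinuous curves through the parenchyma
        for phase, r0 in ((0.0, 0.35), (1.5, 0.68)):
            centre = r0 * rows + 0.06 * rows * np.sin(
                2 * np.pi * (cc / cols) * rng.uniform(1.2, 1.8) + phase
            )
            vessel = np.abs(rr - centre) <= spec.vessel_width_px
            layout[vessel & (layout == NORMAL)] = VESSEL
    if spec.tumor:
        r0 = spec.tumor_center[0] * rows
        c0 = spec.tumor_center[1] * cols
        rad = spec.tumor_radius * min(rows, cols)
        blob = ((rr - r0) ** 2 + (cc - c0) ** 2) <= rad**2
        layout[blob] = TUMOR
    return layout


def _truth_from_layout(layout: np.ndarray, margin: int,
                       unlabeled_extra: np.ndarray | None = None) -> np.ndarray:
    truth = np.full(layout.shape, UNLABELED, dtype=np.int32)
    for code in (NORMAL, TUMOR, VESSEL, BACKGROUND):
        region = layout == code
        # vessels are only a few pixels wide; a full-width erosion would
        # erase them, so their margin is capped at one pixel
        eff = min(margin, 1) if code == VESSEL else margin
        if eff > 0:
            region = binary_erosion(region, iterations=eff)
        truth[region] = code
    if unlabeled_extra is not None:
        truth[unlabeled_extra] = UNLABELED
    return truth


def generate_scene(
    spec: PhantomSpec,
    seed: int = 0,
    endmembers: np.ndarray | None = None,
    name: str = "phantom",
) -> Scene:
    """Synthesize one raw capture with references and a ground-truth map.

    ``endmembers`` may be supplied (e.g. subject-specific spectra from
    :func:`generate_dataset`); by default they are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    wl = _wavelengths(spec)
    if endmembers is None:
        endmembers = generate_endmembers(spec, seed)
    endmembers = np.asarray(endmembers, dtype=float)
    if endmembers.shape != (4, spec.bands):
        raise ValueError(f"endmembers must be 4 x {spec.bands}")

    layout = _class_layout(spec, rng)
    rows, cols, bands = spec.rows, spec.cols, spec.bands
    n_pixels = rows * cols

    # per-pixel smooth spectral jitter: low-dim Gaussian loadings on a smooth basis
    basis = _smooth_basis(bands, 5)
    loadings = rng.normal(0.0, spec.intra_jitter_sd, size=(n_pixels, 5))
    jitter = 1.0 + loadings @ basis
    class_idx = layout.ravel() - 1  # codes 1..4 -> rows 0..3
    refl = endmembers[class_idx] * jitter
    refl = np.clip(refl, 0.005, None).reshape(rows, cols, bands)

    # illumination gain: smooth multiplicative field, mean ~1, folded into white
    rr, cc = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols),
                         indexing="ij")
    gain = 1.0 + spec.illumination_amplitude * (
        0.6 * np.cos(np.pi * (rr - 0.5)) * np.cos(np.pi * (cc - 0.5)) - 0.3
    )
    # white tile spectrum: bright, gently curved across the axis
    t = np.linspace(0.0, 1.0, bands)
    white_spectrum = spec.white_level_dn * (0.75 + 0.25 * np.exp(
        -((t - 0.45) ** 2) / 0.18))
    white = gain[:, :, None] * white_spectrum[None, None, :]
    dark = np.full((rows, cols, bands), spec.dark_level_dn)

    if spec.dead_pixel_fraction > 0:
        n_dead = int(round(spec.dead_pixel_fraction * n_pixels))
        flat = rng.choice(n_pixels, size=n_dead, replace=False)
        white.reshape(n_pixels, bands)[flat] = spec.dark_level_dn
    refs = ReferenceFrames(white=white, dark=dark)

    raw = dark + (white - dark) * refl
    if spec.sensor_noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.sensor_noise_sd, size=raw.shape)

    specular = np.zeros((rows, cols), dtype=bool)
    if spec.specular_fraction > 0:
        interior = layout != BACKGROUND
        candidates = np.nonzero(interior.ravel())[0]
        n_spec = int(round(spec.specular_fraction * len(candidates)))
        if n_spec:
            hit = rng.choice(candidates, size=n_spec, replace=False)
            specular.ravel()[hit] = True
            raw.reshape(n_pixels, bands)[hit] = spec.saturation_dn

    raw = np.clip(raw, 0.0, spec.saturation_dn)
    truth = _truth_from_layout(layout, spec.boundary_margin_px,
                               unlabeled_extra=specular)
    cube = HyperCube(raw, wl, units="raw", name=name)
    return Scene(
        raw=cube,
        refs=refs,
        truth=GoldStandardMap(truth, provenance=[f"synthetic phantom seed={seed}"]),
        reflectance_percent=100.0 * refl,
        class_map=layout,
        spec=spec,
    )


def _subject_endmembers(base: np.ndarray, spec: PhantomSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Apply a subject-level smooth multiplicative offset to the base spectra."""
    basis = _smooth_basis(base.shape[1], 4)
    loadings = rng.normal(0.0, spec.inter_subject_sd, size=(4, 4))
    return np.clip(base * (1.0 + loadings @ basis), 0.005, None)


def generate_dataset(
    spec: PhantomSpec,
    n_subjects: int,
    seed: int = 0,
    n_holdout: int = 1,
    max_per_class: int = 400,
    preprocess_config: PreprocessConfig | None = None,
    holdout_spec: PhantomSpec | None = None,
) -> tuple[TrainingDataset, list[Scene]]:
    """Build a multi-subject training dataset plus held-out scenes.

    Each subject receives its own endmember offsets (inter-subject
    variability) and one capture; labeled pixels are calibrated, pushed
    through the pre-processing chain and subsampled to at most
    ``max_per_class`` rows per class per subject.  ``n_holdout`` additional
    subjects are generated as full scenes and returned unlabeled-rowwise for
    end-to-end evaluation.  ``holdout_spec`` lets the held-out captures use a
    different layout (e.g. tumor-free negative controls) while sharing the
    training population's spectral statistics.
    """
    from .calibration import calibrate
    from .preprocess import preprocess

    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    if preprocess_config is None:
        preprocess_config = PreprocessConfig()
    root = np.random.SeedSequence(seed)
    subject_seeds = root.generate_state(n_subjects + n_holdout + 1) % (2**31)
    base = generate_endmembers(spec, int(subject_seeds[-1]))

    spectra, labels, groups = [], [], []
    for s in range(n_subjects):
        s_seed = int(subject_seeds[s])
        rng = np.random.default_rng(s_seed)
        ems = _subject_endmembers(base, spec, rng)
        scene = generate_scene(spec, seed=s_seed, endmembers=ems,
                               name=f"subject{s}")
        cal = calibrate(scene.raw, scene.refs)
        pp = preprocess(cal.cube, preprocess_config)
        flat = pp.flatten_spectra()
        truth = scene.truth.labels.ravel()
        for code in (NORMAL, TUMOR, VESSEL, BACKGROUND):
            members = np.nonzero(truth == code)[0]
            if len(members) == 0:
                continue
            if len(members) > max_per_class:
                members = rng.choice(members, size=max_per_class, replace=False)
            spectra.append(flat[members])
            labels.append(np.full(len(members), code))
            groups.append(np.full(len(members), s))
    ds = TrainingDataset(np.concatenate(spectra), np.concatenate(labels),
                         np.concatenate(groups))
    holdouts = []
    h_spec = holdout_spec if holdout_spec is not None else spec
    for h in range(n_holdout):
        h_seed = int(subject_seeds[n_subjects + h])
        rng = np.random.default_rng(h_seed)
        ems = _subject_endmembers(base, spec, rng)
        holdouts.append(generate_scene(h_spec, seed=h_seed, endmembers=ems,
                                       name=f"holdout{h}"))
    return ds, holdouts
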