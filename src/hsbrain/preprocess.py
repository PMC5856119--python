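"""Spectral pre-processing chain: clip -> smooth -> downsample -> normalize.

The chain homogenizes spectral signatures before classification and
clustering: noisy sensor extremes are clipped away, spectra are denoised
along the band axis, dimensionality is reduced by contiguous band averaging,
and per-pixel normalization removes illumination-driven amplitude so that
classifiers see spectral shape rather than brightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .hsio import HyperCube

__all__ = [
    "PreprocessConfig",
    "clip_bands",
    "smooth_spectra",
    "downsample_bands",
    "normalize_spectra",
    "preprocess",
]

logger = logging.getLogger(__name__)

MOVING_AVERAGE = "moving_average"
SAVITZKY_GOLAY = "savitzky_golay"
NORM_MODES = ("none", "unit_max", "unit_area", "standardize")


@dataclass
class PreprocessConfig:
    """Configuration of the pre-processing chain.

    Defaults: keep 450-900 nm (drops the noisy sensor extremes of a
    400-1000 nm VNIR axis), moving-average smoothing with a 5-band window,
    reduction to 128 bands, unit-max normalization (illumination-invariant
    spectral shape, and leaves spectral angles unchanged).
    """

    keep_range_nm: tuple[float, float] = (450.0, 900.0)
    smooth_window: int = 5
    smooth_kind: str = MOVING_AVERAGE
    target_bands: int | None = 128
    normalize: str = "unit_max"

    def __post_init__(self) -> None:
        lo, hi = self.keep_range_nm
        if not lo < hi:
            raise ValueError("keep_range_nm must satisfy low < high")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")
        if self.smooth_kind not in (MOVING_AVERAGE, SAVITZKY_GOLAY):
            raise ValueError(f"unknown smooth_kind {self.smooth_kind!r}")
        if self.normalize not in NORM_MODES:
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


def clip_bands(cube: HyperCube, low_nm: float, high_nm: float) -> HyperCube:
    """Keep only bands with wavelength in [low_nm, high_nm]."""
    keep = (cube.wavelengths >= low_nm) & (cube.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(
            f"no bands in [{low_nm}, {high_nm}] nm; cube covers "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return HyperCube(cube.data[:, :, keep], cube.wavelengths[keep],
                     units=cube.units, name=cube.name)


def smooth_spectra(cube: HyperCube, window: int, kind: str = MOVING_AVERAGE) -> HyperCube:
    """Filter each pixel's spectrum along the band axis with edge replication.

    ``window=1`` is the identity.  ``savitzky_golay`` uses a quadratic fit
    (order min(2, window-1)).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > cube.bands:
        raise ValueError(f"window {window} exceeds band count {cube.bands}")
    if window == 1:
        return HyperCube(cube.data.copy(), cube.wavelengths, units=cube.units,
                         name=cube.name)
    if kind == MOVING_AVERAGE:
        out = uniform_filter1d(cube.data, size=window, axis=2, mode="nearest")
    elif kind == SAVITZKY_GOLAY:
        out = savgol_filter(cube.data, window_length=window,
                            polyorder=min(2, window - 1), axis=2,
                            mode="nearest")
    else:
        raise ValueError(f"unknown smoothing kind {kind!r}")
    return HyperCube(out, cube.wavelengths, units=cube.units, name=cube.name)


def downsample_bands(cube: HyperCube, target_bands: int) -> HyperCube:
    """Average contiguous band groups down to ``target_bands`` bands.

    Groups are near-equal contiguous runs; each output band is the arithmetic
    mean of its group's values, its wavelength the mean of the group's
    wavelengths (so the axis stays strictly increasing).
    """
    if not 1 <= target_bands <= cube.bands:
        raise ValueError(
            f"target_bands must be in [1, {cube.bands}], got {target_bands}"
        )
    if target_bands == cube.bands:
        return HyperCube(cube.data.copy(), cube.wavelengths, units=cube.units,
                         name=cube.name)
    edges = np.array_split(np.arange(cube.bands), target_bands)
    data = np.stack([cube.data[:, :, g].mean(axis=2) for g in edges], axis=2)
    wl = np.array([cube.wavelengths[g].mean() for g in edges])
    return HyperCube(data, wl, units=cube.units, name=cube.name)


def normalize_spectra(
    cube: HyperCube, mode: str
) -> tuple[HyperCube, np.ndarray]:
    """Per-pixel spectral normalization.

    Modes: ``unit_max`` scales each spectrum to max 1, ``unit_area`` to sum 1,
    ``standardize`` to mean 0 / sd 1, ``none`` is the identity.  Degenerate
    spectra (all-zero, or zero sd for standardize) are left unchanged and
    flagged in the returned rows x cols boolean mask.
    """
    if mode not in NORM_MODES:
        raise ValueError(f"unknown normalize mode {mode!r}")
    data = cube.data.astype(float).copy()
    flagged = np.zeros(data.shape[:2], dtype=bool)
    if mode == "none":
        pass
    elif mode == "unit_max":
        peak = data.max(axis=2)
        flagged = peak == 0
        safe = np.where(flagged, 1.0, peak)
        data = data / safe[:, :, None]
        data[flagged] = cube.data[flagged]
    elif mode == "unit_area":
        total = data.sum(axis=2)
        flagged = total == 0
        safe = np.where(flagged, 1.0, total)
        data = data / safe[:, :, None]
        data[flagged] = cube.data[flagged]
    else:  # standardize
        mean = data.mean(axis=2)
        sd = data.std(axis=2)
        flagged = sd == 0
        safe = np.where(flagged, 1.0, sd)
        data = (data - mean[:, :, None]) / safe[:, :, None]
        data[flagged] = cube.data[flagged]
    out = HyperCube(data, cube.wavelengths, units=cube.units, name=cube.name)
    return out, flagged


def preprocess(cube: HyperCube, config: PreprocessConfig | None = None) -> HyperCube:
    """Apply the full chain in fixed order: clip, smooth, downsample, normalize."""
    if config is None:
        config = PreprocessConfig()
    lo, hi = config.keep_range_nm
    logger.info("preprocess chain: clip[%g,%g] -> smooth(%s,%d) -> "
                "downsample(%s) -> normalize(%s)", lo, hi, config.smooth_kind,
                config.smooth_window, config.target_bands, config.normalize)
    out = clip_bands(cube, lo, hi)
    out = smooth_spectra(out, config.smooth_window, config.smooth_kind)
    if config.target_bands is not None:
        if config.target_bands > out.bands:
            raise ValueError(
                f"target_bands {config.target_bands} exceeds {out.bands} bands "
                "remaining after clipping"
            )
        out = downsample_bands(out, config.target_bands)
    out, _ = normalize_spectra(out, config.normalize)
    return out
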