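"""White/dark reference reflectance calibration.

Raw digital numbers are converted to percent reflectance by flat-fielding
against a white reference (a ~99%-reflective tile captured in the operating
illumination) and a dark reference (shutter closed):

    reflectance = 100 * (raw - dark) / (white - dark)

For a pushbroom camera the references may be a single line (1 x cols x bands)
that is broadcast along the scan axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsio import RAW, REFLECTANCE_PERCENT, HyperCube

__all__ = ["ReferenceFrames", "CalibrationResult", "ReferenceReport",
           "calibrate", "validate_references"]


@dataclass
class ReferenceFrames:
    """White and dark reference captures sharing the raw cube's band axis.

    ``white`` and ``dark`` are (rows x cols x bands) or (1 x cols x bands)
    raw-DN arrays of identical shape; a single reference line is replicated
    along the scan axis at calibration time.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.ndim != 3 or self.dark.ndim != 3:
            raise ValueError("reference frames must be 3-D (rows, cols, bands)")
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white {self.white.shape} and dark {self.dark.shape} shapes differ"
            )

    @property
    def bands(self) -> int:
        return self.white.shape[2]


@dataclass
class CalibrationResult:
    """Calibrated cube plus the mask of pixels with unusable references."""

    cube: HyperCube
    #: True where white == dark in at least one band (output forced to 0 there).
    invalid_mask: np.ndarray
    #: True where calibrated reflectance exceeds 100% in any band (specular
    #: highlights; kept, not clipped — bright pixels must stay classifiable).
    specular_mask: np.ndarray


@dataclass
class ReferenceReport:
    fraction_invalid: float
    mean_white_spectrum: np.ndarray
    #: band indices where mean(white - dark) falls below the floor
    weak_bands: list


def calibrate(raw: HyperCube, refs: ReferenceFrames) -> CalibrationResult:
    """Convert a raw cube to percent reflectance.

    Where ``white == dark`` the quotient is undefined; those samples are set
    to 0 and the pixel flagged in ``invalid_mask``.  Negative values (sensor
    noise driving raw below dark) are clipped to 0.  Values above 100
    (specular highlights) are kept and flagged.
    """
    if raw.units != RAW:
        raise ValueError(f"cube units must be {RAW!r}, got {raw.units!r}")
    if refs.bands != raw.bands:
        raise ValueError(
            f"reference band count {refs.bands} != cube band count {raw.bands}"
        )
    if refs.white.shape[0] not in (1, raw.rows) or refs.white.shape[1] != raw.cols:
        raise ValueError(
            f"reference shape {refs.white.shape} not broadcastable to {raw.shape}"
        )
    denom = refs.white - refs.dark
    if not np.any(denom != 0):
        raise ValueError("references unusable: white == dark everywhere")
    bad = denom == 0
    safe = np.where(bad, 1.0, denom)
    beta = 100.0 * (raw.data - refs.dark) / safe
    beta = np.where(np.broadcast_to(bad, beta.shape), 0.0, beta)
    beta = np.maximum(beta, 0.0)
    cube = HyperCube(beta, raw.wavelengths, units=REFLECTANCE_PERCENT,
                     name=raw.name)
    invalid = np.broadcast_to(bad, beta.shape).any(axis=2)
    specular = (beta > 100.0).any(axis=2)
    return CalibrationResult(cube, invalid, specular)


def validate_references(
    refs: ReferenceFrames, floor: float = 1.0
) -> ReferenceReport:
    """Sanity-check a reference pair before calibration.

    Reports the fraction of samples with ``white < dark`` (allowed up to
    noise but worth surfacing), the per-band mean white spectrum, and the
    bands whose mean dynamic range ``mean(white - dark)`` is below ``floor``
    DN (dead or starved bands that will amplify noise).
    """
    diff = refs.white - refs.dark
    fraction_invalid = float(np.mean(diff < 0))
    mean_white = refs.white.reshape(-1, refs.bands).mean(axis=0)
    band_range = diff.reshape(-1, refs.bands).mean(axis=0)
    weak = [int(b) for b in np.nonzero(band_range < floor)[0]]
    return ReferenceReport(fraction_invalid, mean_white, weak)
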