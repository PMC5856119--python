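"""Hypercube and label-raster I/O plus acquisition-geometry helpers.

A hypercube is a rows x cols x bands array with a strictly increasing
wavelength axis (nm).  Interchange format is the ENVI dialect: a plain-text
``.hdr`` key=value header next to a flat binary raster, band-sequential by
default, which is what pushbroom camera tooling emits.

Conventions: 0-based indices, row-major ``(row, col, band)``, origin top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperCube",
    "RGBImage",
    "read_envi_cube",
    "write_envi_cube",
    "read_envi_labels",
    "write_envi_labels",
    "band_index",
    "synthetic_rgb",
    "spatial_extent_mm",
]

RAW = "raw"
REFLECTANCE_PERCENT = "reflectance_percent"

# ENVI data-type codes <-> numpy dtypes (unsupported codes rejected on read).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A hyperspectral image: two spatial axes and one spectral axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Non-negative raw digital numbers or percent reflectance.  Calibrated
        specular pixels may legitimately exceed 100.
    wavelengths : ndarray, shape (bands,)
        Band-centre wavelengths in nm, strictly increasing.
    units : str
        ``"raw"`` or ``"reflectance_percent"``.
    name : str
        Free-text identifier carried through the pipeline.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = RAW
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        rows, cols, bands = self.data.shape
        if rows < 1 or cols < 1 or bands < 2:
            raise ValueError(
                f"cube needs rows>=1, cols>=1, bands>=2; got {self.data.shape}"
            )
        if len(self.wavelengths) != bands:
            raise ValueError(
                f"{len(self.wavelengths)} wavelengths for {bands} bands"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.units not in (RAW, REFLECTANCE_PERCENT):
            raise ValueError(f"unknown units flag {self.units!r}")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel(self, row: int, col: int) -> np.ndarray:
        """Spectrum of one pixel (a bands-length view)."""
        return self.data[row, col, :]

    def flatten_spectra(self) -> np.ndarray:
        """All spectra as an (rows*cols, bands) matrix, row-major pixel order."""
        return self.data.reshape(-1, self.bands)


@dataclass
class RGBImage:
    """A rows x cols x 3 colour image with values in [0, 1]."""

    data: np.ndarray = field()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"RGB image must be rows x cols x 3, got {self.data.shape}")
        self.data = np.clip(self.data, 0.0, 1.0)

    def save_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), (self.data * 255).round().astype(np.uint8))


# ---------------------------------------------------------------------------
# ENVI header + raster


def _parse_envi_header(header_path: Path) -> dict:
    text = header_path.read_text()
    # Collapse { ... } blocks (possibly multi-line) before splitting on lines.
    fields: dict[str, str] = {}
    i = 0
    lines = text.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            while i < len(lines) and "}" not in lines[i]:
                parts.append(lines[i].strip())
                i += 1
            if i < len(lines):
                parts.append(lines[i].strip())
                i += 1
            value = " ".join(parts)
        fields[key] = value
    return fields


def _brace_list(value: str) -> list[str]:
    return [v.strip() for v in value.strip().strip("{}").split(",") if v.strip()]


def _find_data_file(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    candidates = [stem, stem.with_suffix(".img"), stem.with_suffix(".raw"),
                  stem.with_suffix(".dat")]
    for cand in candidates:
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(
        f"no raster next to {header_path} (tried {[c.name for c in candidates]})"
    )


def _read_envi_array(header_path: Path) -> tuple[np.ndarray, dict]:
    header_path = Path(header_path)
    hdr = _parse_envi_header(header_path)
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in hdr:
            raise ValueError(f"ENVI header missing required key {key!r}")
    cols = int(hdr["samples"])
    rows = int(hdr["lines"])
    bands = int(hdr["bands"])
    code = int(hdr["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    byte_order = int(hdr.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(hdr.get("header offset", 0))
    interleave = hdr["interleave"].strip().lower()

    data_file = _find_data_file(header_path)
    expected = rows * cols * bands * dtype.itemsize + offset
    actual = data_file.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{data_file} is {actual} bytes but header implies {expected} "
            f"({rows}x{cols}x{bands} {dtype})"
        )
    flat = np.fromfile(data_file, dtype=dtype, offset=offset)
    if interleave == "bsq":
        arr = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = flat.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return np.ascontiguousarray(arr), hdr


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header + raster pair into a :class:`HyperCube`.

    The header must carry a ``wavelength`` list whose length equals ``bands``.
    BSQ, BIL and BIP interleaves and both byte orders are supported.
    """
    header_path = Path(header_path)
    arr, hdr = _read_envi_array(header_path)
    if "wavelength" not in hdr:
        raise ValueError("ENVI header has no 'wavelength' list")
    wavelengths = np.array([float(v) for v in _brace_list(hdr["wavelength"])])
    if len(wavelengths) != arr.shape[2]:
        raise ValueError(
            f"header lists {len(wavelengths)} wavelengths for {arr.shape[2]} bands"
        )
    units = hdr.get("hsbrain units", RAW)
    name = hdr.get("description", "").strip("{} ") or header_path.stem
    return HyperCube(arr.astype(np.float64), wavelengths, units=units, name=name)


def write_envi_cube(
    cube: HyperCube,
    header_path: str | Path,
    dtype: np.dtype | type = np.float64,
    interleave: str = "bsq",
) -> Path:
    """Write a cube as ENVI header + raster; returns the raster path.

    The raster goes next to the header with an ``.img`` suffix.  The cube's
    units flag is persisted in a ``hsbrain units`` header field so round trips
    preserve it.
    """
    header_path = Path(header_path)
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data = cube.data.astype(dtype)
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    data_path = header_path.with_suffix(".img")
    ordered.astype(dtype.newbyteorder("<")).tofile(data_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"description = {{{cube.name}}}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"hsbrain units = {cube.units}\n"
        f"wavelength = {{{wl}}}\n"
    )
    return data_path


def read_envi_labels(header_path: str | Path) -> np.ndarray:
    """Read a single-band integer label raster written by :func:`write_envi_labels`."""
    arr, _ = _read_envi_array(Path(header_path))
    if arr.shape[2] != 1:
        raise ValueError(f"label raster must be single-band, got {arr.shape[2]} bands")
    return arr[:, :, 0].astype(np.int32)


def write_envi_labels(labels: np.ndarray, header_path: str | Path) -> Path:
    """Write a rows x cols integer label map as a single-band ENVI raster."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".img")
    labels.astype("<i4").tofile(data_path)
    header_path.write_text(
        "ENVI\n"
        "description = {label map}\n"
        f"samples = {labels.shape[1]}\n"
        f"lines = {labels.shape[0]}\n"
        "bands = 1\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 3\n"
        "interleave = bsq\n"
        "byte order = 0\n"
    )
    return data_path


# ---------------------------------------------------------------------------
# Wavelength and geometry helpers


def band_index(cube: HyperCube, target_nm: float) -> int:
    """Index of the band whose centre wavelength is closest to ``target_nm``.

    Ties break to the lower index.  Targets outside the wavelength range by
    more than half the edge inter-band spacing are rejected.
    """
    wl = cube.wavelengths
    lo_margin = (wl[1] - wl[0]) / 2.0
    hi_margin = (wl[-1] - wl[-2]) / 2.0
    if target_nm < wl[0] - lo_margin or target_nm > wl[-1] + hi_margin:
        raise ValueError(
            f"target {target_nm} nm outside wavelength range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    return int(np.argmin(np.abs(wl - target_nm)))


def synthetic_rgb(
    cube: HyperCube, nm_triplet: tuple[float, float, float] | None = None
) -> RGBImage:
    """Build a display RGB image from three chosen bands.

    Each channel is the band nearest the requested wavelength, min-max
    rescaled to [0, 1] on its own; a constant band maps to an all-zero
    channel.  Default triplet is the VNIR red/green/blue choice
    (708.97, 539.44, 479.06 nm).
    """
    from .constants import VNIR_RGB_TRIPLET_NM

    if nm_triplet is None:
        nm_triplet = VNIR_RGB_TRIPLET_NM
    channels = []
    for nm in nm_triplet:
        band = cube.data[:, :, band_index(cube, nm)].astype(float)
        lo, hi = band.min(), band.max()
        if hi > lo:
            channels.append((band - lo) / (hi - lo))
        else:
            channels.append(np.zeros_like(band))
    return RGBImage(np.stack(channels, axis=-1))


def spatial_extent_mm(n_pixels: int, pixel_pitch_um: float) -> int:
    """Physical extent of ``n_pixels`` at ``pixel_pitch_um`` µm/pixel, in whole mm.

    Rounding is half-up to the nearest millimetre, e.g. 1787 px at 128.7 µm
    is 229.99 mm -> 230 mm.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be > 0")
    return int(math.floor(n_pixels * pixel_pitch_um / 1000.0 + 0.5))
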