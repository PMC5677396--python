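"""Hyperspectral cube I/O, reflectance correction and ROI extraction.

A cube is a rows x cols x bands array where every pixel carries a full
reflectance spectrum.  Cubes travel as ENVI pairs: a plain-text ``.hdr``
(key = value dialect with a ``wavelength = {...}`` block) next to a flat
binary raster in BSQ, BIL or BIP interleave.

Raw camera frames are converted to percent reflectance against white and
dark reference frames::

    I = (I0 - D) / (W - D) * 100

where ``I0`` is the raw sample cube, ``W`` the white-tile reference and
``D`` the closed-shutter dark current.  Reflectance is kept on the 0-100
scale throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperspectralCube",
    "RawFrames",
    "ROISpec",
    "read_envi",
    "write_envi",
    "correct_reflectance",
    "synthesize_raw_frames",
    "crop_roi",
    "centered_roi",
]

# ENVI numeric codes for the dtypes this package reads/writes.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperspectralCube:
    """rows x cols x bands reflectance (%) or raw digital numbers.

    ``wavelengths`` holds the band centres in nm, strictly increasing.
    ``kind`` distinguishes raw digital numbers from corrected reflectance.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "corrected"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.values.shape}")
        if any(d < 1 for d in self.values.shape):
            raise ValueError(f"cube dimensions must be >= 1, got {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "corrected"):
            raise ValueError(f"kind must be 'raw' or 'corrected', got {self.kind!r}")
        if self.kind == "corrected" and not np.all(np.isfinite(self.values)):
            raise ValueError("corrected cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RawFrames:
    """Raw sample cube plus white/dark reference frames.

    White/dark may be full cubes or single-line ``1 x cols x bands``
    references (push-broom line scan) broadcast across rows.
    """

    i0: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.i0 = np.asarray(self.i0, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.i0.ndim != 3:
            raise ValueError("raw cube must be 3-D (rows x cols x bands)")
        try:
            np.broadcast_shapes(self.i0.shape, self.white.shape, self.dark.shape)
        except ValueError as exc:
            raise ValueError(
                f"white/dark shapes {self.white.shape}/{self.dark.shape} do not "
                f"broadcast to raw cube {self.i0.shape}"
            ) from exc


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based, half-open in both axes."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI height/width must be >= 1, got {self.height}x{self.width}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")


def _parse_header(text: str) -> dict:
    """Parse the ENVI key = value dialect, joining {...} blocks."""
    # collapse brace blocks that span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | Path, raster_path: str | Path | None = None) -> HyperspectralCube:
    """Read an ENVI header + raster pair into a :class:`HyperspectralCube`.

    ``raster_path`` defaults to the header path with its ``.hdr`` suffix
    stripped.  The header must declare samples/lines/bands, an interleave in
    {bsq, bil, bip} and a wavelength block; mismatch between the declared
    dimensions and the raster size is an error.
    """
    header_path = Path(header_path)
    if raster_path is None:
        raster_path = header_path.with_suffix("")
    fields = _parse_header(header_path.read_text())

    for key in ("samples", "lines", "bands"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])

    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength block")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise ValueError("malformed wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace(",", " ").split()], dtype=float
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"wavelength count {len(wavelengths)} does not match bands {bands}"
        )

    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(raster_path, dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"raster holds {raw.size} values but header declares "
            f"{rows}x{cols}x{bands} = {expected}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        values = raw.reshape(rows, cols, bands)

    kind = fields.get("soilhsi kind", "corrected")
    return HyperspectralCube(values=values.astype(float), wavelengths=wavelengths, kind=kind)


def write_envi(
    cube: HyperspectralCube,
    header_path: str | Path,
    raster_path: str | Path | None = None,
    interleave: str = "bsq",
    dtype: np.dtype | type = np.float64,
) -> Path:
    """Write a cube as an ENVI header + raster pair; returns the raster path.

    float64 output is bit-exact on round trip; narrower dtypes quantize.
    """
    header_path = Path(header_path)
    if raster_path is None:
        raster_path = header_path.with_suffix("")
    raster_path = Path(raster_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported output dtype {dtype}")

    rows, cols, bands = cube.shape
    values = cube.values.astype(dtype)
    if interleave == "bsq":
        flat = values.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = values.transpose(0, 2, 1)
    else:
        flat = values
    flat.tofile(raster_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"soilhsi kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return raster_path


def correct_reflectance(frames: RawFrames) -> HyperspectralCube:
    """White/dark reflectance correction to percent reflectance.

    Applies ``I = (I0 - D)/(W - D) * 100`` per pixel per band.  Any pixel
    where the white and dark references coincide is a hard error (the
    correction would divide by zero) rather than a silent NaN.
    """
    denom = frames.white - frames.dark
    denom_b = np.broadcast_to(denom, frames.i0.shape)
    if np.any(denom_b == 0):
        n_bad = int(np.count_nonzero(denom_b == 0))
        raise ZeroDivisionError(
            f"white and dark references coincide at {n_bad} pixel/band positions"
        )
    corrected = (frames.i0 - frames.dark) / denom * 100.0
    wavelengths = frames.wavelengths
    if wavelengths is None:
        wavelengths = np.arange(frames.i0.shape[2], dtype=float)
    return HyperspectralCube(values=corrected, wavelengths=wavelengths, kind="corrected")


def synthesize_raw_frames(
    cube: HyperspectralCube, white: np.ndarray, dark: np.ndarray
) -> RawFrames:
    """Invert the reflectance correction: build raw frames that correct back
    to ``cube`` exactly (up to floating point), for testing the I/O path."""
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    i0 = cube.values / 100.0 * (white - dark) + dark
    return RawFrames(i0=i0, white=white, dark=dark, wavelengths=cube.wavelengths)


def crop_roi(cube: HyperspectralCube, roi: ROISpec) -> HyperspectralCube:
    """Crop a cube to the ROI rectangle; wavelengths are preserved."""
    rows, cols, _ = cube.shape
    if roi.row0 + roi.height > rows or roi.col0 + roi.width > cols:
        raise ValueError(
            f"ROI {roi} exceeds cube extent {rows}x{cols}"
        )
    values = cube.values[
        roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width, :
    ].copy()
    return HyperspectralCube(values=values, wavelengths=cube.wavelengths, kind=cube.kind)


def centered_roi(cube_or_shape, height: int, width: int) -> ROISpec:
    """ROI of the given size centred in the frame (floor on odd margins)."""
    if isinstance(cube_or_shape, HyperspectralCube):
        rows, cols = cube_or_shape.shape[:2]
    else:
        rows, cols = cube_or_shape[:2]
    if height > rows or width > cols:
        raise ValueError(f"ROI {height}x{width} larger than frame {rows}x{cols}")
    return ROISpec(row0=(rows - height) // 2, col0=(cols - width) // 2, height=height, width=width)
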