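"""Gray-level co-occurrence matrix (GLCM) texture features.

For each gray-scale ROI image at an effective wavelength, co-occurrence is
counted at a one-pixel offset in the four directions 0, 45, 90 and 135
degrees, accumulated symmetrically (both pair orderings) and normalised to
joint probabilities p(i, j).  Four statistics summarise each matrix::

    energy      = sum p(i,j)^2
    contrast    = sum (i-j)^2 p(i,j)
    homogeneity = sum p(i,j) / (1 + (i-j)^2)      (inverse difference moment)
    entropy     = -sum p(i,j) ln p(i,j),  0 ln 0 := 0

and the mean over the four directions is reported per wavelength, so k
effective wavelengths yield 4k texture features per sample.

Direction offsets in image coordinates (d(row), d(col)) at distance 1:
0 deg -> (0, +1); 45 deg -> (-1, +1); 90 deg -> (-1, 0); 135 deg -> (-1, -1).

Reflectance images are quantised per ROI by linear min-max scaling to L
gray levels (floor(v_norm * L), clipped to L-1; a constant image maps to
level 0).  L = 64 by default: enough gray resolution without starving the
co-occurrence counts on a 50 x 50 ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "GLCMConfig",
    "TextureStats",
    "DIRECTIONS_DEG",
    "quantize",
    "glcm",
    "glcm_stats",
    "texture_features",
]

DIRECTIONS_DEG = (0, 45, 90, 135)

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

STAT_NAMES = ("energy", "contrast", "homogeneity", "entropy")


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 64
    distance: int = 1
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


@dataclass(frozen=True)
class TextureStats:
    energy: float
    contrast: float
    homogeneity: float
    entropy: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.energy, self.contrast, self.homogeneity, self.entropy)


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantise a ROI image to integer gray levels 0..levels-1."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    norm = (image - lo) / (hi - lo)
    return np.minimum(np.floor(norm * levels).astype(np.intp), levels - 1)


def glcm(
    image: np.ndarray,
    direction_deg: int,
    distance: int = 1,
    levels: int | None = None,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Co-occurrence matrix of a quantised image at one direction/distance."""
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        raise TypeError("glcm expects a quantised integer image")
    if direction_deg not in _OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS_DEG}, got {direction_deg}")
    if levels is None:
        levels = int(image.max()) + 1
    if image.min() < 0 or image.max() >= levels:
        raise ValueError("image gray levels out of range for the requested matrix size")

    dr, dc = _OFFSETS[direction_deg]
    dr *= distance
    dc *= distance
    rows, cols = image.shape
    if rows <= abs(dr) or cols <= abs(dc):
        raise ValueError(
            f"image {rows}x{cols} too small for offset ({dr}, {dc})"
        )

    # reference pixel window and its displaced partner
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    a = image[r0:r1, c0:c1].ravel()
    b = image[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()

    P = np.zeros((levels, levels), dtype=float)
    np.add.at(P, (a, b), 1.0)
    if symmetric:
        np.add.at(P, (b, a), 1.0)
    if normalize:
        P /= P.sum()
    return P


def glcm_stats(P: np.ndarray) -> TextureStats:
    """The four texture statistics of a normalised GLCM."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"GLCM is not normalised (sum = {total})")
    L = P.shape[0]
    i, j = np.indices((L, L))
    d2 = (i - j) ** 2
    energy = float(np.sum(P**2))
    contrast = float(np.sum(d2 * P))
    homogeneity = float(np.sum(P / (1.0 + d2)))
    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log(P[nz])))
    return TextureStats(energy=energy, contrast=contrast, homogeneity=homogeneity, entropy=entropy)


def _band_index(stack_wavelengths: np.ndarray, wl: float) -> int:
    idx = np.flatnonzero(np.isclose(stack_wavelengths, wl, rtol=0, atol=1e-6))
    if idx.size == 0:
        raise ValueError(f"wavelength {wl} nm not present in the ROI stack")
    return int(idx[0])


def texture_features(
    stack: np.ndarray,
    stack_wavelengths: np.ndarray,
    effective_wavelengths: Iterable[float],
    config: GLCMConfig = GLCMConfig(),
) -> dict[str, float]:
    """Direction-averaged texture statistics at each effective wavelength.

    Returns an ordered mapping ``{stat}_{wavelength} -> value`` with
    4 x len(effective_wavelengths) entries, wavelength-major.
    """
    stack = np.asarray(stack, dtype=float)
    stack_wavelengths = np.asarray(stack_wavelengths, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != len(stack_wavelengths):
        raise ValueError("stack must be height x width x bands matching the wavelength vector")

    features: dict[str, float] = {}
    for wl in effective_wavelengths:
        band = _band_index(stack_wavelengths, float(wl))
        q = quantize(stack[:, :, band], config.levels)
        per_dir = np.array(
            [
                glcm_stats(
                    glcm(
                        q,
                        d,
                        distance=config.distance,
                        levels=config.levels,
                        symmetric=config.symmetric,
                        normalize=config.normalize,
                    )
                ).as_tuple()
                for d in DIRECTIONS_DEG
            ]
        )
        means = per_dir.mean(axis=0)
        for name, value in zip(STAT_NAMES, means):
            features[f"{name}_{float(wl):.1f}"] = float(value)
    return features
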