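"""Color-space transforms and vegetation-index planes on 8-bit RGB rasters.

All downstream drought features are computed from three derived
representations of the raw image:

* chromaticity-normalized planes ``Nr = R/(R+G+B)`` (and likewise Ng, Nb),
* the excess-green index ``ExG = 2*Ng - Nr - Nb`` and excess-red index
  ``ExR = 1.4*Nr - Nb``,
* the HSI (hue/saturation/intensity) representation used for plant/background
  thresholding.

Everything here is computed in double precision; no quantization happens
until a threshold is applied downstream.
"""

from __future__ import annotations

from typing import NamedTuple

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "NormalizedPlanes",
    "HSIPlanes",
    "read_rgb",
    "validate_rgb",
    "normalize_rgb",
    "excess_green",
    "excess_red",
    "exg_plane",
    "exr_plane",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "write_index_tiff",
]


class NormalizedPlanes(NamedTuple):
    """Chromaticity planes; each in [0, 1], summing to 1 on non-black pixels."""

    nr: np.ndarray
    ng: np.ndarray
    nb: np.ndarray


class HSIPlanes(NamedTuple):
    """Hue in degrees [0, 360), saturation in [0, 1], intensity in [0, 255]."""

    h: np.ndarray
    s: np.ndarray
    i: np.ndarray


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is an (H, W, 3) 8-bit raster and return it as uint8.

    Raises ``ValueError`` on wrong shape, empty dimensions or out-of-range
    values.
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as an (H, W, 3) uint8 array.

    Grayscale images are replicated to three channels; an alpha channel,
    if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return validate_rgb(arr)


def normalize_rgb(img: np.ndarray) -> NormalizedPlanes:
    """Per-pixel chromaticity normalization Nr = R/(R+G+B), etc.

    Pixels with R+G+B == 0 (pure black) are assigned (0, 0, 0) by
    convention: black is background in both imaging rigs and carries no
    chromaticity information.
    """
    arr = validate_rgb(img).astype(np.float64)
    total = arr.sum(axis=2)
    safe = np.where(total == 0, 1.0, total)
    nr = np.where(total == 0, 0.0, arr[:, :, 0] / safe)
    ng = np.where(total == 0, 0.0, arr[:, :, 1] / safe)
    nb = np.where(total == 0, 0.0, arr[:, :, 2] / safe)
    return NormalizedPlanes(nr, ng, nb)


def excess_green(planes: NormalizedPlanes) -> np.ndarray:
    """Excess-green index ExG = 2*Ng - Nr - Nb, bounded by [-1, 2]."""
    return 2.0 * planes.ng - planes.nr - planes.nb


def excess_red(planes: NormalizedPlanes) -> np.ndarray:
    """Excess-red index ExR = 1.4*Nr - Nb, bounded by [-1, 1.4]."""
    return 1.4 * planes.nr - planes.nb


def exg_plane(img: np.ndarray) -> np.ndarray:
    """Convenience: ExG computed directly from an RGB raster."""
    return excess_green(normalize_rgb(img))


def exr_plane(img: np.ndarray) -> np.ndarray:
    """Convenience: ExR computed directly from an RGB raster."""
    return excess_red(normalize_rgb(img))


def rgb_to_hsi(img: np.ndarray) -> HSIPlanes:
    """RGB -> HSI using the classical arccos (Gonzalez & Woods) formulation.

    * ``I = (R + G + B) / 3`` on the 0-255 scale,
    * ``S = 1 - 3 * min(R, G, B) / (R + G + B)`` with S = 0 at black pixels,
    * ``H = theta`` if B <= G else ``360 - theta``, where theta is the arccos
      of the normalized half-difference term; achromatic pixels (S == 0) are
      assigned H = 0.

    The choice of formulation is a fixed package convention (several
    incompatible "HSI" definitions circulate); it round-trips 8-bit RGB
    through :func:`hsi_to_rgb` to within one intensity level.
    """
    arr = validate_rgb(img).astype(np.float64)
    r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
    total = r + g + b
    i = total / 3.0
    minimum = np.minimum(np.minimum(r, g), b)
    s = np.where(total == 0, 0.0, 1.0 - 3.0 * minimum / np.where(total == 0, 1.0, total))

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    cos_arg = np.where(den == 0, 1.0, num / np.where(den == 0, 1.0, den))
    theta = np.degrees(np.arccos(np.clip(cos_arg, -1.0, 1.0)))
    h = np.where(b > g, 360.0 - theta, theta)
    h = np.where(s == 0, 0.0, h)
    h = np.where(h >= 360.0, h - 360.0, h)
    return HSIPlanes(h, s, i)


def hsi_to_rgb(planes: HSIPlanes) -> np.ndarray:
    """Invert :func:`rgb_to_hsi` (sector formulation), returning uint8 RGB.

    Used mainly to verify that the forward transform preserves information;
    output channels are clipped to [0, 255] and rounded.
    """
    h = np.asarray(planes.h, dtype=np.float64) % 360.0
    s = np.asarray(planes.s, dtype=np.float64)
    i = np.asarray(planes.i, dtype=np.float64)

    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    def _sector(hh):
        """First/middle channel pair for a 120-degree sector."""
        rad = np.radians(hh)
        first = i * (1.0 + s * np.cos(rad) / np.cos(np.radians(60.0) - rad))
        return first

    sec0 = h < 120.0
    sec1 = (h >= 120.0) & (h < 240.0)
    sec2 = h >= 240.0

    b[sec0] = (i * (1.0 - s))[sec0]
    r[sec0] = _sector(h)[sec0]
    g[sec0] = (3.0 * i - (r + b))[sec0]

    r[sec1] = (i * (1.0 - s))[sec1]
    g[sec1] = _sector(h - 120.0)[sec1]
    b[sec1] = (3.0 * i - (r + g))[sec1]

    g[sec2] = (i * (1.0 - s))[sec2]
    b[sec2] = _sector(h - 240.0)[sec2]
    r[sec2] = (3.0 * i - (g + b))[sec2]

    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def write_index_tiff(path, plane: np.ndarray) -> None:
    """Export an index plane (ExG/ExR) as 32-bit float TIFF for inspection."""
    tifffile.imwrite(path, np.asarray(plane, dtype=np.float32))
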