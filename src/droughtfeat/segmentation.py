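"""Plant and greenness segmentation.

Two binary masks drive all morphometry:

* the *plant mask*: HSI thresholding (hue gate, minimum saturation,
  intensity window) followed by small-region removal, and
* the *greenness mask*: within the plant mask, pixels whose excess-green
  index exceeds a threshold AND whose excess-red index stays below a
  threshold.  The double gate matters: senescent yellow tissue has high ExG
  but is rejected by the ExR gate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.morphology import remove_small_objects

from .imaging_core import exg_plane, exr_plane, rgb_to_hsi, validate_rgb

__all__ = [
    "SegmentationConfig",
    "segment_plant",
    "remove_small_regions",
    "greenness_mask",
    "write_mask_png",
    "read_mask_png",
]


@dataclasses.dataclass
class SegmentationConfig:
    """Thresholds for plant/background and greenness discrimination.

    The hue gate keeps pixels with ``h_min <= H <= h_max`` (wrapping across
    0 degrees when ``h_min > h_max``); the defaults span green through
    yellow-green vegetation.  Values are rig-specific conventions and fully
    overridable — they are chosen so that the synthetic palette used in
    testing (green (30,160,60), yellow (210,200,40)) is classified as plant,
    while the blue and brown backgrounds are not.

    Attributes
    ----------
    h_min, h_max : float
        Hue gate in degrees, each in [0, 360).
    s_min : float
        Minimum saturation in [0, 1]; rejects achromatic background.
    i_min, i_max : float
        Intensity window on the 0-255 scale; rejects near-black pixels.
    min_region_area : int
        Connected components (8-connectivity) smaller than this many pixels
        are removed from the plant mask.
    exg_threshold : float
        Greenness requires ExG strictly greater than this.
    exr_threshold : float
        Greenness requires ExR strictly less than this.
    """

    h_min: float = 50.0
    h_max: float = 180.0
    s_min: float = 0.15
    i_min: float = 20.0
    i_max: float = 255.0
    min_region_area: int = 50
    exg_threshold: float = 0.10
    exr_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.h_min < 360.0 and 0.0 <= self.h_max < 360.0):
            raise ValueError("hue bounds must lie in [0, 360)")
        if not 0.0 <= self.s_min <= 1.0:
            raise ValueError("s_min must lie in [0, 1]")
        if self.min_region_area < 0:
            raise ValueError("min_region_area must be >= 0")
        for name in ("exg_threshold", "exr_threshold", "i_min", "i_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_file(cls, path) -> "SegmentationConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _hue_gate(h: np.ndarray, h_min: float, h_max: float) -> np.ndarray:
    # h_min > h_max means the interval wraps across 0 degrees
    if h_min <= h_max:
        return (h >= h_min) & (h <= h_max)
    return (h >= h_min) | (h <= h_max)


def segment_plant(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """HSI-threshold the image into a boolean plant mask.

    A pixel is plant when its hue falls in the configured gate, saturation
    is at least ``s_min`` and intensity lies within ``[i_min, i_max]``;
    small connected components are then removed.  An empty mask is a legal
    output (downstream feature extraction rejects it).
    """
    img = validate_rgb(img)
    h, s, i = rgb_to_hsi(img)
    mask = _hue_gate(h, cfg.h_min, cfg.h_max) & (s >= cfg.s_min)
    mask &= (i >= cfg.i_min) & (i <= cfg.i_max)
    return remove_small_regions(mask, cfg.min_region_area)


def remove_small_regions(mask: np.ndarray, min_region_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_region_area`` pixels.

    Components at or above the threshold pass through unchanged; a
    threshold of 0 (or 1) is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_region_area <= 1:
        return mask.copy()
    # max_size removes components <= its value, so the contract "< min_region_area
    # removed, >= kept" needs min_region_area - 1
    return remove_small_objects(mask, max_size=min_region_area - 1, connectivity=2)


def greenness_mask(
    img: np.ndarray, plant_mask: np.ndarray, cfg: SegmentationConfig
) -> np.ndarray:
    """Greenness pixels: plant pixels passing the ExG/ExR double gate.

    True exactly where the plant mask is true, ExG > ``exg_threshold`` and
    ExR < ``exr_threshold``.  The result is always a subset of the plant
    mask.  Raises ``ValueError`` when mask and image dimensions disagree.
    """
    img = validate_rgb(img)
    plant_mask = np.asarray(plant_mask, dtype=bool)
    if plant_mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {plant_mask.shape} does not match image {img.shape[:2]}"
        )
    exg = exg_plane(img)
    exr = exr_plane(img)
    return plant_mask & (exg > cfg.exg_threshold) & (exr < cfg.exr_threshold)


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 1-bit PNG."""
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a 1-bit (or grayscale) PNG back into a boolean mask."""
    return np.asarray(Image.open(path).convert("1"), dtype=bool)
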