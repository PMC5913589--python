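"""The four drought-response features and their controlled/field variants.

From a single segmented image the pipeline derives:

* ``GPAR`` — greenness projected plant area / total projected plant area,
  a stay-green proxy in [0, 1];
* ``TBR`` — total projected plant area / bounding-rectangle area,
  decreases when leaves roll;
* ``PAR`` — plant perimeter (edge-pixel count) / total projected plant
  area, increases when leaves roll (the preferred rolling descriptor);
* ``TCR`` — total projected plant area / convex-hull pixel area,
  decreases when leaves roll.

Controlled-condition plants imaged from several side angles are summarized
by the arithmetic mean of each feature across views.  Field plots use an
ExG-based vegetation mask (hue gates fail over paddy water/soil) and
compute PAR on the top third of the image only, which isolates leaf tips
from the overlapping canopy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .imaging_core import exg_plane, validate_rgb
from .morphometry import MorphometrySummary, NoPlantError, summarize
from .segmentation import SegmentationConfig, greenness_mask, remove_small_regions, segment_plant

__all__ = [
    "DroughtFeatures",
    "SingleViewResult",
    "MultiViewResult",
    "features_single_view",
    "features_multiview",
    "field_vegetation_mask",
    "field_gpar",
    "field_par",
]

FEATURE_NAMES = ("gpar", "tbr", "par", "tcr")


@dataclasses.dataclass(frozen=True)
class DroughtFeatures:
    """The (GPAR, TBR, PAR, TCR) quadruple for one plant/plot at one time."""

    gpar: float
    tbr: float
    par: float
    tcr: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class SingleViewResult:
    """Features plus the raw pixel counts they were derived from."""

    features: DroughtFeatures
    morphometry: MorphometrySummary
    greenness_area: int


@dataclasses.dataclass(frozen=True)
class MultiViewResult:
    """Per-feature mean across side views, with the contributing-view count."""

    features: DroughtFeatures
    n_views: int


def measure_single_view(img: np.ndarray, cfg: SegmentationConfig) -> SingleViewResult:
    """Segment one side-view image and compute features plus raw counts.

    Raises :class:`NoPlantError` when segmentation yields an empty plant
    mask — callers mark the record missing rather than zero-filling, since
    a zero ratio is not a meaningful feature value.
    """
    img = validate_rgb(img)
    plant = segment_plant(img, cfg)
    area = int(np.count_nonzero(plant))
    if area == 0:
        raise NoPlantError("segmentation produced an empty plant mask")
    green = greenness_mask(img, plant, cfg)
    morpho = summarize(plant)
    green_area = int(np.count_nonzero(green))
    feats = DroughtFeatures(
        gpar=green_area / morpho.area,
        tbr=morpho.area / morpho.bbox_area,
        par=morpho.perimeter / morpho.area,
        tcr=morpho.area / morpho.hull_area,
    )
    return SingleViewResult(feats, morpho, green_area)


def features_single_view(img: np.ndarray, cfg: SegmentationConfig) -> DroughtFeatures:
    """The (GPAR, TBR, PAR, TCR) quadruple from a single side-view image."""
    return measure_single_view(img, cfg).features


def features_multiview(
    views: Iterable[np.ndarray], cfg: SegmentationConfig
) -> MultiViewResult:
    """Mean feature value across side views from different angles.

    Views whose segmentation comes up empty are dropped from the mean (not
    zero-filled); the number of contributing views is reported.  Raises
    :class:`NoPlantError` when every view is empty.
    """
    per_view: list[DroughtFeatures] = []
    for img in views:
        try:
            per_view.append(features_single_view(img, cfg))
        except NoPlantError:
            continue
    if not per_view:
        raise NoPlantError("no view produced a non-empty plant mask")
    means = {
        name: float(np.mean([getattr(f, name) for f in per_view]))
        for name in FEATURE_NAMES
    }
    return MultiViewResult(DroughtFeatures(**means), n_views=len(per_view))


def field_vegetation_mask(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Vegetation mask for field plots: ExG gate plus small-region removal.

    Field backgrounds (paddy water, wet soil) defeat hue-only gates, so the
    plot plant mask is defined by ExG > ``exg_threshold`` instead of the
    HSI thresholds used for single pot-grown plants.
    """
    mask = exg_plane(img) > cfg.exg_threshold
    return remove_small_regions(mask, cfg.min_region_area)


def field_gpar(img: np.ndarray, cfg: SegmentationConfig) -> float:
    """Plot-level GPAR: greenness area / vegetation area over the full image.

    Raises :class:`NoPlantError` when the plot contains no vegetation
    pixels.
    """
    img = validate_rgb(img)
    veg = field_vegetation_mask(img, cfg)
    area = int(np.count_nonzero(veg))
    if area == 0:
        raise NoPlantError("no vegetation pixels in plot image")
    green = greenness_mask(img, veg, cfg)
    return int(np.count_nonzero(green)) / area


def field_par(img: np.ndarray, cfg: SegmentationConfig) -> float:
    """Plot-level PAR computed on the top third of the image only.

    The crop keeps rows ``0 .. floor(height/3) - 1``; leaf tips dominate
    there, which avoids the interference of overlapping plants lower in
    the canopy.  Raises :class:`NoPlantError` when the crop holds no
    vegetation pixels.
    """
    img = validate_rgb(img)
    n_rows = math.floor(img.shape[0] / 3)
    crop = img[:n_rows]
    veg = field_vegetation_mask(crop, cfg)
    area = int(np.count_nonzero(veg))
    if area == 0:
        raise NoPlantError("no vegetation pixels in the top-third crop")
    try:
        morpho = summarize(veg)
    except NoPlantError:  # pragma: no cover - guarded above
        raise
    return morpho.perimeter / morpho.area


def whole_image_par(img: np.ndarray, cfg: SegmentationConfig) -> float:
    """PAR of the full plot image (for comparison with the top-third crop)."""
    img = validate_rgb(img)
    veg = field_vegetation_mask(img, cfg)
    if not veg.any():
        raise NoPlantError("no vegetation pixels in plot image")
    morpho = summarize(veg)
    return morpho.perimeter / morpho.area
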