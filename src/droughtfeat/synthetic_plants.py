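"""Seeded generator of ground-truthed plant and plot imagery.

No public image archive accompanies the drought-feature method, so the
pipeline is validated against synthetic plants whose silhouette and color
are controlled exactly:

* *leaf-rolling* is modeled as silhouette narrowing (thinner rendered
  leaves) — the shape descriptors only see projected geometry, so width
  reduction is precisely the signal they measure;
* *senescence* is modeled by recoloring the tip-most share of plant pixels
  from green to yellow, so the true green fraction is known to the pixel;
* *speck noise* (small green blobs off the plant) exercises small-region
  removal.

A plant is a fan of curved, tapering leaves rising from a basal point.
Rendering is purely integer rasterization driven by one seeded generator,
so identical specs give bit-identical images on every platform.

Palette: green (30, 160, 60), yellow (210, 200, 40); backgrounds blue
(40, 60, 160) for the controlled-condition rig and brown (120, 90, 60) for
field plots.  These are deliberately unambiguous under the default
segmentation thresholds.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

__all__ = [
    "GREEN",
    "YELLOW",
    "BLUE_BACKGROUND",
    "BROWN_BACKGROUND",
    "SyntheticPlantSpec",
    "SyntheticSchedule",
    "GroundTruth",
    "render_plant",
    "render_series",
    "render_field_plot",
    "drought_schedule",
    "discrimination_cohort",
]

GREEN = (30, 160, 60)
YELLOW = (210, 200, 40)
BLUE_BACKGROUND = (40, 60, 160)
BROWN_BACKGROUND = (120, 90, 60)


@dataclasses.dataclass(frozen=True)
class SyntheticPlantSpec:
    """Parameters of one rendered plant.

    ``leaf_width`` is the basal silhouette width in pixels and is the
    rolling proxy (rolled leaves render narrower); ``green_fraction`` is
    the share of plant pixels colored green rather than yellow, counted
    from the leaf base (senescence proceeds from the tips).
    """

    n_leaves: int = 7
    leaf_length: int = 55
    leaf_width: float = 12.0
    arch_curvature: float = 0.25
    green_fraction: float = 0.95
    background_color: tuple = BLUE_BACKGROUND
    speck_count: int = 0
    speck_size: int = 5
    image_size: tuple = (160, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaf_width < 1:
            raise ValueError("leaf_width must be >= 1 pixel")
        if not 0.0 <= self.green_fraction <= 1.0:
            raise ValueError("green_fraction must lie in [0, 1]")
        if self.n_leaves < 1 or self.leaf_length < 2:
            raise ValueError("need at least one leaf of length >= 2")


@dataclasses.dataclass(frozen=True)
class SyntheticSchedule:
    """Per-day width and greenness trajectories for a stress time course."""

    n_days: int
    onset_day: int
    width_trajectory: tuple
    greenness_trajectory: tuple
    rewater_day: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.onset_day <= self.n_days:
            raise ValueError("onset_day must lie within 1..n_days")
        if len(self.width_trajectory) != self.n_days:
            raise ValueError("width_trajectory length must equal n_days")
        if len(self.greenness_trajectory) != self.n_days:
            raise ValueError("greenness_trajectory length must equal n_days")
        end = self.rewater_day if self.rewater_day is not None else self.n_days
        widths = self.width_trajectory[self.onset_day - 1 : end]
        if any(b > a for a, b in zip(widths, widths[1:])):
            raise ValueError("width trajectory must be non-increasing after onset")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Exact masks and parameters behind a render."""

    plant_mask: np.ndarray
    green_mask: np.ndarray
    true_green_fraction: float
    true_onset_day: Optional[int] = None


_footprint_cache: dict[float, np.ndarray] = {}


def _disk_offsets(radius: float) -> np.ndarray:
    """(dy, dx) offsets of pixels within ``radius`` of the origin."""
    key = round(radius, 3)
    if key not in _footprint_cache:
        r = max(0, int(np.floor(key)))
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        keep = dy * dy + dx * dx <= key * key
        _footprint_cache[key] = np.column_stack([dy[keep], dx[keep]])
    return _footprint_cache[key]


def _render_mask(
    spec: SyntheticPlantSpec, angle_offsets: Optional[np.ndarray] = None
) -> tuple[np.ndarray, tuple]:
    """Rasterize the plant silhouette; returns (mask, base point)."""
    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=bool)
    base = (h - 11, w // 2)  # fixed margin keeps the anchor stable across widths
    rng = np.random.default_rng(spec.seed)

    if spec.n_leaves == 1:
        angles = np.array([0.0])
    else:
        angles = np.linspace(-65.0, 65.0, spec.n_leaves)
    angles = angles + rng.uniform(-4.0, 4.0, size=spec.n_leaves)
    if angle_offsets is not None:
        angles = angles + np.asarray(angle_offsets, dtype=float)
    lengths = spec.leaf_length * rng.uniform(0.85, 1.0, size=spec.n_leaves)

    for angle, length in zip(angles, lengths):
        rad = np.radians(angle)
        # tip relative to base, y up the image (negative row direction)
        tip = np.array([-length * np.cos(rad), length * np.sin(rad)])
        mid = tip / 2.0
        perp = np.array([-tip[1], tip[0]]) / max(length, 1e-9)
        # arch leaves outward so the fan droops like a real grass canopy
        ctrl = mid + perp * spec.arch_curvature * length * np.sign(angle or 1.0)
        t = np.linspace(0.0, 1.0, max(4, int(2.5 * length)))[:, None]
        pts = (1 - t) ** 2 * np.zeros(2) + 2 * t * (1 - t) * ctrl + t**2 * tip
        radii = np.maximum(0.5, (spec.leaf_width / 2.0) * (1.0 - 0.65 * t[:, 0]))
        for (dy, dx), r in zip(pts, radii):
            cy = base[0] + int(np.rint(dy))
            cx = base[1] + int(np.rint(dx))
            offs = _disk_offsets(r)
            ys = cy + offs[:, 0]
            xs = cx + offs[:, 1]
            if ys.min() < 0 or xs.min() < 0 or ys.max() >= h or xs.max() >= w:
                raise ValueError(
                    "plant exceeds the image frame; enlarge image_size or "
                    "shorten leaf_length"
                )
            mask[ys, xs] = True
    return mask, base


def render_plant(
    spec: SyntheticPlantSpec, angle_offsets: Optional[np.ndarray] = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one plant; returns the RGB image and its exact ground truth.

    ``angle_offsets`` (degrees per leaf) lets a time-course renderer add
    small day-to-day sway without changing the plant's base geometry.
    Deterministic: the same spec and seed give bit-identical output.
    """
    h, w = spec.image_size
    mask, base = _render_mask(spec, angle_offsets)
    area = int(mask.sum())

    # senescence from the tips: the farthest (1 - green_fraction) share of
    # plant pixels turns yellow, deterministically ordered
    rows, cols = np.nonzero(mask)
    dist2 = (rows - base[0]) ** 2 + (cols - base[1]) ** 2
    order = np.lexsort((cols, rows, -dist2))  # farthest first, stable ties
    n_yellow = int(np.rint((1.0 - spec.green_fraction) * area))
    yellow_idx = order[:n_yellow]
    green_mask = mask.copy()
    green_mask[rows[yellow_idx], cols[yellow_idx]] = False

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:, :] = spec.background_color
    img[green_mask] = GREEN
    img[mask & ~green_mask] = YELLOW

    if spec.speck_count > 0:
        rng = np.random.default_rng([spec.seed, 9173])
        forbidden = binary_dilation(mask, iterations=3)
        offs = _speck_offsets(spec.speck_size)
        margin = int(np.abs(offs).max()) + 1
        placed = 0
        for _ in range(200 * spec.speck_count):
            if placed == spec.speck_count:
                break
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            ys, xs = cy + offs[:, 0], cx + offs[:, 1]
            if forbidden[ys, xs].any():
                continue
            img[ys, xs] = GREEN
            placed += 1

    true_gf = (int(green_mask.sum()) / area) if area else 0.0
    return img, GroundTruth(mask, green_mask, true_green_fraction=true_gf)


def _speck_offsets(size: int) -> np.ndarray:
    """A compact blob of exactly ``size`` pixels around the origin."""
    r = int(np.ceil(np.sqrt(size))) + 1
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    flat = np.column_stack([dy.ravel(), dx.ravel()])
    key = flat[:, 0] ** 2 + flat[:, 1] ** 2
    order = np.lexsort((flat[:, 1], flat[:, 0], key))
    return flat[order[:size]]


def render_series(
    spec: SyntheticPlantSpec, schedule: SyntheticSchedule, sway_deg: float = 1.5
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Render one image per day following the schedule's trajectories.

    Day d uses the base geometry of ``spec`` with that day's leaf width and
    green fraction, plus a small per-day leaf sway (std ``sway_deg``
    degrees, seeded by (spec.seed, day)) emulating wind and growth
    micro-variation.  Each ground truth carries the schedule's true onset
    day.
    """
    out = []
    for day in range(1, schedule.n_days + 1):
        day_spec = dataclasses.replace(
            spec,
            leaf_width=float(schedule.width_trajectory[day - 1]),
            green_fraction=float(schedule.greenness_trajectory[day - 1]),
        )
        sway_rng = np.random.default_rng([spec.seed, day])
        offsets = sway_rng.normal(0.0, sway_deg, size=spec.n_leaves)
        img, gt = render_plant(day_spec, angle_offsets=offsets)
        out.append(
            (img, dataclasses.replace(gt, true_onset_day=schedule.onset_day))
        )
    return out


def drought_schedule(
    n_days: int = 13,
    onset_day: int = 6,
    width_start: float = 12.0,
    width_min: float = 4.0,
    green_start: float = 0.95,
    green_end: float = 0.65,
    rewater_day: Optional[int] = None,
) -> SyntheticSchedule:
    """Build a stress trajectory with a sharp rolling onset.

    Width stays at ``width_start`` before the onset day, drops by roughly
    half of the total decline on the onset day itself (visible rolling is
    abrupt), then declines linearly to ``width_min``.  Greenness declines
    linearly from onset to the final day.  If ``rewater_day`` is set, both
    trajectories recover toward their starting values afterwards.
    """
    widths = [float(width_start)] * n_days
    greens = [float(green_start)] * n_days
    end = rewater_day if rewater_day is not None else n_days
    drop = max(2.0, 0.45 * (width_start - width_min))
    for d in range(onset_day, end + 1):
        if d > n_days:
            break
        if d == onset_day:
            widths[d - 1] = max(width_min, width_start - drop)
        else:
            remaining = max(end - onset_day, 1)
            frac = (d - onset_day) / remaining
            widths[d - 1] = max(
                width_min, (width_start - drop) - frac * (width_start - drop - width_min)
            )
    for d in range(onset_day, end + 1):
        if d > n_days:
            break
        frac = (d - onset_day + 1) / max(end - onset_day + 1, 1)
        greens[d - 1] = green_start - frac * (green_start - green_end)
    if rewater_day is not None:
        for d in range(rewater_day + 1, n_days + 1):
            widths[d - 1] = min(width_start, widths[d - 2] + 2.0)
            greens[d - 1] = min(green_start, greens[d - 2] + 0.05)
    return SyntheticSchedule(
        n_days=n_days,
        onset_day=onset_day,
        width_trajectory=tuple(widths),
        greenness_trajectory=tuple(greens),
        rewater_day=rewater_day,
    )


def render_field_plot(
    grid: Sequence[Sequence[SyntheticPlantSpec]],
    background_color: tuple = BROWN_BACKGROUND,
    cell_overlap: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Composite a rows x cols grid of plants into one plot image.

    Every spec must share ``image_size`` (the cell size).  Neighboring
    cells may overlap by ``cell_overlap`` pixels to mimic canopy closure;
    where plants overlap, the later-drawn plant wins, and the ground-truth
    masks follow the same overwrite rule.
    """
    rows = len(grid)
    cols = len(grid[0])
    cell_h, cell_w = grid[0][0].image_size
    for row in grid:
        if len(row) != cols:
            raise ValueError("grid rows must have equal length")
        for s in row:
            if s.image_size != (cell_h, cell_w):
                raise ValueError("all specs in a plot must share image_size")

    step_h, step_w = cell_h - cell_overlap, cell_w - cell_overlap
    plot_h = step_h * (rows - 1) + cell_h
    plot_w = step_w * (cols - 1) + cell_w
    img = np.empty((plot_h, plot_w, 3), dtype=np.uint8)
    img[:, :] = background_color
    plant_mask = np.zeros((plot_h, plot_w), dtype=bool)
    green_mask = np.zeros((plot_h, plot_w), dtype=bool)

    for i, row in enumerate(grid):
        for j, spec in enumerate(row):
            cell_img, gt = render_plant(spec)
            y0, x0 = i * step_h, j * step_w
            sl = (slice(y0, y0 + cell_h), slice(x0, x0 + cell_w))
            m = gt.plant_mask
            img[sl][m] = cell_img[m]
            plant_mask[sl] |= m
            # overwrite greenness where the new plant covers older pixels
            gsub = green_mask[sl]
            gsub[m] = gt.green_mask[m]
            green_mask[sl] = gsub

    area = int(plant_mask.sum())
    true_gf = (int(green_mask.sum()) / area) if area else 0.0
    return img, GroundTruth(plant_mask, green_mask, true_green_fraction=true_gf)


def discrimination_cohort(
    n_per_group: int = 20, seed: int = 0
) -> list[dict]:
    """Before/after specs for a resistant-vs-sensitive rehearsal.

    Both groups are exchangeable before stress (same spec distribution).
    After stress, resistant plants roll strongly (leaf width 12 -> ~6 px)
    with mild senescence (green fraction down ~0.10), while sensitive
    plants barely roll (width down <= 1 px) but senesce strongly (green
    fraction down ~0.42).  These effect sizes mirror the qualitative
    resistant/sensitive contrast the features are meant to discriminate.

    Returns a list of records with keys ``plant_id``, ``group``,
    ``before`` and ``after`` (SyntheticPlantSpec).
    """
    records = []
    for idx in range(2 * n_per_group):
        group = "resistant" if idx < n_per_group else "sensitive"
        rng = np.random.default_rng([seed, idx])
        base = SyntheticPlantSpec(
            n_leaves=int(rng.integers(6, 10)),
            leaf_length=int(rng.integers(48, 60)),
            leaf_width=12.0,
            arch_curvature=float(rng.uniform(0.18, 0.30)),
            green_fraction=float(rng.uniform(0.92, 0.98)),
            seed=int(rng.integers(2**31)),
        )
        if group == "resistant":
            after = dataclasses.replace(
                base,
                leaf_width=float(rng.uniform(5.5, 7.0)),
                green_fraction=base.green_fraction - float(rng.uniform(0.07, 0.13)),
            )
        else:
            after = dataclasses.replace(
                base,
                leaf_width=float(rng.uniform(11.0, 12.0)),
                green_fraction=base.green_fraction - float(rng.uniform(0.36, 0.48)),
            )
        records.append(
            {"plant_id": f"{group[0]}{idx:03d}", "group": group, "before": base, "after": after}
        )
    return records
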