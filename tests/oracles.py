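"""Independent brute-force oracles used to validate the morphometry and
segmentation primitives.  These deliberately avoid the implementation's
code paths (shapely, scikit-image): the hull oracle is an all-pairs
half-plane test, the perimeter oracle an explicit neighbor scan, and the
region oracle a hand-rolled flood fill.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_EPS = 1e-9


def perimeter_scan(mask: np.ndarray) -> int:
    """Count edge pixels by explicit 4-neighbor lookup (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    count += 1
                    break
    return count


def flood_fill_filter(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_area`` via BFS."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            comp = []
            queue = deque([(y, x)])
            seen[y, x] = True
            while queue:
                cy, cx = queue.popleft()
                comp.append((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            if len(comp) >= min_area:
                for cy, cx in comp:
                    out[cy, cx] = True
    return out


def hull_pixel_count_bruteforce(mask: np.ndarray) -> int:
    """Pixel count of the filled convex hull of true-pixel centers.

    O(n^3) all-pairs half-plane construction: a directed pair (a, b) is a
    hull edge iff every point lies on or left of it; a candidate pixel
    center is inside the hull iff it lies on or left of every such edge.
    Collinear point sets fall back to an explicit on-segment test.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if ys.size == 0:
        raise ValueError("empty mask")
    pts = np.column_stack([xs, ys]).astype(float)
    n = len(pts)
    if n == 1:
        return 1

    gx, gy = np.meshgrid(
        np.arange(xs.min(), xs.max() + 1), np.arange(ys.min(), ys.max() + 1)
    )
    cand = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)

    ref = pts[1] - pts[0]
    rel = pts - pts[0]
    cross0 = ref[0] * rel[:, 1] - ref[1] * rel[:, 0]
    if np.all(np.abs(cross0) <= _EPS):  # collinear: count centers on the segment
        t = rel @ ref / (ref @ ref)
        lo, hi = t.min(), t.max()
        crel = cand - pts[0]
        ccross = ref[0] * crel[:, 1] - ref[1] * crel[:, 0]
        ct = crel @ ref / (ref @ ref)
        on = (np.abs(ccross) <= _EPS) & (ct >= lo - _EPS) & (ct <= hi + _EPS)
        return int(on.sum())

    inside = np.ones(len(cand), dtype=bool)
    for i in range(n):
        dv = pts - pts[i]
        cv = cand - pts[i]
        for j in range(n):
            if i == j:
                continue
            vx, vy = pts[j] - pts[i]
            side = vx * dv[:, 1] - vy * dv[:, 0]
            if np.all(side >= -_EPS):  # (i, j) is a hull edge
                inside &= vx * cv[:, 1] - vy * cv[:, 0] >= -_EPS
    return int(inside.sum())


def random_blob_mask(rng: np.random.Generator, max_side: int = 20) -> np.ndarray:
    """A random non-empty boolean mask for oracle-equivalence sweeps."""
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    density = float(rng.uniform(0.05, 0.4))
    mask = rng.random((h, w)) < density
    if not mask.any():
        mask[int(rng.integers(h)), int(rng.integers(w))] = True
    return mask
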