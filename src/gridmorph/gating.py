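"""In-grid gating, overlap judgment and per-frame counting.

A measurement is only metrically valid while the fish lies on the glowing
panel, so each mask is gated by the fraction of its pixels falling inside
the panel polygon (default threshold 0.99). Raw IoU of the mask against
the whole panel is also recorded, but is not the gate statistic: a small
fish has a tiny IoU with a large panel even when fully inside it.

Merged silhouettes (two fish touching) cannot be measured as one animal.
A mask is flagged *overlapping* when its physical area exceeds the
largest plausible single-fish area, or when its solidity (area divided by
convex-hull area) drops below a floor — a fused pair of fusiform bodies
is markedly less convex than either body alone. Flagged components are
excluded from the clean count and from length statistics; each in-grid
flagged component contributes at least 2 to the reported minimum count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import GridCalibration
from .segmentation import LabeledMask

__all__ = [
    "GateResult",
    "iou",
    "classify_inside",
    "detect_overlap",
    "count_inside",
    "DEFAULT_INSIDE_THRESHOLD",
    "DEFAULT_SOLIDITY_FLOOR",
]

DEFAULT_INSIDE_THRESHOLD = 0.99
DEFAULT_SOLIDITY_FLOOR = 0.75


@dataclass
class GateResult:
    """Inside/overlap verdict for one mask."""

    label: int
    inside_fraction: float
    iou_with_panel: float
    inside: bool
    overlapping: bool = False

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "inside_fraction": self.inside_fraction,
            "iou_with_panel": self.iou_with_panel,
            "inside": self.inside,
            "overlapping": self.overlapping,
        }


def _as_bool_array(region, shape: tuple[int, int] | None) -> np.ndarray:
    if isinstance(region, LabeledMask):
        if shape is None:
            raise ValueError("shape required to expand a LabeledMask")
        return region.to_full(shape)
    arr = np.asarray(region)
    if arr.ndim == 2 and arr.dtype != object:
        return arr.astype(bool)
    raise TypeError("region must be a LabeledMask, a 2D array, or a 4-tuple box")


def _box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = map(float, a)
    bx0, by0, bx1, by1 = map(float, b)
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        area_a = max(ax1 - ax0, 0.0) * max(ay1 - ay0, 0.0)
        area_b = max(bx1 - bx0, 0.0) * max(by1 - by0, 0.0)
        if area_a == 0.0 and area_b == 0.0:
            raise ValueError("IoU undefined: both boxes are empty")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = (
        (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    )
    return inter / union


def iou(region_a, region_b, shape: tuple[int, int] | None = None) -> float:
    """Intersection over union of two regions.

    Regions may be boolean rasters (same shape), :class:`LabeledMask`
    instances (``shape`` then gives the common frame), or half-open
    ``(x0, y0, x1, y1)`` boxes. Raises when both regions are empty (the
    ratio is undefined).
    """
    if isinstance(region_a, tuple) and isinstance(region_b, tuple):
        return _box_iou(region_a, region_b)
    a = _as_bool_array(region_a, shape)
    b = _as_bool_array(region_b, shape)
    if a.shape != b.shape:
        raise ValueError(f"region shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both regions are empty")
    return float(inter) / float(union)


def _polygon_is_rect(polygon: np.ndarray) -> tuple[float, float, float, float] | None:
    xs, ys = polygon[:, 0], polygon[:, 1]
    x0, x1, y0, y1 = xs.min(), xs.max(), ys.min(), ys.max()
    rect = {(x0, y0), (x1, y0), (x1, y1), (x0, y1)}
    got = {(float(x), float(y)) for x, y in polygon}
    return (x0, y0, x1, y1) if got == rect else None


def _pixels_inside_polygon(coords_rc: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Boolean per-pixel inside test; boundary pixels count as inside."""
    rect = _polygon_is_rect(polygon)
    cols = coords_rc[:, 1]
    rows = coords_rc[:, 0]
    if rect is not None:
        x0, y0, x1, y1 = rect
        # half-open: a pixel (row, col) is inside when its index falls in
        # [x0, x1) x [y0, y1) — the top/left boundary belongs to the panel
        return (cols >= x0) & (cols < x1) & (rows >= y0) & (rows < y1)
    from matplotlib.path import Path as MplPath

    path = MplPath(polygon)
    pts = np.column_stack([cols, rows]).astype(float)
    return path.contains_points(pts, radius=1e-9)


def _polygon_pixel_area(polygon: np.ndarray) -> float:
    rect = _polygon_is_rect(polygon)
    if rect is not None:
        x0, y0, x1, y1 = rect
        return float((x1 - x0) * (y1 - y0))
    x, y = polygon[:, 0], polygon[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def classify_inside(
    mask: LabeledMask,
    panel_polygon: np.ndarray,
    threshold: float = DEFAULT_INSIDE_THRESHOLD,
) -> GateResult:
    """Gate one mask by its pixel fraction inside the panel polygon."""
    if mask.area_px == 0:
        raise ValueError("cannot gate an empty mask")
    polygon = np.asarray(panel_polygon, dtype=float)
    coords = mask.pixel_coords()
    inside_px = int(_pixels_inside_polygon(coords, polygon).sum())
    fraction = inside_px / mask.area_px
    panel_area = _polygon_pixel_area(polygon)
    union = mask.area_px + panel_area - inside_px
    return GateResult(
        label=mask.label,
        inside_fraction=fraction,
        iou_with_panel=inside_px / union if union > 0 else 0.0,
        inside=fraction >= threshold,
    )


def detect_overlap(
    masks: list[LabeledMask],
    calibration: GridCalibration,
    expected_max_area_mm2: float,
    solidity_floor: float = DEFAULT_SOLIDITY_FLOOR,
) -> list[bool]:
    """Flag masks that plausibly contain more than one fish.

    A mask is flagged when its mm^2 area strictly exceeds
    ``expected_max_area_mm2`` or its solidity falls below
    ``solidity_floor``.
    """
    if expected_max_area_mm2 <= 0:
        raise ValueError("expected_max_area_mm2 must be positive")
    px_area = calibration.mm_per_px_x * calibration.mm_per_px_y
    flags: list[bool] = []
    for m in masks:
        area_mm2 = m.area_px * px_area
        if area_mm2 > expected_max_area_mm2:
            flags.append(True)
            continue
        flags.append(_solidity(m.mask) < solidity_floor)
    return flags


def _solidity(mask: np.ndarray) -> float:
    """Mask area over convex-hull area.

    The hull area is the polygon area of the convex hull of the boundary
    pixel centres plus a half-pixel perimeter band (so a filled convex
    raster scores ~1).
    """
    from scipy import ndimage
    from scipy.spatial import ConvexHull, QhullError

    area = int(mask.sum())
    if area <= 2:
        return 1.0
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear mask: hull degenerates, treat as solid
        return 1.0
    # hull.volume is the 2D polygon area of pixel centres; pad by the
    # half-pixel rim so solidity of a convex raster is ~1, not < 1
    hull_area = hull.volume + 0.5 * hull.area + 1.0
    return min(area / hull_area, 1.0)


def count_inside(gate_results: list[GateResult]) -> tuple[int, int]:
    """Count in-grid fish.

    Returns ``(count, count_min)``: ``count`` is the number of clean
    (non-overlapping) in-grid masks; ``count_min`` additionally credits
    every overlapping in-grid component with at least 2 fish.
    """
    clean = sum(1 for g in gate_results if g.inside and not g.overlapping)
    merged = sum(1 for g in gate_results if g.inside and g.overlapping)
    return clean, clean + 2 * merged
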