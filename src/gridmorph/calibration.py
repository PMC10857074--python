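"""Pixels-per-metric calibration from the luminous grid.

The grid panel doubles as an in-scene metric reference: its etched lines
glow at a known physical spacing (10 mm by default), so the conversion
factor between pixels and millimetres is

    mm_per_px = cell_mm / (median spacing of detected grid lines, px)

computed independently per axis and combined as a geometric mean. Line
positions come from an axis-collapsed intensity profile restricted to the
panel region: local maxima with sub-pixel refinement by intensity-weighted
centroiding. The median spacing makes the estimate robust to a few missed
or spurious lines (e.g. lines occluded by fish).

No homography is applied: the camera is assumed zoomed and centred on the
panel so perspective distortion is negligible. Both axis scales are kept;
axis disagreement above 5% flags the calibration record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GridCalibration",
    "CalibrationError",
    "detect_grid_lines",
    "estimate_pixels_per_metric",
    "locate_panel_region",
    "calibrate_image",
    "fixed_scale_calibration",
]

ANISOTROPY_TOLERANCE = 0.05


class CalibrationError(RuntimeError):
    """Grid could not be calibrated (no panel, too few lines, ...)."""


@dataclass
class GridCalibration:
    """Recovered scale and panel geometry.

    ``mm_per_px`` is the geometric mean of the per-axis scales and is the
    factor used to convert lengths; areas use the per-axis product.
    """

    mm_per_px_x: float
    mm_per_px_y: float
    mm_per_px: float
    vertical_line_positions_px: list[float]
    horizontal_line_positions_px: list[float]
    panel_polygon_px: np.ndarray
    cell_mm: float
    anisotropy_warning: bool = False

    def __post_init__(self) -> None:
        for v in (self.mm_per_px_x, self.mm_per_px_y, self.mm_per_px):
            if v <= 0:
                raise ValueError("scales must be positive")
        for lines in (
            self.vertical_line_positions_px,
            self.horizontal_line_positions_px,
        ):
            if lines and np.any(np.diff(lines) <= 0):
                raise ValueError("line positions must be strictly increasing")
        self.panel_polygon_px = np.asarray(self.panel_polygon_px, dtype=float)

    @property
    def panel_rect_px(self) -> tuple[int, int, int, int]:
        """Axis-aligned half-open (row0, col0, row1, col1) bounding the panel."""
        xs, ys = self.panel_polygon_px[:, 0], self.panel_polygon_px[:, 1]
        return (
            int(np.floor(ys.min())),
            int(np.floor(xs.min())),
            int(np.ceil(ys.max())),
            int(np.ceil(xs.max())),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "mm_per_px_x": self.mm_per_px_x,
            "mm_per_px_y": self.mm_per_px_y,
            "mm_per_px": self.mm_per_px,
            "vertical_line_positions_px": list(self.vertical_line_positions_px),
            "horizontal_line_positions_px": list(self.horizontal_line_positions_px),
            "panel_polygon_px": self.panel_polygon_px.tolist(),
            "cell_mm": self.cell_mm,
            "anisotropy_warning": self.anisotropy_warning,
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GridCalibration":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["panel_polygon_px"] = np.asarray(d["panel_polygon_px"], dtype=float)
        return cls(**d)


def locate_panel_region(image: np.ndarray) -> np.ndarray:
    """Find the glowing panel as the bounding box of the bright region.

    The panel (interior + lines) is brighter than the tank background, so
    an Otsu cut on the whole image separates them; the returned polygon is
    the axis-aligned quadrilateral around the largest connected bright
    component. Dark fish inside the panel do not affect the bounds.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    image = np.asarray(image)
    if image.max() - image.min() < 1e-6:
        raise CalibrationError("image has no contrast; panel not found")
    # histogram threshold from a subsampled view; applied at full resolution
    sub = image[:: max(image.shape[0] // 1024, 1), :: max(image.shape[1] // 1024, 1)]
    thr = threshold_otsu(sub)
    bright = image > thr
    if not bright.any():
        raise CalibrationError("no above-threshold region; panel not found")
    lab, n = ndimage.label(bright)
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    rows, cols = np.nonzero(lab == largest)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    return np.array([[c0, r0], [c1, r0], [c1, r1], [c0, r1]], dtype=float)


def _refine_peak(profile: np.ndarray, peak: int, radius: int) -> float:
    """Sub-pixel peak position by centroiding above the local base level."""
    lo = max(peak - radius, 0)
    hi = min(peak + radius + 1, len(profile))
    window = profile[lo:hi].astype(float)
    base = window.min()
    weights = np.clip(window - base, 0.0, None)
    if weights.sum() <= 0:
        return float(peak)
    return float(lo + np.average(np.arange(hi - lo), weights=weights))


def detect_grid_lines(
    image: np.ndarray,
    axis: str,
    panel_polygon_px: np.ndarray | None = None,
) -> np.ndarray:
    """Detect grid-line positions along one axis, sub-pixel, sorted.

    ``axis='x'`` returns the column positions of vertical lines,
    ``axis='y'`` the row positions of horizontal lines. The detector
    collapses the panel region to a 1D mean-intensity profile and picks
    prominent local maxima.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    image = np.asarray(image, dtype=float)
    if panel_polygon_px is None:
        panel_polygon_px = locate_panel_region(image)
    xs = panel_polygon_px[:, 0]
    ys = panel_polygon_px[:, 1]
    r0, r1 = int(np.floor(ys.min())), int(np.ceil(ys.max()))
    c0, c1 = int(np.floor(xs.min())), int(np.ceil(xs.max()))
    crop = image[r0:r1, c0:c1]
    profile = crop.mean(axis=0) if axis == "x" else crop.mean(axis=1)
    spread = profile.max() - profile.min()
    if spread < 1e-6:
        raise CalibrationError(f"no grid contrast along axis {axis!r}")
    prominence = 0.25 * (profile.max() - np.median(profile))
    peaks, _ = find_peaks(profile, prominence=max(prominence, 1e-6), distance=2)
    if len(peaks) < 2:
        raise CalibrationError(
            f"fewer than 2 grid lines detected along axis {axis!r}"
        )
    spacing = float(np.median(np.diff(peaks)))
    radius = max(1, int(round(spacing / 4)))
    offset = c0 if axis == "x" else r0
    refined = np.array(
        [offset + _refine_peak(profile, p, radius) for p in peaks]
    )
    return np.sort(refined)


def estimate_pixels_per_metric(
    lines_x: np.ndarray,
    lines_y: np.ndarray,
    cell_mm: float,
    panel_polygon_px: np.ndarray | None = None,
) -> GridCalibration:
    """Build a :class:`GridCalibration` from detected line positions.

    The per-axis scale is ``cell_mm`` divided by the median consecutive
    line spacing along that axis; the combined scale is the geometric mean.
    """
    lines_x = np.asarray(lines_x, dtype=float)
    lines_y = np.asarray(lines_y, dtype=float)
    if len(lines_x) < 2 or len(lines_y) < 2:
        raise CalibrationError("need at least 2 lines per axis")
    sx = float(np.median(np.diff(lines_x)))
    sy = float(np.median(np.diff(lines_y)))
    if sx <= 0 or sy <= 0:
        raise CalibrationError("non-positive median line spacing")
    mm_x = cell_mm / sx
    mm_y = cell_mm / sy
    mm = float(np.sqrt(mm_x * mm_y))
    if panel_polygon_px is None:
        x0, x1 = lines_x.min(), lines_x.max()
        y0, y1 = lines_y.min(), lines_y.max()
        panel_polygon_px = np.array(
            [[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float
        )
    return GridCalibration(
        mm_per_px_x=mm_x,
        mm_per_px_y=mm_y,
        mm_per_px=mm,
        vertical_line_positions_px=list(lines_x),
        horizontal_line_positions_px=list(lines_y),
        panel_polygon_px=panel_polygon_px,
        cell_mm=cell_mm,
        anisotropy_warning=abs(mm_x - mm_y) / mm > ANISOTROPY_TOLERANCE,
    )


def calibrate_image(image: np.ndarray, cell_mm: float = 10.0) -> GridCalibration:
    """Full self-calibration: locate the panel, detect lines, estimate scale."""
    polygon = locate_panel_region(image)
    lines_x = detect_grid_lines(image, "x", polygon)
    lines_y = detect_grid_lines(image, "y", polygon)
    return estimate_pixels_per_metric(lines_x, lines_y, cell_mm, polygon)


def fixed_scale_calibration(
    mm_per_px: float,
    image_shape: tuple[int, int],
    cell_mm: float = 10.0,
    panel_polygon_px: np.ndarray | None = None,
) -> GridCalibration:
    """Calibration record for a known (externally measured) scale.

    Covers installs where the px-to-mm relationship was measured once at
    setup time rather than recovered from each image. The panel polygon
    defaults to the whole image.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    h, w = image_shape
    if panel_polygon_px is None:
        panel_polygon_px = np.array(
            [[0, 0], [w, 0], [w, h], [0, h]], dtype=float
        )
    spacing = cell_mm / mm_per_px
    lines = [0.0, spacing]
    return GridCalibration(
        mm_per_px_x=mm_per_px,
        mm_per_px_y=mm_per_px,
        mm_per_px=mm_per_px,
        vertical_line_positions_px=lines,
        horizontal_line_positions_px=list(lines),
        panel_polygon_px=panel_polygon_px,
        cell_mm=cell_mm,
    )
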