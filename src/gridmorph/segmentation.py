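"""Dark-object instance segmentation against the luminous panel.

The panel glows, the fish do not: inside the calibrated panel region the
fish silhouettes are the darkest pixel population, sitting below both the
cell interiors and the bright grid lines. The segmenter therefore
thresholds the panel crop with a 3-class multi-Otsu cut (fish / interior /
lines) and takes the lowest boundary, capped at a fraction of the median
panel intensity so that a fish-free frame — whose histogram only contains
interior and lines — yields no foreground at all. Morphological closing
bridges slivers, holes are filled, and 8-connected components become one
:class:`LabeledMask` each, sorted by descending area.

Users who run their own detector (e.g. a fine-tuned neural segmenter)
can bypass this stage entirely via :func:`import_masks`, which ingests an
integer-labelled raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .calibration import GridCalibration

__all__ = [
    "LabeledMask",
    "SegmentationParams",
    "choose_fish_threshold",
    "segment_dark_objects",
    "filter_components",
    "import_masks",
    "export_masks",
    "select_channel",
]


@dataclass(frozen=True)
class LabeledMask:
    """One segmented instance: a pixel region with bounding geometry.

    ``bbox_px`` is the tight half-open box ``(row0, col0, row1, col1)`` in
    full-image coordinates; ``mask`` is the boolean raster cropped to it.
    """

    label: int
    mask: np.ndarray
    bbox_px: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("label must be a positive integer")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def pixel_coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) indices in full-image coordinates."""
        rc = np.argwhere(self.mask)
        rc[:, 0] += self.bbox_px[0]
        rc[:, 1] += self.bbox_px[1]
        return rc

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox_px
        full[r0:r1, c0:c1] = self.mask
        return full


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the classical segmenter.

    ``dark_fraction`` caps the fish threshold at that fraction of the
    median panel intensity (guards fish-free frames). ``line_width_mm``
    sets the closing radius to about half the rendered grid-line width.
    ``channel`` picks the plane of an RGB input; the default is blue to
    match a blue-LED panel.
    """

    dark_fraction: float = 0.5
    line_width_mm: float = 1.0
    closing_radius_px: int | None = None
    fill_holes: bool = True
    channel: str = "blue"


_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def select_channel(image: np.ndarray, channel: str = "blue") -> np.ndarray:
    """Reduce an RGB(A) frame to a single intensity plane, scaled to [0, 1]."""
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[..., _CHANNELS[channel]]
    image = image.astype(float)
    if image.max() > 1.0:
        image = image / 255.0
    return image


def choose_fish_threshold(
    image: np.ndarray, panel_rect: tuple[int, int, int, int], dark_fraction: float = 0.5
) -> float:
    """Automatic fish/panel intensity threshold inside the panel region.

    Lowest multi-Otsu cut of the (fish, interior, lines) mixture, capped
    at ``dark_fraction`` times the median panel intensity.
    """
    from skimage.filters import threshold_multiotsu

    r0, c0, r1, c1 = panel_rect
    crop = np.asarray(image)[r0:r1, c0:c1]
    # histogram statistics from a subsampled view (threshold choice only)
    sub = crop[:: max(crop.shape[0] // 1500, 1), :: max(crop.shape[1] // 1500, 1)]
    cap = dark_fraction * float(np.median(sub))
    try:
        cuts = threshold_multiotsu(sub, classes=3)
        thr = float(cuts[0])
    except ValueError:  # fewer distinct grey levels than classes
        thr = cap
    return min(thr, cap)


def _masks_from_labels(labels: np.ndarray, offset_rc: tuple[int, int]) -> list[LabeledMask]:
    out: list[LabeledMask] = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        region = labels[sl] == i
        r0 = sl[0].start + offset_rc[0]
        c0 = sl[1].start + offset_rc[1]
        out.append(
            LabeledMask(
                label=i,
                mask=region,
                bbox_px=(r0, c0, r0 + region.shape[0], c0 + region.shape[1]),
            )
        )
    out.sort(key=lambda m: m.area_px, reverse=True)
    return [
        LabeledMask(label=k, mask=m.mask, bbox_px=m.bbox_px)
        for k, m in enumerate(out, start=1)
    ]


def segment_dark_objects(
    image: np.ndarray,
    calibration: GridCalibration,
    params: SegmentationParams = SegmentationParams(),
) -> list[LabeledMask]:
    """Segment dark fish silhouettes within the calibrated panel region.

    Returns instance masks sorted by descending area; an empty list is a
    valid result for a fish-free frame.
    """
    image = select_channel(image, params.channel)
    rect = calibration.panel_rect_px
    r0, c0, r1, c1 = rect
    crop = image[r0:r1, c0:c1]
    thr = choose_fish_threshold(image, rect, params.dark_fraction)
    fg = crop < thr
    if not fg.any():
        return []
    radius = params.closing_radius_px
    if radius is None:
        radius = max(1, int(round(params.line_width_mm / (2 * calibration.mm_per_px))))
    # morphology only needs to touch the neighbourhood of the foreground
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    pad = radius + 1
    wr0 = max(rows[0] - pad, 0)
    wr1 = min(rows[-1] + 1 + pad, fg.shape[0])
    wc0 = max(cols[0] - pad, 0)
    wc1 = min(cols[-1] + 1 + pad, fg.shape[1])
    window = fg[wr0:wr1, wc0:wc1]
    if radius > 0:
        yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
        disk = (xx * xx + yy * yy) <= radius * radius
        # edge-pad so the zero border of the erosion step cannot eat
        # foreground that legitimately touches the panel-crop boundary
        padded = np.pad(window, radius, mode="edge")
        padded = ndimage.binary_closing(padded, structure=disk)
        window = padded[radius:-radius, radius:-radius]
    if params.fill_holes:
        window = ndimage.binary_fill_holes(window)
    fg = np.zeros_like(fg)
    fg[wr0:wr1, wc0:wc1] = window
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    return _masks_from_labels(labels, (r0, c0))


def filter_components(
    masks: list[LabeledMask],
    min_area_mm2: float,
    calibration: GridCalibration,
) -> list[LabeledMask]:
    """Drop masks whose physical area falls below ``min_area_mm2``."""
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    px_area_scale = calibration.mm_per_px_x * calibration.mm_per_px_y
    return [m for m in masks if m.area_px * px_area_scale >= min_area_mm2]


def import_masks(labelled: np.ndarray | str | Path) -> list[LabeledMask]:
    """Build instance masks from an integer-labelled raster (0 = background).

    Accepts an array or a path to a labelled PNG (16-bit). This is the
    bridge for externally produced segmentations.
    """
    if isinstance(labelled, (str, Path)):
        labelled = iio.imread(labelled)
    labelled = np.asarray(labelled)
    if not np.issubdtype(labelled.dtype, np.integer):
        raise ValueError(
            f"labelled mask raster must have integer dtype, got {labelled.dtype}"
        )
    out: list[LabeledMask] = []
    for k, lab in enumerate(np.unique(labelled), start=0):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labelled == lab)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        region = labelled[r0:r1, c0:c1] == lab
        out.append(LabeledMask(label=int(lab), mask=region, bbox_px=(r0, c0, r1, c1)))
    return out


def export_masks(
    masks: list[LabeledMask], shape: tuple[int, int], path: str | Path | None = None
) -> np.ndarray:
    """Render instance masks into one 16-bit label raster; optionally save PNG."""
    out = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        r0, c0, r1, c1 = m.bbox_px
        out[r0:r1, c0:c1][m.mask] = m.label
    if path is not None:
        iio.imwrite(Path(path), out)
    return out
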