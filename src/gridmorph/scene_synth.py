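"""Synthetic luminous-grid-panel scenes with exact ground truth.

Emulates a tank camera looking down at an edge-lit acrylic panel whose
laser-etched grid lines glow: bright lines every ``cell_mm`` on a dimmer
interior, dark background outside the panel, and dark fusiform fish
silhouettes occluding the grid. Every rendered scene carries the exact
rasterised per-fish masks (recorded before blur/noise), the panel polygon
and the true mm-per-pixel scale, so the calibration, segmentation,
morphometry and gating stages can be tested against known truth without a
camera.

Conventions
-----------
Pixel indices are 0-based, row-major (row = y down, col = x right). Panel
coordinates are in mm with the origin at the panel's top-left corner; the
pixel with index ``(row, col)`` samples the scene at mm point
``((col + 0.5 - margin_px) * scale, (row + 0.5 - margin_px) * scale)``.
Bounding boxes are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PanelSpec",
    "FishSpec",
    "SceneConfig",
    "CirculationMotion",
    "FishOutOfBoundsError",
    "GridUnresolvableError",
    "FishMask",
    "GroundTruth",
    "Scene",
    "FrameSample",
    "render_panel",
    "render_scene",
    "generate_sequence",
    "write_fixture",
    "read_fixture",
]

# Minimum resolvable grid spacing: below 4 px/cell the line/interior
# alternation cannot be separated by the profile detector.
MIN_CELL_PX = 4.0


class GridUnresolvableError(ValueError):
    """Raised when the grid cell would span fewer than 4 pixels."""


class FishOutOfBoundsError(ValueError):
    """Raised when a fish silhouette extends outside the image bounds."""

    def __init__(self, fish_index: int, message: str | None = None):
        self.fish_index = fish_index
        super().__init__(
            message or f"fish {fish_index} extends outside the image bounds"
        )


@dataclass(frozen=True)
class PanelSpec:
    """True geometry and luminance of the light-emitting grid panel.

    Defaults are the 900 x 600 mm panel with 10 x 10 mm cells; the etched
    lines glow brightest, cell interiors glow dimmer, and the tank floor
    outside the panel is dark.
    """

    panel_width_mm: float = 900.0
    panel_height_mm: float = 600.0
    cell_mm: float = 10.0
    line_width_mm: float = 1.0
    line_intensity: float = 1.0
    interior_intensity: float = 0.55
    background_intensity: float = 0.05

    def __post_init__(self) -> None:
        if self.cell_mm <= 0:
            raise ValueError("cell_mm must be positive")
        for name in ("panel_width_mm", "panel_height_mm"):
            v = getattr(self, name)
            if v <= 0 or abs(v / self.cell_mm - round(v / self.cell_mm)) > 1e-9:
                raise ValueError(
                    f"{name}={v} must be a positive integer multiple of cell_mm"
                )
        if not (
            self.line_intensity
            > self.interior_intensity
            > self.background_intensity
        ):
            raise ValueError(
                "require line_intensity > interior_intensity > background_intensity"
            )

    @property
    def n_vertical_lines(self) -> int:
        return int(round(self.panel_width_mm / self.cell_mm)) + 1

    @property
    def n_horizontal_lines(self) -> int:
        return int(round(self.panel_height_mm / self.cell_mm)) + 1


@dataclass(frozen=True)
class FishSpec:
    """One fish silhouette: true size, pose and darkness.

    ``length_mm`` is the end-to-end extent along the major axis,
    ``width_mm`` the extent along the minor axis. ``orientation_deg`` is
    the major-axis angle from the image x-axis (y down, so positive angles
    turn clockwise on screen). ``shape`` is ``"ellipse"`` (analytically
    checkable area) or ``"fusiform"`` (tapered tail lobe, same extents).
    """

    length_mm: float
    width_mm: float
    centroid_mm: tuple[float, float]
    orientation_deg: float = 0.0
    intensity: float = 0.12
    shape: str = "ellipse"

    def __post_init__(self) -> None:
        if not (self.length_mm >= self.width_mm > 0):
            raise ValueError("require length_mm >= width_mm > 0")
        if self.shape not in ("ellipse", "fusiform"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic scene."""

    panel: PanelSpec = field(default_factory=PanelSpec)
    fish: tuple[FishSpec, ...] = ()
    scale_mm_per_px: float = 0.2
    margin_px: int = 25
    noise_sigma: float = 0.03
    blur_sigma: float = 0.5
    seed: int = 0
    clip_out_of_bounds: bool = False

    def __post_init__(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be >= 0")
        object.__setattr__(self, "fish", tuple(self.fish))

    @property
    def image_shape(self) -> tuple[int, int]:
        h = int(round(self.panel.panel_height_mm / self.scale_mm_per_px))
        w = int(round(self.panel.panel_width_mm / self.scale_mm_per_px))
        return (h + 2 * self.margin_px, w + 2 * self.margin_px)


@dataclass(frozen=True)
class FishMask:
    """Exact rasterised silhouette of one fish, cropped to its bbox.

    ``bbox_px`` is half-open ``(row0, col0, row1, col1)`` in full-image
    coordinates; ``mask`` has shape ``(row1-row0, col1-col0)``.
    """

    bbox_px: tuple[int, int, int, int]
    mask: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox_px
        full[r0:r1, c0:c1] = self.mask
        return full


@dataclass
class GroundTruth:
    """Exact truth for one rendered scene."""

    masks: list[FishMask]
    fish: list[FishSpec]
    panel_polygon_px: np.ndarray  # (4, 2) array of (x, y) corners
    scale_mm_per_px: float

    def true_area_px(self, i: int) -> int:
        return self.masks[i].area_px

    def true_area_mm2(self, i: int) -> float:
        """Area of the exact rasterised mask converted with the true scale."""
        return self.masks[i].area_px * self.scale_mm_per_px**2

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        """16-bit label raster; later fish overwrite earlier on overlap."""
        lab = np.zeros(shape, dtype=np.uint16)
        for i, m in enumerate(self.masks, start=1):
            r0, c0, r1, c1 = m.bbox_px
            lab[r0:r1, c0:c1][m.mask] = i
        return lab


@dataclass
class Scene:
    """A rendered frame plus its ground truth and generating config."""

    image: np.ndarray
    ground_truth: GroundTruth
    config: SceneConfig


@dataclass
class FrameSample:
    """One frame of a generated sequence."""

    index: int
    time_s: float
    image: np.ndarray
    ground_truth: GroundTruth


def _panel_rect_px(
    spec: PanelSpec, scale: float, margin_px: int
) -> tuple[int, int, int, int]:
    """Half-open pixel rect (row0, col0, row1, col1) covered by the panel."""
    h = int(round(spec.panel_height_mm / scale))
    w = int(round(spec.panel_width_mm / scale))
    return (margin_px, margin_px, margin_px + h, margin_px + w)


def _rect_polygon(rect: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = rect
    return np.array(
        [[c0, r0], [c1, r0], [c1, r1], [c0, r1]], dtype=float
    )


def render_panel(
    spec: PanelSpec, scale_mm_per_px: float, margin_px: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Render the empty glowing panel.

    Returns ``(image, panel_polygon)``: a float image in [0, 1] with bright
    grid lines at spacing ``cell_mm / scale_mm_per_px`` px, dimmer cell
    interiors, dark background, and the (4, 2) polygon of (x, y) pixel
    corners delimiting the panel.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    cell_px = spec.cell_mm / scale_mm_per_px
    if cell_px < MIN_CELL_PX:
        raise GridUnresolvableError(
            f"grid cell spans {cell_px:.2f} px (< {MIN_CELL_PX}); "
            "grid is unresolvable at this scale"
        )
    rect = _panel_rect_px(spec, scale_mm_per_px, margin_px)
    r0, c0, r1, c1 = rect
    img = np.full(
        (r1 + margin_px, c1 + margin_px), spec.background_intensity, dtype=np.float32
    )
    img[r0:r1, c0:c1] = spec.interior_intensity

    # Lines sit at every multiple of cell_mm; a line narrower than one pixel
    # still rasterises one pixel wide.
    half_w_px = max(spec.line_width_mm / scale_mm_per_px, 1.0) / 2.0
    for axis_len_mm, lo, hi, horizontal in (
        (spec.panel_width_mm, c0, c1, False),
        (spec.panel_height_mm, r0, r1, True),
    ):
        n_lines = int(round(axis_len_mm / spec.cell_mm)) + 1
        idx = np.arange(lo, hi)
        centers = (idx + 0.5 - margin_px) * scale_mm_per_px
        for k in range(n_lines):
            m = k * spec.cell_mm
            sel = idx[np.abs(centers - m) <= half_w_px * scale_mm_per_px]
            if sel.size == 0:
                sel = np.array([min(max(lo, round(m / scale_mm_per_px + margin_px - 0.5)), hi - 1)])
            if horizontal:
                img[sel, c0:c1] = spec.line_intensity
            else:
                img[r0:r1, sel] = spec.line_intensity
    return img, _rect_polygon(rect)


def _half_width_profile(s: np.ndarray, shape: str) -> np.ndarray:
    """Half-width of the silhouette at normalised axial position s in [-1, 1].

    Returned as a fraction of width_mm/2; zero outside [-1, 1].
    """
    s = np.clip(s, -1.0, 1.0)
    base = np.sqrt(np.maximum(0.0, 1.0 - s * s))
    if shape == "ellipse":
        return base
    # fusiform: elliptical head, linearly tapered rear third (tail lobe);
    # extents along both axes are unchanged.
    taper = np.where(s > 0.4, 1.0 - 0.5 * (s - 0.4) / 0.6, 1.0)
    return base * taper


def _rasterize_fish(
    fish: FishSpec, scale: float, margin_px: int, shape_px: tuple[int, int]
) -> tuple[FishMask, bool]:
    """Exact silhouette raster at pixel centres, clipped to the image.

    Returns ``(mask, out_of_bounds)``; the mask is empty when the fish is
    fully off-image.
    """
    a = fish.length_mm / 2.0
    b = fish.width_mm / 2.0
    cx, cy = fish.centroid_mm
    th = math.radians(fish.orientation_deg)
    cos_t, sin_t = math.cos(th), math.sin(th)
    # conservative bbox of the rotated ellipse, in mm
    hx = math.hypot(a * cos_t, b * sin_t)
    hy = math.hypot(a * sin_t, b * cos_t)
    H, W = shape_px
    c_lo = int(math.floor((cx - hx) / scale + margin_px - 0.5))
    c_hi = int(math.ceil((cx + hx) / scale + margin_px + 0.5))
    r_lo = int(math.floor((cy - hy) / scale + margin_px - 0.5))
    r_hi = int(math.ceil((cy + hy) / scale + margin_px + 0.5))
    out_of_bounds = c_lo < 0 or r_lo < 0 or c_hi > W or r_hi > H
    c_lo_c, r_lo_c = max(c_lo, 0), max(r_lo, 0)
    c_hi_c, r_hi_c = min(c_hi, W), min(r_hi, H)
    if c_lo_c >= c_hi_c or r_lo_c >= r_hi_c:
        return FishMask((0, 0, 0, 0), np.zeros((0, 0), bool)), True
    cols = np.arange(c_lo_c, c_hi_c)
    rows = np.arange(r_lo_c, r_hi_c)
    xm = (cols + 0.5 - margin_px) * scale - cx
    ym = (rows + 0.5 - margin_px) * scale - cy
    X, Y = np.meshgrid(xm, ym)
    u = X * cos_t + Y * sin_t  # along major axis
    v = -X * sin_t + Y * cos_t
    s = u / a
    half = _half_width_profile(s, fish.shape) * b
    inside = (np.abs(s) <= 1.0) & (np.abs(v) <= half)
    return FishMask((r_lo_c, c_lo_c, r_hi_c, c_hi_c), inside), out_of_bounds


def render_scene(config: SceneConfig) -> Scene:
    """Render a full scene: panel, fish silhouettes, blur, noise.

    Ground-truth masks are the exact rasterised silhouettes recorded before
    blur and noise. With ``clip_out_of_bounds`` unset, a fish whose
    silhouette leaves the image raises :class:`FishOutOfBoundsError` naming
    its index.
    """
    img, polygon = render_panel(
        config.panel, config.scale_mm_per_px, config.margin_px
    )
    masks: list[FishMask] = []
    for i, fish in enumerate(config.fish):
        if fish.intensity >= config.panel.interior_intensity:
            raise ValueError(
                f"fish {i} intensity {fish.intensity} is not darker than the "
                f"panel interior {config.panel.interior_intensity}"
            )
        fm, out_of_bounds = _rasterize_fish(
            fish, config.scale_mm_per_px, config.margin_px, img.shape
        )
        if out_of_bounds and not config.clip_out_of_bounds:
            raise FishOutOfBoundsError(i)
        masks.append(fm)
        r0, c0, r1, c1 = fm.bbox_px
        if fm.mask.size:
            img[r0:r1, c0:c1][fm.mask] = fish.intensity

    if config.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, config.blur_sigma)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        img = img + config.noise_sigma * noise
    img = np.clip(img, 0.0, 1.0)
    gt = GroundTruth(
        masks=masks,
        fish=list(config.fish),
        panel_polygon_px=polygon,
        scale_mm_per_px=config.scale_mm_per_px,
    )
    return Scene(image=img, ground_truth=gt, config=config)


@dataclass(frozen=True)
class CirculationMotion:
    """Circular-arc drift of fish around the tank centre.

    Fish centroids move on a circle of radius ``radius_mm`` about
    ``center_mm`` (panel coordinates; the centre may lie outside the
    panel), at ``angular_speed_deg_s`` degrees per second, each offset by
    an initial phase. Orientation follows the local tangent so the fish
    swims along the arc. ``radius_mm = 0`` degenerates to static fish at
    their configured poses.
    """

    center_mm: tuple[float, float]
    radius_mm: float
    angular_speed_deg_s: float
    phase_deg: tuple[float, ...] = ()


def _fish_at_time(
    base: Sequence[FishSpec], motion: CirculationMotion, t: float
) -> tuple[FishSpec, ...]:
    if motion.radius_mm == 0:
        return tuple(base)
    out = []
    for i, f in enumerate(base):
        phase = motion.phase_deg[i] if i < len(motion.phase_deg) else i * 360.0 / max(len(base), 1)
        ang = math.radians(phase + motion.angular_speed_deg_s * t)
        cx = motion.center_mm[0] + motion.radius_mm * math.cos(ang)
        cy = motion.center_mm[1] + motion.radius_mm * math.sin(ang)
        # tangent direction of the (counter-clockwise in image coords) arc
        tangent = math.degrees(math.atan2(math.cos(ang), -math.sin(ang)))
        out.append(
            dataclasses.replace(f, centroid_mm=(cx, cy), orientation_deg=tangent)
        )
    return tuple(out)


def generate_sequence(
    config: SceneConfig,
    fps: float,
    duration_s: float,
    motion: CirculationMotion,
) -> Iterator[FrameSample]:
    """Yield ``floor(fps * duration_s)`` frames of circulating fish.

    Each frame is rendered independently with a child seed derived from
    ``config.seed`` and the frame index, so regeneration is bit-identical.
    Fish are clipped at the image border (they may leave and re-enter the
    field of view as they circulate).
    """
    if fps <= 0 or duration_s <= 0:
        raise ValueError("fps and duration_s must be positive")
    n_frames = int(math.floor(fps * duration_s))
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_frames)]
    for k in range(n_frames):
        t = k / fps
        frame_cfg = dataclasses.replace(
            config,
            fish=_fish_at_time(config.fish, motion, t),
            seed=child_seeds[k],
            clip_out_of_bounds=True,
        )
        scene = render_scene(frame_cfg)
        yield FrameSample(
            index=k, time_s=t, image=scene.image, ground_truth=scene.ground_truth
        )


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)


def _config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["fish"] = [dataclasses.asdict(f) for f in config.fish]
    return d


def config_from_dict(d: dict) -> SceneConfig:
    panel = PanelSpec(**d["panel"])
    fish = tuple(
        FishSpec(**{**f, "centroid_mm": tuple(f["centroid_mm"])})
        for f in d["fish"]
    )
    rest = {
        k: v for k, v in d.items() if k not in ("panel", "fish")
    }
    return SceneConfig(panel=panel, fish=fish, **rest)


def write_fixture(
    scenes: Scene | Sequence[Scene] | Iterator[FrameSample],
    directory: str | Path,
) -> Path:
    """Write frames (8-bit PNG), label masks (16-bit PNG) and a JSON manifest.

    Returns the manifest path. The manifest records each frame's file
    names, per-fish truth, the panel polygon, scale and generating config,
    so the fixture round-trips and can be regenerated bit-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(scenes, Scene):
        items: list = [scenes]
    else:
        items = list(scenes)
    manifest: dict = {"frames": [], "masks": [], "records": []}
    for k, item in enumerate(items):
        if isinstance(item, Scene):
            image, gt, cfg = item.image, item.ground_truth, item.config
            manifest["config"] = _config_to_dict(cfg)
        else:
            image, gt = item.image, item.ground_truth
        frame_name = f"frame_{k:05d}.png"
        mask_name = f"masks/mask_{k:05d}.png"
        (directory / "masks").mkdir(exist_ok=True)
        try:
            iio.imwrite(directory / frame_name, _quantize(image))
            iio.imwrite(
                directory / mask_name, gt.label_image(image.shape[:2])
            )
        except OSError as exc:
            raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
        manifest["frames"].append(frame_name)
        manifest["masks"].append(mask_name)
        manifest["records"].append(
            {
                "fish": [dataclasses.asdict(f) for f in gt.fish],
                "mask_areas_px": [m.area_px for m in gt.masks],
                "panel_polygon_px": gt.panel_polygon_px.tolist(),
                "scale_mm_per_px": gt.scale_mm_per_px,
            }
        )
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_fixture(directory: str | Path) -> tuple[dict, list[np.ndarray], list[np.ndarray]]:
    """Read a fixture directory back: (manifest, frames, label masks)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = [iio.imread(directory / f) for f in manifest["frames"]]
    masks = [iio.imread(directory / f) for f in manifest["masks"]]
    return manifest, frames, masks
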