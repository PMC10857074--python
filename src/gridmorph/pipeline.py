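"""Per-frame and per-sequence orchestration, evaluation and benchmarks.

``process_frame`` chains the stages — segmentation, component filtering,
morphometry, in-grid gating — under one calibration and returns a
:class:`FrameReport`. ``process_sequence`` maps that over an ordered frame
source with optional per-frame recalibration and aggregates a summary.
``evaluate`` scores predicted masks against ground truth with greedy IoU
matching, whole-frame pixel accuracy, and per-fish length/area errors.
``run_size_benchmark`` renders the five-model-fish measurement protocol
(multiple seeded poses per size) and tabulates per-fish accuracy.

The pipeline is frame-synchronous and stateless across frames: each frame
is measured on its own, as on a live monitor; no identity tracking.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import scene_synth
from .calibration import (
    CalibrationError,
    GridCalibration,
    calibrate_image,
    fixed_scale_calibration,
)
from .gating import (
    DEFAULT_INSIDE_THRESHOLD,
    DEFAULT_SOLIDITY_FLOOR,
    GateResult,
    classify_inside,
    count_inside,
    detect_overlap,
    iou,
)
from .morphometry import Measurement, measure
from .scene_synth import FishSpec, GroundTruth, PanelSpec, SceneConfig
from .segmentation import (
    LabeledMask,
    SegmentationParams,
    filter_components,
    segment_dark_objects,
    select_channel,
)

__all__ = [
    "PipelineConfig",
    "FrameReport",
    "EvaluationResult",
    "process_frame",
    "process_sequence",
    "evaluate",
    "evaluate_frame",
    "run_size_benchmark",
    "benchmark_targets",
    "reports_to_dataframe",
    "draw_overlay",
    "PAPER_FISH_LENGTHS_MM",
]

logger = logging.getLogger("gridmorph")

# The five mock-fish model lengths of the validation protocol, mm.
PAPER_FISH_LENGTHS_MM = (600.0, 450.0, 448.0, 315.0, 270.0)

# Fusiform aspect ratio (length/width) used for synthetic benchmark fish.
BENCHMARK_ASPECT = 4.5


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the measurement pipeline."""

    cell_mm: float = 10.0
    fixed_mm_per_px: float | None = None
    recalibrate_per_frame: bool = False
    inside_threshold: float = DEFAULT_INSIDE_THRESHOLD
    min_area_mm2: float = 500.0
    max_single_area_mm2: float | None = None
    solidity_floor: float = DEFAULT_SOLIDITY_FLOOR
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    @property
    def expected_max_area_mm2(self) -> float:
        if self.max_single_area_mm2 is not None:
            return self.max_single_area_mm2
        # default: 1.6 x the area of the largest benchmark fish body
        L = max(PAPER_FISH_LENGTHS_MM)
        return 1.6 * math.pi * (L / 2.0) * (L / BENCHMARK_ASPECT / 2.0)


@dataclass
class FrameReport:
    """Everything measured on one frame."""

    frame_id: str
    measurements: list[Measurement]
    gates: list[GateResult]
    count_inside: int
    count_min: int
    calibration_ref: str = ""
    timestamp: float | None = None
    masks: list[LabeledMask] = field(default_factory=list, repr=False)

    def rows(self) -> list[dict]:
        out = []
        for m, g in zip(self.measurements, self.gates):
            row = {"frame": self.frame_id, **m.to_row(), **g.to_row()}
            row.pop("label", None)
            row["label"] = m.label
            out.append(row)
        return out


@dataclass
class EvaluationResult:
    """Score of one predicted instance (or a miss) against ground truth."""

    frame_id: str
    pred_label: int | None
    gt_index: int
    iou: float
    pixel_accuracy: float
    length_abs_error_mm: float
    length_rel_error_pct: float
    area_rel_error_pct: float


def _get_calibration(
    image: np.ndarray, config: PipelineConfig
) -> GridCalibration:
    if config.fixed_mm_per_px is not None:
        return fixed_scale_calibration(
            config.fixed_mm_per_px, image.shape[:2], config.cell_mm
        )
    return calibrate_image(select_channel(image, config.segmentation.channel), config.cell_mm)


def _touches_rect_border(
    bbox: tuple[int, int, int, int], rect: tuple[int, int, int, int]
) -> bool:
    r0, c0, r1, c1 = bbox
    pr0, pc0, pr1, pc1 = rect
    return r0 <= pr0 or c0 <= pc0 or r1 >= pr1 or c1 >= pc1


def process_frame(
    image: np.ndarray,
    calibration: GridCalibration,
    config: PipelineConfig = PipelineConfig(),
    frame_id: str = "0",
    masks: list[LabeledMask] | None = None,
) -> FrameReport:
    """Segment, filter, measure and gate one frame.

    Out-of-grid fish are still measured and reported with
    ``inside_grid=False``; only in-grid, non-overlapping fish enter the
    count. Pass ``masks`` to measure an externally produced segmentation
    (e.g. from :func:`gridmorph.segmentation.import_masks`) instead of
    running the built-in segmenter. Internally segmented masks touching
    the panel-region border are treated as truncated (the fish extends
    beyond the measurable region) and gated out of the count.
    """
    t0 = time.perf_counter()
    internally_segmented = masks is None
    if internally_segmented:
        try:
            masks = segment_dark_objects(image, calibration, config.segmentation)
        except CalibrationError as exc:
            raise CalibrationError(f"frame {frame_id}: {exc}") from exc
    masks = filter_components(masks, config.min_area_mm2, calibration)
    flags = detect_overlap(
        masks, calibration, config.expected_max_area_mm2, config.solidity_floor
    )
    measurements: list[Measurement] = []
    gates: list[GateResult] = []
    for m, flag in zip(masks, flags):
        meas = measure(m, calibration)
        gate = classify_inside(
            m, calibration.panel_polygon_px, config.inside_threshold
        )
        gate.overlapping = flag
        if internally_segmented and gate.inside and _touches_rect_border(
            m.bbox_px, calibration.panel_rect_px
        ):
            gate.inside = False  # clipped at the measurable-region border
        meas.inside_grid = gate.inside
        measurements.append(meas)
        gates.append(gate)
    count, count_min = count_inside(gates)
    ms = (time.perf_counter() - t0) * 1e3
    logger.info(
        "frame=%s n_masks=%d count=%d count_min=%d ms=%.1f",
        frame_id, len(masks), count, count_min, ms,
    )
    return FrameReport(
        frame_id=str(frame_id),
        measurements=measurements,
        gates=gates,
        count_inside=count,
        count_min=count_min,
        masks=masks,
    )


def process_sequence(
    frames: Iterable,
    config: PipelineConfig = PipelineConfig(),
    calibration: GridCalibration | None = None,
) -> tuple[list[FrameReport], dict]:
    """Run the pipeline over an ordered frame source.

    ``frames`` yields images, ``(frame_id, image)`` pairs, image file
    paths, or :class:`scene_synth.FrameSample` objects. Unreadable frames
    are logged, skipped, and counted in the summary. The first readable
    frame calibrates the run unless ``recalibrate_per_frame`` is set or a
    calibration is supplied.
    """
    import imageio.v3 as iio

    reports: list[FrameReport] = []
    skipped = 0
    prev_scale: float | None = None
    for k, item in enumerate(frames):
        frame_id = str(k)
        try:
            if isinstance(item, scene_synth.FrameSample):
                frame_id, image = str(item.index), item.image
            elif isinstance(item, (str, Path)):
                frame_id = Path(item).stem
                image = iio.imread(item)
            elif isinstance(item, tuple):
                frame_id, image = str(item[0]), item[1]
            else:
                image = item
            image = select_channel(np.asarray(image), config.segmentation.channel)
        except Exception as exc:  # unreadable frame: log, skip, count
            logger.warning("frame %s unreadable: %s", frame_id, exc)
            skipped += 1
            continue
        if calibration is None or config.recalibrate_per_frame:
            try:
                cal = calibrate_image(image, config.cell_mm) if config.fixed_mm_per_px is None else fixed_scale_calibration(config.fixed_mm_per_px, image.shape[:2], config.cell_mm)
            except CalibrationError as exc:
                raise CalibrationError(f"frame {frame_id}: {exc}") from exc
            if prev_scale is not None and abs(cal.mm_per_px - prev_scale) / prev_scale > 0.05:
                logger.warning(
                    "frame %s: calibration drift %.1f%%",
                    frame_id, 100 * abs(cal.mm_per_px - prev_scale) / prev_scale,
                )
            prev_scale = cal.mm_per_px
            if not config.recalibrate_per_frame:
                calibration = cal
        else:
            cal = calibration
        reports.append(process_frame(image, cal, config, frame_id))
    in_grid = [
        m
        for r in reports
        for m, g in zip(r.measurements, r.gates)
        if g.inside and not g.overlapping
    ]
    lengths = np.array([m.length_mm for m in in_grid])
    areas = np.array([m.area_mm2 for m in in_grid])
    summary = {
        "n_frames": len(reports),
        "n_skipped": skipped,
        "n_in_grid_measurements": len(in_grid),
        "mean_length_mm": float(lengths.mean()) if len(in_grid) else None,
        "median_length_mm": float(np.median(lengths)) if len(in_grid) else None,
        "mean_area_mm2": float(areas.mean()) if len(in_grid) else None,
        "median_area_mm2": float(np.median(areas)) if len(in_grid) else None,
        "total_count_inside": int(sum(r.count_inside for r in reports)),
    }
    return reports, summary


def evaluate_frame(
    pred_masks: Sequence[LabeledMask],
    gt: GroundTruth,
    shape: tuple[int, int],
    calibration: GridCalibration | None = None,
    frame_id: str = "0",
) -> list[EvaluationResult]:
    """Greedy IoU matching of predictions to truth on one frame.

    Every ground-truth fish yields one result; unmatched truth is a miss
    with IoU 0. Pixel accuracy is the whole-frame fraction of pixels whose
    foreground/background label agrees with truth.
    """
    gt_full = [m.to_full(shape) for m in gt.masks]
    pred_full = [m.to_full(shape) for m in pred_masks]
    pred_union = np.logical_or.reduce(pred_full) if pred_full else np.zeros(shape, bool)
    gt_union = np.logical_or.reduce(gt_full) if gt_full else np.zeros(shape, bool)
    pixel_acc = float(np.mean(pred_union == gt_union))

    pairs = []
    for gi, g in enumerate(gt_full):
        for pi, p in enumerate(pred_full):
            inter = np.logical_and(g, p).sum()
            if inter:
                union = np.logical_or(g, p).sum()
                pairs.append((inter / union, gi, pi))
    pairs.sort(reverse=True)
    matched_g: dict[int, tuple[int, float]] = {}
    used_p: set[int] = set()
    for val, gi, pi in pairs:
        if gi in matched_g or pi in used_p:
            continue
        matched_g[gi] = (pi, val)
        used_p.add(pi)

    results = []
    for gi, fish in enumerate(gt.fish):
        true_len = fish.length_mm
        true_area = gt.true_area_mm2(gi)
        if gi in matched_g:
            pi, val = matched_g[gi]
            if calibration is not None:
                meas = measure(pred_masks[pi], calibration)
                len_err = abs(meas.length_mm - true_len)
                area_err = abs(meas.area_mm2 - true_area) / true_area * 100.0
            else:
                len_err, area_err = float("nan"), float("nan")
            results.append(
                EvaluationResult(
                    frame_id=frame_id,
                    pred_label=pred_masks[pi].label,
                    gt_index=gi,
                    iou=float(val),
                    pixel_accuracy=pixel_acc,
                    length_abs_error_mm=len_err,
                    length_rel_error_pct=len_err / true_len * 100.0,
                    area_rel_error_pct=area_err,
                )
            )
        else:
            results.append(
                EvaluationResult(
                    frame_id=frame_id,
                    pred_label=None,
                    gt_index=gi,
                    iou=0.0,
                    pixel_accuracy=pixel_acc,
                    length_abs_error_mm=float("nan"),
                    length_rel_error_pct=float("nan"),
                    area_rel_error_pct=float("nan"),
                )
            )
    return results


def evaluate(
    reports: Sequence[FrameReport],
    ground_truths: Sequence[GroundTruth],
    shape: tuple[int, int],
    calibration: GridCalibration | None = None,
    frame_ids: Sequence[str] | None = None,
) -> list[EvaluationResult]:
    """Evaluate a run against per-frame ground truth (ids must align)."""
    if len(reports) != len(ground_truths):
        raise ValueError(
            f"{len(reports)} reports vs {len(ground_truths)} ground-truth frames"
        )
    if frame_ids is not None:
        for r, fid in zip(reports, frame_ids):
            if r.frame_id != str(fid):
                raise ValueError(f"frame-id mismatch: {r.frame_id} vs {fid}")
    out: list[EvaluationResult] = []
    for r, gt in zip(reports, ground_truths):
        out.extend(
            evaluate_frame(r.masks, gt, shape, calibration, frame_id=r.frame_id)
        )
    return out


def reports_to_dataframe(reports: Sequence[FrameReport]) -> pd.DataFrame:
    """Flatten reports to one row per measurement (the CSV report format)."""
    rows = [row for r in reports for row in r.rows()]
    cols = [
        "frame", "label", "length_mm", "width_mm", "area_mm2", "area_px",
        "angle_deg", "inside_grid", "inside_fraction", "iou_with_panel",
        "inside", "overlapping",
    ]
    df = pd.DataFrame(rows)
    return df.reindex(columns=cols) if len(df) else pd.DataFrame(columns=cols)


def _sample_pose(
    rng: np.random.Generator,
    length_mm: float,
    width_mm: float,
    panel: PanelSpec,
    pad_mm: float = 15.0,
) -> tuple[tuple[float, float], float]:
    """Random orientation + centroid keeping the fish fully on the panel."""
    a, b = length_mm / 2.0, width_mm / 2.0
    for _ in range(256):
        theta = rng.uniform(0.0, 180.0)
        th = math.radians(theta)
        hx = math.hypot(a * math.cos(th), b * math.sin(th))
        hy = math.hypot(a * math.sin(th), b * math.cos(th))
        if (
            2 * (hx + pad_mm) <= panel.panel_width_mm
            and 2 * (hy + pad_mm) <= panel.panel_height_mm
        ):
            cx = rng.uniform(hx + pad_mm, panel.panel_width_mm - hx - pad_mm)
            cy = rng.uniform(hy + pad_mm, panel.panel_height_mm - hy - pad_mm)
            return (cx, cy), theta
    raise ValueError(
        f"fish of length {length_mm} mm cannot fit on the panel at any sampled pose"
    )


def run_size_benchmark(
    seed: int = 0,
    sizes_mm: Sequence[float] = PAPER_FISH_LENGTHS_MM,
    poses: int = 20,
    scale_mm_per_px: float = 0.2,
    noise_sigma: float = 0.03,
    blur_sigma: float = 0.5,
    panel: PanelSpec | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Five-model-fish measurement protocol on synthetic scenes.

    Renders one fish per scene — each true size at ``poses`` seeded random
    orientations/positions on the 900 x 600 mm panel — runs the full
    pipeline (self-calibration, segmentation, morphometry, gating) and
    returns one row per scene with estimated vs true length and area and
    the derived accuracies.
    """
    panel = panel or PanelSpec()
    config = config or PipelineConfig()
    rows = []
    for si, L in enumerate(sizes_mm):
        W = L / BENCHMARK_ASPECT
        for pose in range(poses):
            ss = np.random.SeedSequence([seed, si, pose])
            rng = np.random.default_rng(ss)
            centroid, theta = _sample_pose(rng, L, W, panel)
            scene_seed = int(ss.generate_state(1)[0] % (2**31))
            scene_cfg = SceneConfig(
                panel=panel,
                fish=(
                    FishSpec(
                        length_mm=L, width_mm=W, centroid_mm=centroid,
                        orientation_deg=theta,
                    ),
                ),
                scale_mm_per_px=scale_mm_per_px,
                noise_sigma=noise_sigma,
                blur_sigma=blur_sigma,
                seed=scene_seed,
            )
            scene = scene_synth.render_scene(scene_cfg)
            cal = _get_calibration(scene.image, config)
            report = process_frame(scene.image, cal, config, frame_id=f"{si}_{pose}")
            gt = scene.ground_truth
            true_area = gt.true_area_mm2(0)
            candidates = [
                m for m, g in zip(report.measurements, report.gates)
                if g.inside and not g.overlapping
            ]
            if candidates:
                meas = max(candidates, key=lambda m: m.area_px)
                est_len, est_area = meas.length_mm, meas.area_mm2
            else:
                est_len, est_area = float("nan"), float("nan")
            len_err = abs(est_len - L)
            rows.append(
                {
                    "true_length_mm": L,
                    "pose": pose,
                    "orientation_deg": theta,
                    "est_length_mm": est_len,
                    "length_abs_error_mm": len_err,
                    "length_rel_error_pct": len_err / L * 100.0,
                    "length_accuracy_pct": 100.0 * (1.0 - len_err / L),
                    "true_area_mm2": true_area,
                    "est_area_mm2": est_area,
                    "area_rel_error_pct": abs(est_area - true_area) / true_area * 100.0,
                    "area_accuracy_pct": 100.0 * (1.0 - abs(est_area - true_area) / true_area),
                    "mm_per_px": cal.mm_per_px,
                    "count_inside": report.count_inside,
                }
            )
    return pd.DataFrame(rows)


def benchmark_targets(table: pd.DataFrame) -> dict:
    """Headline statistics of a :func:`run_size_benchmark` table.

    Returns the maximum absolute length error of the 450 mm fish, the
    maximum relative length error over all sizes and poses, and the
    minimum accuracy over both length and area.
    """
    sub450 = table[table["true_length_mm"] == 450.0]
    return {
        "max_abs_error_450_mm": float(sub450["length_abs_error_mm"].max()),
        "max_rel_error_pct": float(table["length_rel_error_pct"].max()),
        "min_accuracy_pct": float(
            min(table["length_accuracy_pct"].min(), table["area_accuracy_pct"].min())
        ),
    }


def draw_overlay(
    image: np.ndarray, report: FrameReport, color=(255, 64, 64)
) -> np.ndarray:
    """Annotated RGB frame: mask outlines, oriented boxes, length labels."""
    from skimage.draw import line as draw_line
    from skimage.segmentation import find_boundaries

    img = select_channel(image)
    rgb = np.stack([np.clip(img * 255, 0, 255).astype(np.uint8)] * 3, axis=-1)
    for mask, meas in zip(report.masks, report.measurements):
        full = mask.to_full(img.shape)
        boundary = find_boundaries(full, mode="outer")
        rgb[boundary] = color
        corners = meas.oriented_box.corners_px
        for i in range(4):
            x0, y0 = corners[i]
            x1, y1 = corners[(i + 1) % 4]
            rr, cc = draw_line(
                int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
            )
            keep = (rr >= 0) & (rr < rgb.shape[0]) & (cc >= 0) & (cc < rgb.shape[1])
            rgb[rr[keep], cc[keep]] = (64, 255, 64)
    return rgb


def write_report(
    reports: Sequence[FrameReport], summary: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the CSV measurement report and JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "measurements.csv"
    reports_to_dataframe(reports).to_csv(csv_path, index=False)
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=1))
    return csv_path, json_path
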