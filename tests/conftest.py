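"""Shared small-scale synthetic fixtures.

Module tests run on a miniature panel (200 x 150 mm at 1 mm/px) so the
whole suite stays fast; the acceptance tests use the full 900 x 600 mm
geometry.
"""

import numpy as np
import pytest

from gridmorph.scene_synth import (
    FishSpec,
    PanelSpec,
    SceneConfig,
    render_scene,
)

SMALL_SCALE = 1.0  # mm per px


@pytest.fixture(scope="session")
def small_panel() -> PanelSpec:
    return PanelSpec(panel_width_mm=200.0, panel_height_mm=150.0, cell_mm=10.0)


@pytest.fixture(scope="session")
def small_fish() -> FishSpec:
    return FishSpec(
        length_mm=60.0, width_mm=16.0, centroid_mm=(100.0, 75.0),
        orientation_deg=25.0,
    )


def make_scene(panel, fish=(), *, scale=SMALL_SCALE, noise=0.0, blur=0.0,
               seed=0, margin_px=10, clip=False):
    cfg = SceneConfig(
        panel=panel,
        fish=tuple(fish),
        scale_mm_per_px=scale,
        noise_sigma=noise,
        blur_sigma=blur,
        seed=seed,
        margin_px=margin_px,
        clip_out_of_bounds=clip,
    )
    return render_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_scene(small_panel, small_fish):
    return make_scene(small_panel, [small_fish])


@pytest.fixture(scope="session")
def empty_scene(small_panel):
    return make_scene(small_panel)


def brute_force_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Independent pixel-by-pixel IoU (oracle; no vector tricks)."""
    inter = union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] and b[i, j]:
                inter += 1
            if a[i, j] or b[i, j]:
                union += 1
    if union == 0:
        raise ZeroDivisionError
    return inter / union
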