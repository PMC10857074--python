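"""Synthetic scene generator: geometry, determinism, fixtures."""

import math

import numpy as np
import pytest

from gridmorph.scene_synth import (
    CirculationMotion,
    FishOutOfBoundsError,
    FishSpec,
    GridUnresolvableError,
    PanelSpec,
    SceneConfig,
    config_from_dict,
    generate_sequence,
    read_fixture,
    render_panel,
    render_scene,
    write_fixture,
)

from conftest import make_scene


class TestRenderPanel:
    def test_line_counts_and_spacing_at_paper_geometry(self):
        spec = PanelSpec()  # 900 x 600 mm, 10 mm cells
        assert spec.n_vertical_lines == 91
        assert spec.n_horizontal_lines == 61
        img, poly = render_panel(spec, 0.2, margin_px=25)
        # columns at full line intensity, probed along a cell-interior row
        # (row 1550 samples y = 305.1 mm, between horizontal lines)
        col = img[1550, 25:4525]
        line_cols = np.flatnonzero(col == spec.line_intensity)
        groups = np.split(line_cols, np.flatnonzero(np.diff(line_cols) > 1) + 1)
        assert len(groups) == 91
        centers = np.array([g.mean() for g in groups])
        # boundary lines are clipped by the panel edge; interior spacing exact
        assert np.allclose(np.diff(centers)[1:-1], 50.0, atol=0.5)

    def test_unresolvable_cell_rejected(self):
        with pytest.raises(GridUnresolvableError):
            render_panel(PanelSpec(), 5.0)  # 2 px per 10 mm cell

    def test_background_outside_polygon(self):
        spec = PanelSpec(
            panel_width_mm=100, panel_height_mm=50, background_intensity=0.0
        )
        img, poly = render_panel(spec, 1.0, margin_px=7)
        x0, y0 = poly[0]
        x1, y1 = poly[2]
        outside = np.ones(img.shape, bool)
        outside[int(y0):int(y1), int(x0):int(x1)] = False
        assert np.all(img[outside] == 0.0)

    def test_zero_margin_polygon_covers_image(self):
        img, poly = render_panel(
            PanelSpec(panel_width_mm=100, panel_height_mm=50), 1.0, margin_px=0
        )
        assert img.shape == (50, 100)
        assert poly.tolist() == [[0, 0], [100, 0], [100, 50], [0, 50]]

    def test_panel_invariants_enforced(self):
        with pytest.raises(ValueError):
            PanelSpec(panel_width_mm=95.0)  # not a multiple of 10
        with pytest.raises(ValueError):
            PanelSpec(interior_intensity=1.5)


class TestRenderScene:
    def test_axis_aligned_mask_extent_matches_true_length(self, small_panel):
        fish = FishSpec(60.0, 16.0, centroid_mm=(100.0, 75.0))
        scene = make_scene(small_panel, [fish], scale=0.5)
        fm = scene.ground_truth.masks[0]
        cols = np.flatnonzero(fm.mask.any(axis=0))
        extent = cols[-1] - cols[0] + 1
        assert abs(extent - 60.0 / 0.5) <= 1

    def test_ellipse_mask_area_matches_brute_force_and_analytic(self, small_panel):
        fish = FishSpec(60.0, 16.0, centroid_mm=(100.0, 75.0), orientation_deg=30.0)
        scene = make_scene(small_panel, [fish], scale=0.5, margin_px=5)
        fm = scene.ground_truth.masks[0]
        # independent oracle: test the ellipse inequality at every pixel centre
        scale, margin = 0.5, 5
        th = math.radians(30.0)
        count = 0
        r0, c0, r1, c1 = fm.bbox_px
        for r in range(r0, r1):
            for c in range(c0, c1):
                x = (c + 0.5 - margin) * scale - 100.0
                y = (r + 0.5 - margin) * scale - 75.0
                u = x * math.cos(th) + y * math.sin(th)
                v = -x * math.sin(th) + y * math.cos(th)
                if abs(u / 30.0) <= 1 and abs(v) <= 8.0 * math.sqrt(
                    max(0.0, 1 - (u / 30.0) ** 2)
                ):
                    count += 1
        assert fm.area_px == count
        analytic_px = math.pi * 30.0 * 8.0 / scale**2
        assert abs(fm.area_px - analytic_px) / analytic_px < 0.01

    def test_determinism_bit_identical(self, small_panel, small_fish):
        a = make_scene(small_panel, [small_fish], noise=0.05, blur=0.7, seed=42)
        b = make_scene(small_panel, [small_fish], noise=0.05, blur=0.7, seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.ground_truth.masks[0].mask, b.ground_truth.masks[0].mask)

    def test_out_of_bounds_fish_names_index(self, small_panel):
        ok = FishSpec(40.0, 10.0, centroid_mm=(100.0, 75.0))
        bad = FishSpec(40.0, 10.0, centroid_mm=(199.0, 75.0))
        with pytest.raises(FishOutOfBoundsError) as exc:
            make_scene(small_panel, [ok, bad])
        assert exc.value.fish_index == 1

    def test_clip_mode_keeps_masks_in_bounds(self, small_panel):
        bad = FishSpec(40.0, 10.0, centroid_mm=(205.0, 75.0))
        scene = make_scene(small_panel, [bad], clip=True)
        fm = scene.ground_truth.masks[0]
        assert fm.bbox_px[3] <= scene.image.shape[1]
        assert 0 < fm.area_px < math.pi * 20 * 5 / 1.0**2

    def test_masks_pairwise_disjoint(self, small_panel):
        fish = [
            FishSpec(40.0, 10.0, centroid_mm=(50.0, 40.0), orientation_deg=10),
            FishSpec(40.0, 10.0, centroid_mm=(150.0, 110.0), orientation_deg=100),
        ]
        scene = make_scene(small_panel, fish)
        a, b = (m.to_full(scene.image.shape) for m in scene.ground_truth.masks)
        assert not np.logical_and(a, b).any()

    def test_scale_consistency_invariant(self, small_panel):
        # major-axis extent of the mask, in mm, within one cell diagonal
        fish = FishSpec(70.0, 18.0, centroid_mm=(100.0, 75.0), orientation_deg=55.0)
        scene = make_scene(small_panel, [fish], scale=0.5)
        full = scene.ground_truth.masks[0].to_full(scene.image.shape)
        coords = np.argwhere(full).astype(float)
        th = math.radians(55.0)
        u = coords[:, 1] * math.cos(th) + coords[:, 0] * math.sin(th)
        extent_mm = (u.max() - u.min() + 1) * 0.5
        assert abs(extent_mm - 70.0) <= 10.0 * math.sqrt(2)

    def test_fusiform_shape_keeps_extents_and_shrinks_area(self, small_panel):
        ell = FishSpec(60.0, 16.0, centroid_mm=(100.0, 75.0))
        fus = FishSpec(60.0, 16.0, centroid_mm=(100.0, 75.0), shape="fusiform")
        s_e = make_scene(small_panel, [ell], scale=0.5)
        s_f = make_scene(small_panel, [fus], scale=0.5)
        me, mf = s_e.ground_truth.masks[0], s_f.ground_truth.masks[0]
        cols_e = np.flatnonzero(me.mask.any(axis=0))
        cols_f = np.flatnonzero(mf.mask.any(axis=0))
        assert abs(len(cols_e) - len(cols_f)) <= 1  # same length extent
        assert mf.area_px < me.area_px  # tail taper removes body area


class TestSequences:
    def test_frame_count_is_floor_of_fps_times_duration(self, small_panel):
        motion = CirculationMotion(center_mm=(100, 75), radius_mm=0, angular_speed_deg_s=0)
        cfg = SceneConfig(panel=small_panel, scale_mm_per_px=2.0, margin_px=5,
                          noise_sigma=0, blur_sigma=0)
        assert sum(1 for _ in generate_sequence(cfg, fps=2, duration_s=5, motion=motion)) == 10
        assert sum(1 for _ in generate_sequence(cfg, fps=2.5, duration_s=4.2, motion=motion)) == 10

    def test_paper_protocol_frame_count(self, small_panel):
        # 60 fps for 30 s -> 1800 frames
        motion = CirculationMotion(center_mm=(100, 75), radius_mm=0, angular_speed_deg_s=0)
        cfg = SceneConfig(panel=small_panel, scale_mm_per_px=2.5, margin_px=2,
                          noise_sigma=0, blur_sigma=0)
        assert sum(1 for _ in generate_sequence(cfg, fps=60, duration_s=30, motion=motion)) == 1800

    def test_zero_amplitude_motion_is_static(self, small_panel, small_fish):
        motion = CirculationMotion(center_mm=(100, 75), radius_mm=0, angular_speed_deg_s=90)
        cfg = SceneConfig(panel=small_panel, fish=(small_fish,), noise_sigma=0,
                          blur_sigma=0, margin_px=10)
        frames = list(generate_sequence(cfg, fps=3, duration_s=1, motion=motion))
        ref = frames[0].ground_truth.masks[0]
        for f in frames[1:]:
            assert f.ground_truth.masks[0].bbox_px == ref.bbox_px
            assert np.array_equal(f.ground_truth.masks[0].mask, ref.mask)

    def test_circulating_fish_enters_and_exits_panel(self, small_panel):
        fish = FishSpec(30.0, 8.0, centroid_mm=(0.0, 0.0))
        # circle centred below the panel: its top arc sweeps across the
        # panel, the rest of the orbit lies outside it
        motion = CirculationMotion(
            center_mm=(100.0, 160.0), radius_mm=120.0, angular_speed_deg_s=90.0
        )
        cfg = SceneConfig(panel=small_panel, fish=(fish,), scale_mm_per_px=1.0,
                          margin_px=60, noise_sigma=0, blur_sigma=0,
                          clip_out_of_bounds=True)
        on_panel = []
        for f in generate_sequence(cfg, fps=8, duration_s=4, motion=motion):
            poly = f.ground_truth.panel_polygon_px
            fm = f.ground_truth.masks[0]
            if fm.area_px == 0:
                on_panel.append(False)
                continue
            coords = np.argwhere(fm.to_full(f.image.shape))
            inside = (
                (coords[:, 1] >= poly[0][0]) & (coords[:, 1] < poly[2][0])
                & (coords[:, 0] >= poly[0][1]) & (coords[:, 0] < poly[2][1])
            )
            on_panel.append(bool(inside.all()) and fm.area_px > 0)
        assert any(on_panel) and not all(on_panel)

    def test_sequence_regeneration_is_bit_identical(self, small_panel, small_fish):
        motion = CirculationMotion(center_mm=(100, 75), radius_mm=30, angular_speed_deg_s=45)
        cfg = SceneConfig(panel=small_panel, fish=(small_fish,), noise_sigma=0.03,
                          margin_px=60, clip_out_of_bounds=True, seed=7)
        a = [f.image for f in generate_sequence(cfg, fps=3, duration_s=1, motion=motion)]
        b = [f.image for f in generate_sequence(cfg, fps=3, duration_s=1, motion=motion)]
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestFixtures:
    def test_roundtrip_single_scene(self, tmp_path, small_panel, small_fish):
        scene = make_scene(small_panel, [small_fish], noise=0.02, seed=3)
        manifest_path = write_fixture(scene, tmp_path)
        manifest, frames, masks = read_fixture(tmp_path)
        expected = np.clip(np.rint(scene.image * 255), 0, 255).astype(np.uint8)
        assert np.array_equal(frames[0], expected)
        assert np.array_equal(masks[0], scene.ground_truth.label_image(scene.image.shape))
        assert manifest["config"]["seed"] == 3
        assert manifest["records"][0]["scale_mm_per_px"] == 1.0

    def test_regeneration_from_manifest_is_bit_identical(self, tmp_path, small_panel, small_fish):
        scene = make_scene(small_panel, [small_fish], noise=0.02, seed=9)
        write_fixture(scene, tmp_path)
        manifest, frames, _ = read_fixture(tmp_path)
        cfg = config_from_dict(manifest["config"])
        again = render_scene(cfg)
        expected = np.clip(np.rint(again.image * 255), 0, 255).astype(np.uint8)
        assert np.array_equal(frames[0], expected)

    def test_empty_fish_list_yields_zero_masks(self, tmp_path, small_panel):
        scene = make_scene(small_panel)
        write_fixture(scene, tmp_path)
        manifest, _, masks = read_fixture(tmp_path)
        assert manifest["records"][0]["mask_areas_px"] == []
        assert masks[0].max() == 0
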