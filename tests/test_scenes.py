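"""Scene generation, stereo rendering, window extraction, disparity model."""

import numpy as np
import pytest

from aecvision import scenes as sc


def brute_force_render_right(scene):
    """Painter's oracle: per-pixel loop over planes far to near."""
    h, w = scene.height, scene.width
    right = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            val = None
            for p in (scene.background, *scene.planes):  # later = nearer wins
                lx = x + p.disparity  # left-image column this right pixel sees
                if p.y0 <= y < p.y1 and p.x0 <= lx < p.x1:
                    val = p.texture[y, p.pad + lx]
            right[y, x] = val
    return right


class TestSceneGeneration:
    def test_degenerate_scene_has_zero_disparity_map(self):
        cfg = sc.SceneConfig(n_planes=0, background_disparity=0)
        scene = sc.generate_scene(cfg, 0)
        assert np.all(scene.disparity_map == 0)

    def test_single_plane_disparity_map_construction(self):
        cfg = sc.SceneConfig(n_planes=1)
        scene = sc.generate_scene(
            cfg, 0, plane_disparities=[8], plane_rects=[(100, 200, 100, 200)]
        )
        d = scene.disparity_map
        assert np.all(d[100:200, 100:200] == 8)
        mask = np.ones_like(d, dtype=bool)
        mask[100:200, 100:200] = False
        assert np.all(d[mask] == 0)

    def test_same_seed_gives_byte_identical_scenes(self):
        cfg = sc.SceneConfig()
        a = sc.generate_scene(cfg, 1)
        b = sc.generate_scene(cfg, 1)
        assert np.array_equal(sc.render_stereo(a).left, sc.render_stereo(b).left)
        assert np.array_equal(a.disparity_map, b.disparity_map)

    def test_plane_disparities_stay_in_configured_range(self, rng):
        cfg = sc.SceneConfig(disparity_range=(-5, 5), n_planes=8)
        for seed in range(5):
            scene = sc.generate_scene(cfg, seed)
            assert all(-5 <= p.disparity <= 5 for p in scene.planes)

    def test_every_pixel_covered_by_exactly_one_visible_plane(self, two_plane_scene):
        # disparity map constant within each visible region
        d = two_plane_scene.disparity_map
        assert set(np.unique(d)) <= {-6, 10, 0}

    def test_too_small_frame_raises_naming_minimum(self):
        geom = sc.FixationGeometry(window_base=55, max_shift=40)
        cfg = sc.SceneConfig(width=200, height=200)
        with pytest.raises(ValueError, match="300"):
            sc.generate_scene(cfg, 0, geometry=geom)


class TestRendering:
    def test_zero_disparity_scene_renders_identical_eyes(self):
        cfg = sc.SceneConfig(n_planes=2, disparity_range=(0, 0))
        scene = sc.generate_scene(cfg, 3)
        frame = sc.render_stereo(scene)
        np.testing.assert_array_equal(frame.left, frame.right)

    def test_full_frame_plane_is_pure_shift(self):
        cfg = sc.SceneConfig(n_planes=1)
        scene = sc.generate_scene(
            cfg, 5, plane_disparities=[4], plane_rects=[(0, 240, 0, 320)]
        )
        frame = sc.render_stereo(scene)
        np.testing.assert_array_equal(frame.right[:, :-4], frame.left[:, 4:])

    def test_two_plane_scene_matches_painters_oracle(self, two_plane_scene):
        frame = sc.render_stereo(two_plane_scene)
        oracle = brute_force_render_right(two_plane_scene)
        np.testing.assert_array_equal(frame.right, oracle)

    def test_random_scenes_match_painters_oracle(self):
        cfg = sc.SceneConfig(width=80, height=60, n_planes=3, disparity_range=(-8, 8))
        for seed in range(3):
            scene = sc.generate_scene(cfg, seed)
            np.testing.assert_array_equal(
                sc.render_stereo(scene).right, brute_force_render_right(scene)
            )


class TestRetinalDisparity:
    def test_matched_shift_gives_zero(self):
        cfg = sc.SceneConfig(n_planes=0, background_disparity=8)
        scene = sc.generate_scene(cfg, 0)
        assert sc.retinal_disparity(scene, sc.FixationState(100, 100, shift=8)) == 0

    def test_sign_convention(self):
        cfg = sc.SceneConfig(n_planes=0, background_disparity=12)
        scene = sc.generate_scene(cfg, 0)
        assert sc.retinal_disparity(scene, sc.FixationState(50, 50, shift=0)) == -12

    def test_matches_per_pixel_lookup_oracle(self, two_plane_scene, rng):
        d = two_plane_scene.disparity_map
        for _ in range(50):
            x = int(rng.integers(0, two_plane_scene.width))
            y = int(rng.integers(0, two_plane_scene.height))
            shift = int(rng.integers(-20, 21))
            fix = sc.FixationState(x, y, shift)
            assert sc.retinal_disparity(two_plane_scene, fix) == shift - d[y, x]


class TestVergenceActions:
    def test_action_set_is_the_11_signed_powers_of_two(self):
        assert sc.VERGENCE_ACTIONS == (-16, -8, -4, -2, -1, 0, 1, 2, 4, 8, 16)
        assert len(sc.VERGENCE_ACTIONS) == 11
        assert tuple(-a for a in reversed(sc.VERGENCE_ACTIONS)) == sc.VERGENCE_ACTIONS

    def test_action_moves_shift_and_counter(self):
        fix = sc.FixationState(0, 0, shift=10)
        out = sc.apply_vergence_action(fix, -8)
        assert out.shift == 2 and out.frame == 1

    def test_zero_action_only_increments_counter(self):
        fix = sc.FixationState(3, 4, shift=7, frame=2)
        out = sc.apply_vergence_action(fix, 0)
        assert (out.x, out.y, out.shift, out.frame) == (3, 4, 7, 3)

    def test_invalid_action_rejected(self):
        with pytest.raises(ValueError):
            sc.apply_vergence_action(sc.FixationState(0, 0), 3)

    def test_shift_clamped_to_support(self):
        fix = sc.FixationState(0, 0, shift=38)
        assert sc.apply_vergence_action(fix, 16).shift == 40

    def test_every_disparity_reachable_within_ten_steps(self):
        """BFS over shift states: every |d0| <= 20 reaches 0 in <= 10 actions."""
        for d0 in range(-20, 21):
            frontier = {d0}
            steps = 0
            while 0 not in frontier and steps <= 10:
                frontier = {
                    int(np.clip(d + a, -40, 40))
                    for d in frontier
                    for a in sc.VERGENCE_ACTIONS
                }
                steps += 1
            assert 0 in frontier and steps <= 10


class TestWindowExtraction:
    def test_three_pairs_all_base_sized(self, desk_geometry, two_plane_scene):
        frame = sc.render_stereo(two_plane_scene)
        ws = desk_geometry.extract_vergence_input(
            frame, sc.FixationState(160, 120, shift=6)
        )
        for left, right in ws.pairs().values():
            assert left.shape == right.shape == (25, 25)

    def test_full_scale_windows_are_55x55(self):
        geom = sc.FixationGeometry(window_base=55)
        cfg = sc.SceneConfig(width=640, height=480)
        frame = sc.render_stereo(sc.generate_scene(cfg, 0))
        ws = geom.extract_vergence_input(frame, sc.FixationState(320, 240, shift=0))
        for left, right in ws.pairs().values():
            assert left.shape == right.shape == (55, 55)

    def test_zero_retinal_disparity_aligns_fine_windows(self, desk_geometry):
        cfg = sc.SceneConfig(n_planes=0, background_disparity=7)
        frame = sc.render_stereo(sc.generate_scene(cfg, 2))
        ws = desk_geometry.extract_vergence_input(
            frame, sc.FixationState(160, 120, shift=7)
        )
        np.testing.assert_array_equal(ws.fine[0], ws.fine[1])

    def test_constant_image_stays_constant_through_bicubic(self, desk_geometry):
        frame = sc.StereoFrame(np.full((240, 320), 0.37), np.full((240, 320), 0.37))
        ws = desk_geometry.extract_vergence_input(frame, sc.FixationState(160, 120))
        np.testing.assert_allclose(ws.coarse[0], 0.37, atol=1e-12)

    def test_out_of_margin_fixation_raises(self, desk_geometry, two_plane_scene):
        frame = sc.render_stereo(two_plane_scene)
        with pytest.raises(ValueError):
            desk_geometry.extract_vergence_input(frame, sc.FixationState(10, 120))

    def test_translation_covariance_of_fine_window(self, desk_geometry, two_plane_scene):
        frame = sc.render_stereo(two_plane_scene)
        a = desk_geometry.extract_vergence_input(frame, sc.FixationState(160, 120))
        b = desk_geometry.extract_vergence_input(frame, sc.FixationState(163, 118))
        # shifting the fixation by (+3, -2) shifts the fine window content
        np.testing.assert_array_equal(a.fine[0][:-2, 3:], b.fine[0][2:, :-3])
        # and each fine window is a pure crop of the left image
        y, x, s = 120, 160, 25
        np.testing.assert_array_equal(
            a.fine[0], frame.left[y - s // 2:y + s - s // 2, x - s // 2:x + s - s // 2]
        )


class TestSaccadeInput:
    def test_zero_shift_returns_full_frames(self, desk_geometry, two_plane_scene):
        frame = sc.render_stereo(two_plane_scene)
        lw, rw, off = desk_geometry.extract_saccade_input(frame, 0)
        assert off == 0
        assert lw.shape == rw.shape == (60, 80)

    def test_tsukuba_sized_window_arithmetic(self):
        geom = sc.FixationGeometry(window_base=55)
        frame = sc.StereoFrame(np.zeros((480, 640)), np.zeros((480, 640)))
        lw, rw, off = geom.extract_saccade_input(frame, 8)
        # pre-downsample windows are 480 x 632; /4 -> 120 x 158
        assert lw.shape == rw.shape == (120, 158)
        assert off == 8

    def test_matched_disparity_aligns_the_pair(self, desk_geometry):
        cfg = sc.SceneConfig(n_planes=0, background_disparity=8)
        frame = sc.render_stereo(sc.generate_scene(cfg, 1))
        lw, rw, _ = desk_geometry.extract_saccade_input(frame, 8)
        np.testing.assert_allclose(lw, rw, atol=1e-9)

    def test_excessive_shift_raises(self, desk_geometry):
        frame = sc.StereoFrame(np.zeros((60, 80)), np.zeros((60, 80)))
        with pytest.raises(ValueError):
            desk_geometry.extract_saccade_input(frame, 80)


class TestLaplacianDisparity:
    def test_pmf_normalized_and_symmetric(self):
        p = sc.laplacian_disparity_pmf(5.0)
        assert len(p) == 81
        assert np.isclose(p.sum(), 1.0)
        np.testing.assert_allclose(p, p[::-1])

    def test_small_spread_concentrates_at_zero(self):
        p = sc.laplacian_disparity_pmf(0.1)
        assert p[40] > 0.9999

    def test_probability_ratio_is_exponential(self):
        p = sc.laplacian_disparity_pmf(5.0)
        assert np.isclose(p[40] / p[45], np.e)

    def test_invalid_spread_rejected(self, rng):
        with pytest.raises(ValueError):
            sc.sample_laplacian_disparity(0.0, rng)

    @pytest.mark.parametrize("spread", [5.0, 50.0])
    def test_sampler_matches_pmf_in_total_variation(self, spread):
        rng = np.random.default_rng(99)
        draws = sc.sample_laplacian_disparity(spread, rng, size=100_000)
        counts = np.bincount(draws + 40, minlength=81) / len(draws)
        tv = 0.5 * np.abs(counts - sc.laplacian_disparity_pmf(spread)).sum()
        assert tv < 0.01


class TestMargin:
    def test_margin_bounds_desk_profile(self, desk_geometry):
        assert desk_geometry.margin_bounds(320, 240) == (90, 230, 50, 190)

    def test_windows_fit_at_margin_corners_with_max_shift(self, desk_geometry):
        frame = sc.StereoFrame(np.zeros((240, 320)), np.zeros((240, 320)))
        x_lo, x_hi, y_lo, y_hi = desk_geometry.margin_bounds(320, 240)
        for x, y in [(x_lo, y_lo), (x_hi, y_hi)]:
            for shift in (-40, 40):
                desk_geometry.extract_vergence_input(
                    frame, sc.FixationState(x, y, shift)
                )
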