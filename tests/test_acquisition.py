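import numpy as np
import pytest

import holoscope as h
from holoscope.acquisition import DISPLAY_SHAPE
from holoscope.errors import DegenerateFrameError, PlanningError


class TestPlanGrid:
    @pytest.mark.parametrize("rows, cols, n", [(5, 5, 25), (8, 8, 64), (1, 1, 1)])
    def test_frame_counts(self, rows, cols, n):
        plan = h.plan_grid(rows, cols, 10, 4.0)
        assert plan.n_frames == n
        assert len(plan.led_indices()) == n

    def test_physical_step(self):
        plan = h.plan_grid(8, 8, 10, 4.0)
        assert plan.physical_step == pytest.approx(40.0)

    def test_off_display_rejected(self):
        with pytest.raises(PlanningError):
            h.plan_grid(5, 5, 10, 4.0, center_led=(5, 320))

    def test_leds_on_display(self):
        plan = h.plan_grid(8, 8, 10, 4.0)
        for r, c in plan.led_indices():
            assert 0 <= r < DISPLAY_SHAPE[0] and 0 <= c < DISPLAY_SHAPE[1]

    def test_center_frame_has_zero_offset(self):
        plan = h.plan_grid(3, 3, 10, 4.0)
        offsets = plan.offsets_um()
        assert offsets[4] == (0.0, 0.0)
        assert offsets[0] == (-40.0, -40.0)


class TestExpectedShift:
    def test_zero_displacement(self, moderate_config):
        assert h.expected_shift((0.0, 0.0), moderate_config) == (0.0, 0.0)

    def test_hand_computed_shift(self):
        cfg = h.OpticalConfig(z_sample_sensor=7000.0, z_source_sample=300.0)
        sy, sx = h.expected_shift((40.0, 0.0), cfg)
        assert sx == pytest.approx(-388.9, abs=0.1)
        assert sy == 0.0

    def test_doubling_z2_halves_shift(self):
        a = h.OpticalConfig(z_sample_sensor=7000.0, z_source_sample=300.0)
        b = h.OpticalConfig(z_sample_sensor=7000.0, z_source_sample=600.0)
        assert h.expected_shift((40.0, 0.0), a)[1] == pytest.approx(
            2 * h.expected_shift((40.0, 0.0), b)[1]
        )


def _jittered_set(config, seed=0, jitter=0.05, noise=None, plan_shape=(2, 2)):
    pitch = h.object_plane_pitch(config)
    phantom = h.make_disk_phantom(6, (2.5, 4.0), pitch, (384, 384), seed=seed,
                                  min_separation=20.0)
    plan = h.plan_grid(*plan_shape, 2, config.led_pitch)
    return h.simulate_grid_acquisition(phantom, config, plan, seed=seed,
                                       noise=noise, intensity_jitter=jitter)


class TestNormalize:
    def test_gain_invariance(self, moderate_config):
        hset = _jittered_set(moderate_config, jitter=0.0)
        doubled = h.HologramSet(
            [h.Hologram(2.0 * f.intensity, f.led_index, f.led_offset_um)
             for f in hset.frames],
            hset.background, hset.config, hset.plan,
        )
        a = h.normalize(hset)
        b = h.normalize(doubled)
        for fa, fb in zip(a.frames, b.frames):
            denom = np.abs(fa.intensity).max()
            assert np.abs(fa.intensity - fb.intensity).max() / denom < 1e-10

    def test_frame_equal_to_background_is_degenerate(self, moderate_config):
        bg = h.Hologram(np.full((64, 64), 7.0))
        frames = [h.Hologram(np.full((64, 64), 7.0))]
        plan = h.plan_grid(1, 1, 1, 4.0)
        hset = h.HologramSet(frames, bg, moderate_config, plan)
        with pytest.raises(DegenerateFrameError):
            h.normalize(hset)

    def test_jitter_removed(self, moderate_config):
        hset = _jittered_set(moderate_config, jitter=0.05)
        normalized = h.normalize(hset)
        medians = [np.median(f.intensity) for f in normalized.frames]
        assert (max(medians) - min(medians)) / np.mean(medians) < 1e-3


class TestStitch:
    def test_single_frame_identity(self, moderate_config):
        hset = _jittered_set(moderate_config, jitter=0.0, plan_shape=(1, 1))
        composite = h.stitch(h.normalize(hset))
        assert composite.offsets_used == [(0.0, 0.0)]
        np.testing.assert_allclose(
            composite.intensity, h.normalize(hset).frames[0].intensity
        )

    def test_identical_frames_zero_displacement(self, moderate_config):
        rng = np.random.default_rng(0)
        img = 1.0 + 0.1 * rng.standard_normal((128, 128))
        img -= img.min() - 0.1
        plan = h.plan_grid(2, 1, 1, 4.0)
        frames = [h.Hologram(img.copy(), led_offset_um=(0.0, 0.0)) for _ in range(2)]
        hset = h.HologramSet(frames, h.Hologram(np.zeros((128, 128))),
                             moderate_config, plan, normalized=True)
        composite = h.stitch(hset)
        assert composite.intensity.shape == (128, 128)
        assert np.abs(composite.intensity - img).max() < 1e-8

    def test_two_frame_offset_recovery(self, moderate_config):
        hset = _jittered_set(moderate_config, jitter=0.0, plan_shape=(2, 1))
        composite = h.stitch(h.normalize(hset))
        (oy0, ox0), (oy1, ox1) = composite.offsets_used
        s0 = h.expected_shift(hset.frames[0].led_offset_um, moderate_config)
        s1 = h.expected_shift(hset.frames[1].led_offset_um, moderate_config)
        expected = (-(s1[0] - s0[0]), -(s1[1] - s0[1]))
        assert abs((oy1 - oy0) - expected[0]) < 0.5
        assert abs((ox1 - ox0) - expected[1]) < 0.5

    def test_composite_extent_and_seams(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_usaf_phantom([h.USAFSpec(5, 1)], pitch, (512, 512))
        # step of 9 LEDs -> hologram shift of exactly 50.0 px at this
        # geometry, so frames are integer-pixel crops of one pattern
        plan = h.plan_grid(3, 3, 9, moderate_config.led_pitch)
        hset = h.simulate_grid_acquisition(phantom, moderate_config, plan,
                                           seed=0, intensity_jitter=0.02)
        composite = h.stitch(h.normalize(hset))
        frame_shape = hset.frames[0].shape
        assert composite.intensity.shape[0] > frame_shape[0]
        assert composite.intensity.shape[1] > frame_shape[1]
        # recovered grid geometry: adjacent-offset spacing close to geometric
        step_px = plan.physical_step * (
            moderate_config.z_sample_sensor / moderate_config.z_source_sample
        ) / moderate_config.camera_pixel_pitch
        offsets = np.array(composite.offsets_used).reshape(3, 3, 2)
        dy = np.diff(offsets[:, :, 0], axis=0)
        dx = np.diff(offsets[:, :, 1], axis=1)
        assert np.abs(dy - step_px).max() < 2.0
        assert np.abs(dx - step_px).max() < 2.0
        # blending consistency: where a frame contributed, the composite
        # must agree with that frame — any disagreement is a seam artifact
        normalized = h.normalize(hset)
        oy_min = min(o[0] for o in composite.offsets_used)
        ox_min = min(o[1] for o in composite.offsets_used)
        from scipy import ndimage as ndi

        for k in (0, 4, 8):
            frame = normalized.frames[k].intensity
            py = composite.offsets_used[k][0] - oy_min
            px = composite.offsets_used[k][1] - ox_min
            iy, ix = int(np.floor(py)), int(np.floor(px))
            resampled = ndi.shift(frame, (py - iy, px - ix), order=1, mode="nearest")
            crop = composite.intensity[iy : iy + frame.shape[0],
                                       ix : ix + frame.shape[1]]
            inner = (slice(8, -8), slice(8, -8))
            rel = np.abs(crop[inner] - resampled[inner]) / np.maximum(
                resampled[inner], 1e-6
            )
            assert np.quantile(rel, 0.99) < 0.02

    def test_scan_order_invariance(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(6, (2.5, 4.0), pitch, (384, 384), seed=5,
                                      min_separation=20.0)
        composites = []
        for ordering in ("row_major", "serpentine"):
            plan = h.plan_grid(2, 2, 2, moderate_config.led_pitch, ordering=ordering)
            hset = h.simulate_grid_acquisition(phantom, moderate_config, plan,
                                               seed=0, intensity_jitter=0.0)
            composites.append(h.stitch(h.normalize(hset)).intensity)
        assert composites[0].shape == composites[1].shape
        assert np.abs(composites[0] - composites[1]).max() < 1e-8
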