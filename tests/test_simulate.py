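import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import holoscope as h
from holoscope.errors import PackingError, ResolutionError
from holoscope.metrology import michelson_contrast, profiles_for_element

from .conftest import single_frame_composite
from .oracles import rayleigh_sommerfeld


class TestUSAFArithmetic:
    @pytest.mark.parametrize(
        "group, element, expected",
        [(7, 1, 128.0), (0, 1, 1.0), (2, 4, 2 ** (2 + 3 / 6))],
    )
    def test_frequency(self, group, element, expected):
        assert h.usaf_frequency(h.USAFSpec(group, element)) == pytest.approx(expected)

    def test_finest_group7_element(self):
        spec = h.USAFSpec(7, 6)
        assert round(h.usaf_frequency(spec)) == 228
        assert round(h.usaf_line_width(spec), 2) == 2.19

    @pytest.mark.parametrize(
        "group, element, width",
        [(1, 1, 250.0), (7, 1, 1000.0 / 256.0)],
    )
    def test_line_width(self, group, element, width):
        assert h.usaf_line_width(h.USAFSpec(group, element)) == pytest.approx(width)

    @pytest.mark.parametrize("element", [0, 7])
    def test_element_domain(self, element):
        with pytest.raises(ValueError):
            h.USAFSpec(7, element)

    @given(g=st.integers(-2, 9), e=st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_frequency_increases_within_group(self, g, e):
        f1 = h.usaf_frequency(h.USAFSpec(g, e))
        f2 = h.usaf_frequency(h.USAFSpec(g, e + 1))
        assert f2 > f1
        assert f2 / f1 == pytest.approx(2 ** (1 / 6))


class TestPhantoms:
    def test_usaf_bar_construction(self):
        # three dark bars of one line width, separated by one line width
        phantom = h.make_usaf_phantom([h.USAFSpec(5, 4)], 1.0, (256, 256))
        el = phantom.truth["elements"][0]
        w = el["line_width_um"]
        y0, y1, x0, x1 = el["roi_um"]
        row = phantom.amplitude_transmission[int((y0 + y1) / 2), int(x0) : int(x1) + 1]
        dark_runs = np.diff(np.flatnonzero(np.diff(np.r_[0, row < 0.5, 0])))[::2]
        assert len(dark_runs) == 3
        assert all(abs(run - w) <= 1.5 for run in dark_runs)

    def test_empty_spec_list_is_transparent(self):
        phantom = h.make_usaf_phantom([], 1.0, (64, 64))
        assert np.all(phantom.amplitude_transmission == 1.0)

    def test_undersampled_target_rejected(self):
        with pytest.raises(ResolutionError):
            h.make_usaf_phantom([h.USAFSpec(7, 6)], 2.0, (128, 128))

    def test_fine_element_period(self):
        phantom = h.make_usaf_phantom([h.USAFSpec(7, 6)], 0.5, (128, 128))
        el = phantom.truth["elements"][0]
        assert 2 * el["line_width_um"] / 0.5 == pytest.approx(8.77, abs=0.01)

    def test_disk_phantom_determinism(self):
        a = h.make_disk_phantom(25, (2.0, 4.0), 1.0, (300, 300), seed=1)
        b = h.make_disk_phantom(25, (2.0, 4.0), 1.0, (300, 300), seed=1)
        np.testing.assert_array_equal(a.amplitude_transmission, b.amplitude_transmission)
        assert a.truth == b.truth

    def test_disk_phantom_separation(self):
        phantom = h.make_disk_phantom(
            25, (2.0, 4.0), 1.0, (500, 500), seed=1, min_separation=12.0
        )
        centers = np.array(phantom.truth["centers_um"])
        assert len(centers) == 25
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 12.0

    def test_empty_disk_phantom(self):
        phantom = h.make_disk_phantom(0, (2.0, 4.0), 1.0, (64, 64), seed=0)
        assert np.all(phantom.amplitude_transmission == 1.0)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            h.make_disk_phantom(50, (5.0, 8.0), 1.0, (64, 64), seed=0,
                                min_separation=30.0, max_tries=500)

    def test_edge_phantom_truth_width(self):
        phantom = h.make_edge_phantom(32.0, 1.29, 0.1, (16, 640))
        assert phantom.truth["width_10_90_um"] == 1.29
        profile = phantom.amplitude_transmission[8]
        x = (np.arange(640) + 0.5) * 0.1
        p10 = np.interp(0.10, profile, x)
        p90 = np.interp(0.90, profile, x)
        assert p90 - p10 == pytest.approx(1.29, abs=0.01)

    def test_edge_phantom_width_scales(self):
        a = h.make_edge_phantom(50.0, 2.0, 0.1, (8, 1024))
        b = h.make_edge_phantom(50.0, 4.0, 0.1, (8, 1024))
        assert b.truth["width_10_90_um"] == 2 * a.truth["width_10_90_um"]

    def test_zero_width_edge_is_step(self):
        phantom = h.make_edge_phantom(10.0, 0.0, 0.5, (4, 64))
        assert set(np.unique(phantom.amplitude_transmission)) <= {0.0, 1.0}


class TestForwardModel:
    def test_transparent_phantom_gives_flat_field(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(0, (2.0, 4.0), pitch, (320, 320), seed=0)
        holo = h.simulate_hologram(phantom, moderate_config)
        cv = holo.intensity.std() / holo.intensity.mean()
        assert cv < 1e-6

    def test_weak_object_preserves_mean_intensity(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(
            3, (2.5, 3.5), pitch, (320, 320), seed=2, amplitude=0.9, phase=0.05
        )
        holo = h.simulate_hologram(phantom, moderate_config)
        assert holo.intensity.mean() == pytest.approx(1.0, rel=0.01)

    def test_pitch_mismatch_rejected(self, moderate_config):
        phantom = h.make_disk_phantom(1, (2.5, 3.5), 1.0, (320, 320), seed=0)
        with pytest.raises(ResolutionError):
            h.simulate_hologram(phantom, moderate_config)

    def test_single_disk_fringes_match_rayleigh_sommerfeld(self):
        # tiny, finely sampled geometry so the direct quadrature oracle is
        # trustworthy; the simulator continues the unit background beyond
        # the grid, so the matching free-space oracle is the propagated
        # plane wave e^{ikz} plus RS applied to the compact scattered part
        z2 = 41.666667  # z_eff = 40 µm
        magnification = (1000.0 + z2) / z2
        cfg = h.OpticalConfig(
            z_sample_sensor=1000.0,
            z_source_sample=z2,
            camera_pixel_pitch=0.2 * magnification,  # object pitch 0.2 µm
            sensor_shape=(64, 64),
            source_diameter=0.01,  # negligible blur
        )
        pitch = h.object_plane_pitch(cfg)
        assert pitch == pytest.approx(0.2, abs=1e-3)
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(yy - 31.5, xx - 31.5) * pitch
        cov = np.clip(0.5 + (1.5 - r) / pitch, 0.0, 1.0)
        phantom = h.Phantom(1 - 0.7 * cov, 0.0 * cov, pitch, {"kind": "disks"})
        holo = h.simulate_hologram(phantom, cfg)
        geom = h.derive_geometry(cfg)
        k = 2.0 * np.pi / cfg.wavelength
        ref = np.exp(1j * k * geom.z_effective) + rayleigh_sommerfeld(
            phantom.transmission() - 1.0, pitch, cfg.wavelength, geom.z_effective
        )
        diff = np.sqrt(np.mean((np.sqrt(holo.intensity) - np.abs(ref)) ** 2))
        assert diff / np.sqrt(np.mean(np.abs(ref) ** 2)) < 0.01

    def test_fringe_contrast_nonincreasing_in_source_diameter(self):
        from dataclasses import replace

        base = h.OpticalConfig(z_sample_sensor=7000.0, z_source_sample=300.0,
                               sensor_shape=(256, 256))
        pitch = h.object_plane_pitch(base)
        phantom = h.make_usaf_phantom([h.USAFSpec(7, 1)], pitch, (256, 256))
        el = phantom.truth["elements"][0]
        contrasts = []
        for ds in (0.5, 1.0, 10.0, 90.0):
            cfg = replace(base, source_diameter=ds)
            holo = h.simulate_hologram(phantom, cfg)
            pset = profiles_for_element(holo.intensity, pitch, el, n_lines=5)
            contrasts.append(
                np.mean([michelson_contrast(p) for p in pset.profiles])
            )
        assert all(a >= b - 1e-12 for a, b in zip(contrasts, contrasts[1:]))

    def test_seed_determinism(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(3, (2.5, 3.5), pitch, (320, 320), seed=2)
        a = h.simulate_hologram(phantom, moderate_config, seed=9, noise=h.NoiseSpec())
        b = h.simulate_hologram(phantom, moderate_config, seed=9, noise=h.NoiseSpec())
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestGridAcquisition:
    def test_frame_counts(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(2, (2.5, 3.5), pitch, (384, 384), seed=4)
        for rows, cols in ((5, 5),):
            plan = h.plan_grid(rows, cols, 2, moderate_config.led_pitch)
            hset = h.simulate_grid_acquisition(phantom, moderate_config, plan, seed=0)
            assert len(hset.frames) == rows * cols
            assert hset.background is not None

    def test_single_led_matches_direct_simulation(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(2, (2.5, 3.5), pitch, (320, 320), seed=4)
        plan = h.plan_grid(1, 1, 1, moderate_config.led_pitch)
        hset = h.simulate_grid_acquisition(
            phantom, moderate_config, plan, seed=0, intensity_jitter=0.0
        )
        direct = h.simulate_hologram(phantom, moderate_config, (0.0, 0.0))
        np.testing.assert_allclose(hset.frames[0].intensity, direct.intensity)

    def test_grid_determinism(self, moderate_config):
        pitch = h.object_plane_pitch(moderate_config)
        phantom = h.make_disk_phantom(2, (2.5, 3.5), pitch, (512, 512), seed=4)
        plan = h.plan_grid(2, 2, 2, moderate_config.led_pitch)
        a = h.simulate_grid_acquisition(phantom, moderate_config, plan, seed=3,
                                        noise=h.NoiseSpec())
        b = h.simulate_grid_acquisition(phantom, moderate_config, plan, seed=3,
                                        noise=h.NoiseSpec())
        for fa, fb in zip(a.frames + [a.background], b.frames + [b.background]):
            np.testing.assert_array_equal(fa.intensity, fb.intensity)
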