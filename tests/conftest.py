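import numpy as np
import pytest

import holoscope as h


@pytest.fixture(scope="session")
def moderate_config():
    """Moderate-magnification geometry (M = 4.33) used by pipeline tests."""
    return h.OpticalConfig(
        z_sample_sensor=2000.0, z_source_sample=600.0, sensor_shape=(256, 256)
    )


@pytest.fixture(scope="session")
def smooth_field():
    """Band-limited Gaussian test field, 128x128 at 1 µm pitch."""
    x = np.arange(128) - 63.5
    yy, xx = np.meshgrid(x, x, indexing="ij")
    g = np.exp(-(yy**2 + xx**2) / (2.0 * 6.0**2))
    return h.ComplexField(g, pixel_pitch=1.0, wavelength=0.45)


def single_frame_composite(phantom, config, z=None):
    """Simulate one centred hologram and wrap it as a composite."""
    holo = h.simulate_hologram(phantom, config, (0.0, 0.0))
    plan = h.plan_grid(1, 1, 1, config.led_pitch)
    return h.CompositeHologram(holo.intensity, [(0.0, 0.0)], config, plan)


@pytest.fixture(scope="session")
def disk_scene(moderate_config):
    """8-disk phantom, its noiseless composite, and a background mask."""
    cfg = moderate_config
    pitch = h.object_plane_pitch(cfg)
    phantom = h.make_disk_phantom(8, (2.5, 4.0), pitch, (384, 384), seed=3)
    composite = single_frame_composite(phantom, cfg)
    margin = (384 - 256) // 2
    yy = (np.arange(256)[:, None] + 0.5) * pitch + margin * pitch
    xx = (np.arange(256)[None, :] + 0.5) * pitch + margin * pitch
    mask = np.ones((256, 256), dtype=bool)
    for (cy, cx), r in zip(phantom.truth["centers_um"], phantom.truth["radii_um"]):
        mask &= np.hypot(yy - cy, xx - cx) > r + 3.0
    return phantom, composite, mask
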