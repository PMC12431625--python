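"""Seeded synthetic phantoms and the forward in-line holography model.

Phantoms are complex transmission functions sampled on the demagnified
object-plane grid (pitch = camera pixel pitch / M).  The forward model
propagates ``illumination x transmission`` to the effective plane-wave
distance, takes the intensity, applies the partial-coherence blur of the
finite LED emitting area, shifts the pattern by the geometric shadow
displacement of the firing LED, and finally adds shot noise, read noise and
an ambient offset.

Partial spatial coherence is modelled as an intensity convolution with the
geometrically imaged source spot (diameter ``source_diameter * z1/z2`` at
the sensor): the incoherent superposition of mutually uncorrelated source
points reduces, in the paraxial limit, to exactly this blur.  Fringe
contrast therefore falls as the emitting area grows, which is why a 1-µm
micro-LED outresolves a 90–150 µm pinhole at the same geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .acquisition import Hologram, HologramSet, LEDGridPlan, expected_shift
from .errors import ContractError, PackingError, ResolutionError
from .optics import ComplexField, OpticalConfig, derive_geometry, object_plane_pitch, propagate

__all__ = [
    "USAFSpec",
    "Phantom",
    "NoiseSpec",
    "usaf_frequency",
    "usaf_line_width",
    "make_usaf_phantom",
    "make_disk_phantom",
    "make_edge_phantom",
    "simulate_hologram",
    "simulate_grid_acquisition",
]


@dataclass(frozen=True)
class USAFSpec:
    """A group/element address on a USAF-1951 three-bar resolution target."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError(f"USAF element must be in 1..6, got {self.element}")


def usaf_frequency(spec: USAFSpec) -> float:
    """Spatial frequency of a USAF-1951 element in line pairs per mm.

    ``f = 2 ** (group + (element - 1) / 6)``, unrounded.
    """
    return 2.0 ** (spec.group + (spec.element - 1) / 6.0)


def usaf_line_width(spec: USAFSpec) -> float:
    """Width of a single bar (equal to the spacing) in µm: 1000 / (2 f)."""
    return 1000.0 / (2.0 * usaf_frequency(spec))


@dataclass
class Phantom:
    """Complex-transmission sample model with ground-truth annotations.

    ``amplitude_transmission`` in [0, 1] (1 = transparent), ``phase_shift``
    in radians, both on a square grid of ``pixel_pitch`` µm.  ``truth``
    carries whatever the generating function knows: bar ROIs and lp/mm for
    resolution targets, centers/radii for disks, the analytic edge width for
    edge targets.
    """

    amplitude_transmission: np.ndarray
    phase_shift: np.ndarray
    pixel_pitch: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude_transmission = np.asarray(self.amplitude_transmission, dtype=np.float64)
        self.phase_shift = np.asarray(self.phase_shift, dtype=np.float64)
        if self.amplitude_transmission.shape != self.phase_shift.shape:
            raise ContractError("amplitude and phase grids must have identical shapes")
        if self.amplitude_transmission.min() < -1e-12 or self.amplitude_transmission.max() > 1 + 1e-12:
            raise ContractError("amplitude transmission must lie in [0, 1]")
        if self.pixel_pitch <= 0:
            raise ContractError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude_transmission.shape

    def transmission(self) -> np.ndarray:
        return self.amplitude_transmission * np.exp(1j * self.phase_shift)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise model: Poisson shot noise at a photon budget per pixel
    at unit (full-scale) intensity, Gaussian read noise, and a constant
    ambient offset, all in counts."""

    photon_budget: float = 5000.0
    read_noise: float = 2.0
    ambient_offset: float = 20.0


def _axis_coverage(n: int, pitch: float, lo: float, hi: float) -> np.ndarray:
    """Fraction of each pixel [i*pitch, (i+1)*pitch) covered by [lo, hi)."""
    edges = np.arange(n + 1) * pitch
    cov = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
    return cov / pitch


def make_usaf_phantom(
    specs: list[USAFSpec],
    pixel_pitch: float,
    field_size: tuple[int, int],
    orientation: str = "vertical",
) -> Phantom:
    """Render three-bar resolution elements on a transparent background.

    Each element is a triplet of opaque bars (amplitude 0) with bar width =
    spacing = the element's line width and bar length 5x the width, drawn
    with area-weighted anti-aliasing.  ``orientation='vertical'`` draws
    vertical bars (intensity modulates along x).  Elements are stacked top
    to bottom, centred horizontally.  Raises when the finest element would
    be sampled below Nyquist (line width < 2 px).
    """
    rows, cols = field_size
    amp = np.ones((rows, cols))
    truth_elements = []
    if specs:
        widths = [usaf_line_width(s) for s in specs]
        if min(widths) < 2.0 * pixel_pitch:
            raise ResolutionError(
                f"finest line width {min(widths):.3g} µm is below the Nyquist "
                f"limit 2*pitch = {2 * pixel_pitch:.3g} µm"
            )
        gap = max(w * 3 for w in widths)
        total_h = sum(5 * w for w in widths) + gap * (len(specs) - 1)
        y = (rows * pixel_pitch - total_h) / 2
        for spec, w in zip(specs, widths):
            length = 5 * w
            cx = cols * pixel_pitch / 2
            if orientation == "vertical":
                # three bars modulating along x, long axis along y
                x0 = cx - 2.5 * w
                ycov = _axis_coverage(rows, pixel_pitch, y, y + length)
                for b in range(3):
                    lo = x0 + 2 * b * w
                    xcov = _axis_coverage(cols, pixel_pitch, lo, lo + w)
                    amp -= np.outer(ycov, xcov)
                roi = (y, y + length, x0, x0 + 5 * w)  # (y0, y1, x0, x1) µm
            elif orientation == "horizontal":
                x0 = cx - length / 2
                xcov = _axis_coverage(cols, pixel_pitch, x0, x0 + length)
                for b in range(3):
                    lo = y + 2 * b * w
                    ycov = _axis_coverage(rows, pixel_pitch, lo, lo + w)
                    amp -= np.outer(ycov, xcov)
                roi = (y, y + 5 * w, x0, x0 + length)
            else:
                raise ValueError(f"unknown orientation {orientation!r}")
            truth_elements.append(
                {
                    "group": spec.group,
                    "element": spec.element,
                    "lp_per_mm": usaf_frequency(spec),
                    "line_width_um": w,
                    "roi_um": roi,
                    "orientation": orientation,
                }
            )
            y += 5 * w + gap
    amp = np.clip(amp, 0.0, 1.0)
    return Phantom(amp, np.zeros_like(amp), pixel_pitch,
                   truth={"kind": "usaf", "elements": truth_elements})


def make_disk_phantom(
    n_disks: int,
    radius_range: tuple[float, float],
    pixel_pitch: float,
    field_size: tuple[int, int],
    seed: int = 0,
    min_separation: float | None = None,
    amplitude: float = 0.3,
    phase: float = 0.5,
    max_tries: int = 20000,
    edge_margin_um: float = 0.0,
) -> Phantom:
    """Scatter non-overlapping partially absorbing disks (yeast-like cells).

    Disks transmit ``amplitude`` (default 0.3) with a small uniform phase
    shift; centres are rejection-sampled so that pairwise distances exceed
    ``min_separation`` (default: 2.5x the max radius).  ``edge_margin_um``
    keeps disk centres away from the field border — useful when the field
    extends beyond the sensor window, so every disk stays imaged.
    Deterministic in ``seed``.  Raises :class:`PackingError` when placement
    is infeasible within the retry budget.
    """
    rows, cols = field_size
    r_lo, r_hi = radius_range
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("radius_range must satisfy 0 < min <= max")
    if min_separation is None:
        min_separation = 2.5 * r_hi
    rng = np.random.default_rng(seed)
    height, width = rows * pixel_pitch, cols * pixel_pitch

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_disks:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n_disks} disks with separation "
                f"{min_separation} µm in {height:.0f}x{width:.0f} µm "
                f"after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        margin = r + 2 * pixel_pitch + edge_margin_um
        cy = rng.uniform(margin, height - margin)
        cx = rng.uniform(margin, width - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_separation**2 for y, x in centers):
            centers.append((cy, cx))
            radii.append(r)

    yy = (np.arange(rows)[:, None] + 0.5) * pixel_pitch
    xx = (np.arange(cols)[None, :] + 0.5) * pixel_pitch
    coverage = np.zeros((rows, cols))
    for (cy, cx), r in zip(centers, radii):
        dist = np.hypot(yy - cy, xx - cx)
        # signed-distance anti-aliasing: exact to first order at the rim
        coverage += np.clip(0.5 + (r - dist) / pixel_pitch, 0.0, 1.0)
    coverage = np.clip(coverage, 0.0, 1.0)
    amp = 1.0 - (1.0 - amplitude) * coverage
    pha = phase * coverage
    truth = {
        "kind": "disks",
        "centers_um": [list(c) for c in centers],
        "radii_um": radii,
        "min_separation_um": min_separation,
    }
    return Phantom(amp, pha, pixel_pitch, truth)


def make_edge_phantom(
    edge_position: float,
    transition_width: float,
    pixel_pitch: float,
    field_size: tuple[int, int],
) -> Phantom:
    """Smooth error-function edge target for PSF-width estimation.

    The amplitude rises from 0 to 1 along x with an erf profile whose
    analytic 10–90% width equals ``transition_width`` µm (an ideal step when
    zero); the truth records that width and the edge position.
    """
    if transition_width < 0:
        raise ValueError("transition_width must be nonnegative")
    rows, cols = field_size
    x = (np.arange(cols) + 0.5) * pixel_pitch
    if transition_width == 0:
        profile = (x >= edge_position).astype(np.float64)
    else:
        # 10-90 width of 0.5*(1+erf(u/(sigma*sqrt2))) is 2*1.28155*sigma
        sigma = transition_width / (2.0 * 1.2815515655446004)
        from scipy.special import erf

        profile = 0.5 * (1.0 + erf((x - edge_position) / (sigma * math.sqrt(2.0))))
    amp = np.tile(profile, (rows, 1))
    truth = {"kind": "edge", "edge_position_um": edge_position,
             "width_10_90_um": transition_width}
    return Phantom(amp, np.zeros_like(amp), pixel_pitch, truth)


def _disk_kernel(diameter_px: float) -> np.ndarray | None:
    """Normalized circular top-hat kernel with anti-aliased rim."""
    if diameter_px <= 1.0:
        return None
    r = diameter_px / 2.0
    n = int(math.ceil(diameter_px)) + 2
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c)
    k = np.clip(0.5 + (r - dist), 0.0, 1.0)
    return k / k.sum()


def coherence_kernel_diameter_px(config: OpticalConfig) -> float:
    """Diameter (sensor pixels) of the geometrically imaged source spot."""
    return (config.source_diameter * config.z_sample_sensor
            / config.z_source_sample / config.camera_pixel_pitch)


def _base_intensity(phantom: Phantom, config: OpticalConfig) -> np.ndarray:
    """Noise-free full-field hologram intensity on the phantom grid."""
    pitch = object_plane_pitch(config)
    if abs(phantom.pixel_pitch - pitch) > 1e-6 * pitch:
        raise ResolutionError(
            f"phantom pitch {phantom.pixel_pitch:.6g} µm must equal the "
            f"demagnified sensor pitch {pitch:.6g} µm for this geometry"
        )
    geom = derive_geometry(config)
    field_in = ComplexField(phantom.transmission(), pitch, config.wavelength)
    # the sample is transparent beyond the rendered grid, so the forward
    # model continues the unit background rather than a dark aperture
    sensor_field = propagate(field_in, geom.z_effective, pad_value=1.0)
    intensity = sensor_field.intensity
    kernel = _disk_kernel(coherence_kernel_diameter_px(config))
    if kernel is not None:
        intensity = signal.fftconvolve(intensity, kernel, mode="same")
    return np.clip(intensity, 0.0, None)


def _crop_shifted(full: np.ndarray, sensor_shape: tuple[int, int],
                  shift_px: tuple[float, float]) -> np.ndarray:
    """Sensor window of the full-field pattern translated by ``shift_px``."""
    rows, cols = sensor_shape
    if full.shape[0] < rows or full.shape[1] < cols:
        raise ResolutionError(
            f"phantom grid {full.shape} smaller than sensor {sensor_shape}"
        )
    sy, sx = shift_px
    oy = (full.shape[0] - rows) / 2.0 - sy
    ox = (full.shape[1] - cols) / 2.0 - sx
    iy, ix = int(math.floor(oy)), int(math.floor(ox))
    fy, fx = oy - iy, ox - ix
    pad = 2
    y0, x0 = iy - pad, ix - pad
    win = np.empty((rows + 2 * pad + 1, cols + 2 * pad + 1))
    ys = np.clip(np.arange(y0, y0 + win.shape[0]), 0, full.shape[0] - 1)
    xs = np.clip(np.arange(x0, x0 + win.shape[1]), 0, full.shape[1] - 1)
    win[:] = full[np.ix_(ys, xs)]
    if fy or fx:
        win = ndimage.shift(win, (-fy, -fx), order=1, mode="nearest")
    return win[pad : pad + rows, pad : pad + cols]


def _apply_noise(intensity: np.ndarray, noise: NoiseSpec | None,
                 rng: np.random.Generator) -> np.ndarray:
    if noise is None:
        return intensity
    photons = rng.poisson(np.clip(intensity, 0, None) * noise.photon_budget)
    counts = photons + rng.normal(0.0, noise.read_noise, intensity.shape)
    return np.clip(counts + noise.ambient_offset, 0.0, None)


def simulate_hologram(
    phantom: Phantom,
    config: OpticalConfig,
    led_offset: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    noise: NoiseSpec | None = None,
    intensity_scale: float = 1.0,
    _base: np.ndarray | None = None,
) -> Hologram:
    """Simulate the sensor frame recorded when one LED illuminates the sample.

    ``led_offset`` is the physical (dx, dy) source displacement in µm; the
    hologram pattern translates by the geometric shadow shift on the fixed
    sensor window.  With ``noise=None`` the frame is the noiseless
    illumination-normalized intensity (flat field = 1).
    """
    base = _base_intensity(phantom, config) if _base is None else _base
    shift_px = expected_shift(led_offset, config)
    frame = _crop_shifted(base, config.sensor_shape, shift_px) * intensity_scale
    rng = np.random.default_rng(seed)
    frame = _apply_noise(frame, noise, rng)
    return Hologram(frame, led_offset_um=led_offset,
                    metadata={"seed": seed, "noiseless": noise is None})


def simulate_grid_acquisition(
    phantom: Phantom,
    config: OpticalConfig,
    plan: LEDGridPlan,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    intensity_jitter: float = 0.05,
) -> HologramSet:
    """Sequentially fire the planned LED grid and record one frame per LED.

    Per-LED intensity jitter (uniform within ±``intensity_jitter``) emulates
    drive-current variation across the display; the normalization stage is
    expected to remove it.  A final illumination-off background frame
    carries only ambient offset and read noise.  Deterministic in ``seed``.
    """
    base = _base_intensity(phantom, config)
    seeds = np.random.SeedSequence(seed).spawn(plan.n_frames + 2)
    jitter_rng = np.random.default_rng(seeds[-2])
    frames = []
    for k, (led, offset) in enumerate(zip(plan.led_indices(), plan.offsets_um())):
        scale = 1.0
        if intensity_jitter > 0:
            scale = 1.0 + jitter_rng.uniform(-intensity_jitter, intensity_jitter)
        frame = simulate_hologram(
            phantom, config, offset,
            seed=int(seeds[k].generate_state(1)[0] % (2**31)),
            noise=noise, intensity_scale=scale, _base=base,
        )
        frame.led_index = led
        frames.append(frame)
    bg_rng = np.random.default_rng(seeds[-1])
    bg = _apply_noise(np.zeros(config.sensor_shape), noise, bg_rng)
    background = Hologram(bg, metadata={"background": True})
    return HologramSet(frames, background, config, plan)
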