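"""Geometry and free-space propagation for point-source in-line holography.

The instrument places a micro-LED point source a short distance ``z2``
(z_source_sample) before the sample and the bare CMOS sensor a distance
``z1`` (z_sample_sensor) behind it.  Under the paraxial equivalence for
spherical-wave illumination, the recorded hologram equals a plane-wave
hologram of the object magnified by ``M = (z1 + z2) / z2`` recorded at the
effective distance ``z_eff = z1 * z2 / (z1 + z2)``.  All propagation in this
package therefore runs on demagnified object-plane grids with the
angular-spectrum method; coordinates are rescaled by ``M`` only at the
sensor interface.

Units: micrometres for all lengths, cycles/µm for spatial frequencies.
Arrays are row-major with the origin at the top-left; y increases downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ContractError, InvalidConfigurationError

__all__ = [
    "OpticalConfig",
    "GeometryDerived",
    "ComplexField",
    "derive_geometry",
    "object_plane_pitch",
    "propagate",
    "band_limit_mask",
]

#: Default emission wavelength in µm (blue InGaN micro-LED).
DEFAULT_WAVELENGTH_UM = 0.45


@dataclass(frozen=True)
class OpticalConfig:
    """Physical description of the source / sample / sensor stack.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in µm.
    camera_pixel_pitch : float
        Sensor pixel pitch in µm.
    led_pitch : float
        Centre-to-centre spacing of the LEDs on the display, µm.
    source_diameter : float
        Effective emitting diameter of a single LED, µm.  Controls spatial
        coherence: fringe contrast improves as it shrinks.
    z_sample_sensor : float
        Sample-to-sensor distance z1, µm.
    z_source_sample : float
        Source-to-sample distance z2, µm.  Must be smaller than z1
        (source-near-sample regime).
    sensor_shape : tuple of int
        Sensor size as (rows, cols) pixels.
    """

    wavelength: float = DEFAULT_WAVELENGTH_UM
    camera_pixel_pitch: float = 2.4
    led_pitch: float = 4.0
    source_diameter: float = 1.0
    z_sample_sensor: float = 7000.0
    z_source_sample: float = 300.0
    sensor_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        for name in (
            "wavelength",
            "camera_pixel_pitch",
            "led_pitch",
            "source_diameter",
            "z_sample_sensor",
            "z_source_sample",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidConfigurationError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if self.z_source_sample >= self.z_sample_sensor:
            raise InvalidConfigurationError(
                "source-near-sample regime requires z_source_sample < "
                f"z_sample_sensor (got z2={self.z_source_sample} µm, "
                f"z1={self.z_sample_sensor} µm)"
            )
        rows, cols = self.sensor_shape
        if rows < 16 or cols < 16:
            raise InvalidConfigurationError(
                f"sensor_shape dimensions must be >= 16, got {self.sensor_shape}"
            )

    def with_z_sample_sensor(self, z1: float) -> "OpticalConfig":
        """Copy of this config at a different sample-to-sensor distance."""
        return replace(self, z_sample_sensor=z1)


@dataclass(frozen=True)
class GeometryDerived:
    """Magnification and effective plane-wave distance for a configuration."""

    magnification: float
    z_effective: float


def derive_geometry(config: OpticalConfig, z_sample_sensor: float | None = None) -> GeometryDerived:
    """Derive magnification M and effective propagation distance.

    ``M = (z1 + z2) / z2`` and ``z_eff = z1 * z2 / (z1 + z2)``, where
    ``z1`` is the sample-to-sensor and ``z2`` the source-to-sample distance.
    An optional ``z_sample_sensor`` overrides the configured z1, which is how
    reconstruction at a user-chosen object distance is expressed.
    """
    z1 = config.z_sample_sensor if z_sample_sensor is None else z_sample_sensor
    z2 = config.z_source_sample
    if not np.isfinite(z1) or z1 <= 0:
        raise InvalidConfigurationError(f"z_sample_sensor must be positive, got {z1!r}")
    magnification = (z1 + z2) / z2
    z_effective = z1 * z2 / (z1 + z2)
    return GeometryDerived(magnification=magnification, z_effective=z_effective)


def object_plane_pitch(config: OpticalConfig, z_sample_sensor: float | None = None) -> float:
    """Sensor pixel pitch demagnified to the object plane (µm)."""
    geom = derive_geometry(config, z_sample_sensor)
    return config.camera_pixel_pitch / geom.magnification


@dataclass
class ComplexField:
    """A sampled 2-D complex optical amplitude with physical metadata."""

    values: np.ndarray
    pixel_pitch: float
    wavelength: float = DEFAULT_WAVELENGTH_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ContractError("field values must be a non-empty 2-D grid")
        if self.pixel_pitch <= 0:
            raise ContractError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        if self.wavelength <= 0:
            raise ContractError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def energy(self) -> float:
        """Total power sum(|U|^2) on the grid."""
        return float(np.sum(np.abs(self.values) ** 2))

    def copy(self) -> "ComplexField":
        return ComplexField(self.values.copy(), self.pixel_pitch, self.wavelength)


def band_limit_mask(
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    distance: float,
) -> np.ndarray:
    """Binary frequency mask for alias-free angular-spectrum propagation.

    Keeps a frequency component when (a) it is a propagating wave
    (|f| < 1/λ) and (b) the transfer-function phase is adequately sampled on
    this grid over the given distance (band-limited angular spectrum
    criterion: along each axis |f_x| <= 1 / (λ sqrt((2 Δf_x z)^2 + 1)) with
    Δf_x the frequency-bin width).  ``distance = 0`` keeps everything.
    """
    if pixel_pitch <= 0 or wavelength <= 0:
        raise ContractError("pixel_pitch and wavelength must be positive")
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pixel_pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=pixel_pitch)[None, :]
    f2 = fy**2 + fx**2
    mask = f2 < (1.0 / wavelength) ** 2
    z = abs(float(distance))
    if z > 0:
        dfy = 1.0 / (rows * pixel_pitch)
        dfx = 1.0 / (cols * pixel_pitch)
        fy_limit = 1.0 / (wavelength * np.hypot(2.0 * dfy * z, 1.0))
        fx_limit = 1.0 / (wavelength * np.hypot(2.0 * dfx * z, 1.0))
        mask &= np.abs(fy) <= fy_limit
        mask &= np.abs(fx) <= fx_limit
    return mask.astype(np.float64)


def _transfer_function(
    shape: tuple[int, int],
    pixel_pitch: float,
    wavelength: float,
    distance: float,
    kernel: str,
) -> np.ndarray:
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pixel_pitch)[:, None]
    fx = np.fft.fftfreq(cols, d=pixel_pitch)[None, :]
    f2 = fy**2 + fx**2
    if kernel == "angular_spectrum":
        # exp(i 2π z sqrt(1/λ² − f²)); evanescent part decays for z > 0 and
        # is zeroed for z < 0 (its amplification would be unphysical noise).
        arg = (1.0 / wavelength) ** 2 - f2
        kz = np.sqrt(np.abs(arg)) * (arg > 0)
        h = np.exp(2j * np.pi * distance * kz)
        h[arg <= 0] = 0.0
        return h
    if kernel == "fresnel":
        return np.exp(2j * np.pi * distance / wavelength) * np.exp(
            -1j * np.pi * wavelength * distance * f2
        )
    raise ValueError(f"unknown propagation kernel {kernel!r}")


def propagate(
    field: ComplexField,
    distance: float,
    *,
    kernel: str = "angular_spectrum",
    pad_factor: int = 2,
    band_limit: bool = True,
    pad_value: complex = 0.0,
) -> ComplexField:
    """Propagate a field over a signed free-space distance (µm).

    Positive ``distance`` moves away from the source; negative distances
    backpropagate.  The field is padded by ``pad_factor`` per axis to
    suppress circular wrap-around, multiplied by the (optionally
    band-limited) transfer function in the Fourier domain, and cropped back.
    ``pad_value`` sets the padding amplitude: 0 models a dark surround
    (a true aperture), while the unit background of a normalized in-line
    hologram avoids spurious aperture-edge diffraction ringing.
    """
    if not np.isfinite(distance):
        raise ContractError(f"propagation distance must be finite, got {distance!r}")
    if distance == 0:
        return field.copy()

    rows, cols = field.shape
    nyquist_z = field.pixel_pitch**2 * max(rows, cols) / field.wavelength
    if abs(distance) > 4 * nyquist_z and pad_factor <= 1 and not band_limit:
        warnings.warn(
            "angular-spectrum kernel may be under-sampled at this distance; "
            "consider padding or the band-limited mask",
            RuntimeWarning,
            stacklevel=2,
        )

    if pad_factor > 1:
        prow = rows * (pad_factor - 1) // 2
        pcol = cols * (pad_factor - 1) // 2
        work = np.pad(field.values, ((prow, prow), (pcol, pcol)),
                      constant_values=pad_value)
    else:
        prow = pcol = 0
        work = field.values

    spectrum = np.fft.fft2(work)
    h = _transfer_function(work.shape, field.pixel_pitch, field.wavelength, distance, kernel)
    if band_limit:
        h = h * band_limit_mask(work.shape, field.pixel_pitch, field.wavelength, distance)
    out = np.fft.ifft2(spectrum * h)
    if pad_factor > 1:
        out = out[prow : prow + rows, pcol : pcol + cols]
    return ComplexField(out, field.pixel_pitch, field.wavelength)
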