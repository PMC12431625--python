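"""Independent numerical oracles used only by the test suite.

These deliberately avoid the package's FFT propagation path: direct
Rayleigh–Sommerfeld quadrature and closed-form Gaussian-beam spreading.
"""

from __future__ import annotations

import numpy as np


def rayleigh_sommerfeld(values: np.ndarray, pitch: float, wavelength: float,
                        z: float) -> np.ndarray:
    """Direct summation of the first Rayleigh–Sommerfeld diffraction integral.

    O(N^4); suitable only for tiny grids.  The kernel is
    h = z (1 - i k r) exp(i k r) / (2 pi r^3), which reduces to the familiar
    z exp(ikr) / (i lambda r^2) in the far field.  Negative ``z``
    backpropagates via the conjugate kernel.
    """
    values = np.asarray(values, dtype=np.complex128)
    n0, n1 = values.shape
    k = 2.0 * np.pi / wavelength
    y = (np.arange(n0) - n0 / 2) * pitch
    x = (np.arange(n1) - n1 / 2) * pitch
    zz = abs(z)
    src = values if z >= 0 else np.conj(values)
    dx2 = ((x[:, None] - x[None, :]) ** 2)[:, None, :]  # (n1, 1, n1)
    out = np.empty_like(values)
    for i in range(n0):
        dy2 = ((y[i] - y) ** 2)[None, :, None]  # (1, n0, 1)
        r = np.sqrt(dy2 + dx2 + zz * zz)  # r[j, i_src, j_src]
        hk = zz * (1.0 - 1j * k * r) * np.exp(1j * k * r) / (2.0 * np.pi * r**3)
        out[i] = np.sum(src[None, :, :] * hk, axis=(1, 2)) * pitch * pitch
    return out if z >= 0 else np.conj(out)


def gaussian_beam_width(w0: float, wavelength: float, z: float) -> float:
    """Closed-form 1/e^2 amplitude half-width of a Gaussian beam at z."""
    zr = np.pi * w0**2 / wavelength
    return w0 * np.sqrt(1.0 + (z / zr) ** 2)


def second_moment_width(intensity: np.ndarray, pitch: float) -> float:
    """Gaussian-equivalent 1/e^2 half-width from intensity second moments.

    For I ~ exp(-2 r^2 / w^2) the per-axis variance is w^2/4, so
    w = 2 * sqrt(mean of the two axis variances).
    """
    total = intensity.sum()
    n0, n1 = intensity.shape
    y = (np.arange(n0) - n0 / 2 + 0.5) * pitch
    x = (np.arange(n1) - n1 / 2 + 0.5) * pitch
    cy = (intensity.sum(axis=1) * y).sum() / total
    cx = (intensity.sum(axis=0) * x).sum() / total
    vy = (intensity.sum(axis=1) * (y - cy) ** 2).sum() / total
    vx = (intensity.sum(axis=0) * (x - cx) ** 2).sum() / total
    return float(2.0 * np.sqrt((vy + vx) / 2.0))
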