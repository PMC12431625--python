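"""Circular-object detection and concentration estimation.

Reconstructed yeast-like cells appear as dark disks on the amplitude
image.  Detection runs a gradient (Canny) edge map through a circular
Hough transform over the requested radius range, takes accumulator peaks
above a sensitivity threshold with non-maximum suppression at the detected
radius, and reports physical centres and radii.  The cell concentration is
the count divided by the imaged chamber volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.morphology import dilation, disk as disk_footprint
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import ResolutionError

__all__ = ["DetectionResult", "hough_circles", "concentration"]

#: Concentration range (cells/mL) over which Hough counting is validated.
VALIDATED_RANGE = (0.5e6, 50e6)

#: Default accumulator threshold (fraction of the strongest peak).
DEFAULT_SENSITIVITY = 0.45


@dataclass
class DetectionResult:
    """Detected circle centres/radii in µm, plus optional concentration."""

    centers_um: list[tuple[float, float]]  # (y, x)
    radii_um: list[float]
    fov_area_mm2: float | None = None
    chamber_depth_um: float | None = None
    concentration_per_ml: float | None = None

    @property
    def count(self) -> int:
        return len(self.centers_um)

    def __post_init__(self) -> None:
        if len(self.centers_um) != len(self.radii_um):
            raise ValueError("centers and radii must have the same length")
        if self.concentration_per_ml is not None and self.concentration_per_ml < 0:
            raise ValueError("concentration must be nonnegative")


def hough_circles(
    amplitude_image: np.ndarray,
    pixel_pitch: float,
    radius_range_um: tuple[float, float],
    sensitivity: float = DEFAULT_SENSITIVITY,
    canny_sigma: float = 2.0,
    dark_threshold: float = 0.65,
    border_px: int = 0,
) -> DetectionResult:
    """Detect circular absorbers on a reconstructed amplitude image.

    Cells appear as dark cores on a unit background that still carries
    residual twin-image ripple, so the gradient (Canny) edge map is gated
    to the neighbourhood of genuinely dark regions before Hough voting:

    1. pixels below ``dark_threshold`` x the image median form candidate
       cores; specks smaller than a fraction of the minimum-radius disk are
       discarded;
    2. Canny edges within 1.5 max-radii of a core vote in a circular Hough
       accumulator over ``radius_range_um``;
    3. accumulator peaks above ``sensitivity`` x the strongest peak are
       kept, with non-maximum suppression at one detected radius and an
       optional ``border_px`` exclusion zone (the reconstruction border
       carries window-diffraction ringing).

    Returns physical centres (y, x) and radii in µm.
    """
    image = np.asarray(amplitude_image, dtype=np.float64)
    r_lo, r_hi = radius_range_um
    if not 0 < r_lo < r_hi:
        raise ValueError("radius_range must satisfy 0 < min < max")
    r_lo_px = r_lo / pixel_pitch
    r_hi_px = r_hi / pixel_pitch
    if r_lo_px < 2.0:
        raise ResolutionError(
            f"minimum radius {r_lo} µm is below 2 px at {pixel_pitch} µm/px"
        )

    med = float(np.median(image))
    if med <= 0:
        return DetectionResult([], [])
    cores = image < dark_threshold * med
    min_area = max(4, int(0.3 * math.pi * r_lo_px**2))
    labels, n_labels = ndimage.label(cores)
    if n_labels:
        sizes = np.bincount(labels.ravel())
        cores = sizes[labels] >= min_area
        cores &= labels > 0
    if not cores.any():
        return DetectionResult([], [])
    gate = dilation(cores, disk_footprint(int(math.ceil(1.5 * r_hi_px))))

    span = image.max() - image.min()
    norm = (image - image.min()) / span if span > 0 else np.zeros_like(image)
    edges = canny(norm, sigma=canny_sigma) & gate
    radii_px = np.arange(int(np.floor(r_lo_px)), int(np.ceil(r_hi_px)) + 1)
    accums = hough_circle(edges, radii_px)
    peak_max = accums.max()
    if peak_max <= 0:
        return DetectionResult([], [])
    # generous first pass; final pruning enforces sensitivity and radius NMS
    accs, cxs, cys, rads = hough_circle_peaks(
        accums,
        radii_px,
        min_xdistance=int(np.ceil(r_lo_px)),
        min_ydistance=int(np.ceil(r_lo_px)),
        threshold=sensitivity * peak_max,
        num_peaks=np.inf,
        total_num_peaks=np.inf,
    )
    order = np.argsort(accs)[::-1]
    rows, cols = image.shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    kept_px: list[tuple[float, float, float]] = []
    for k in order:
        cy, cx, r = float(cys[k]), float(cxs[k]), float(rads[k])
        if not (border_px <= cy < rows - border_px
                and border_px <= cx < cols - border_px):
            continue
        if any(np.hypot(cy - ky, cx - kx) < max(r, kr) for ky, kx, kr in kept_px):
            continue
        kept_px.append((cy, cx, r))
        centers.append(((cy + 0.5) * pixel_pitch, (cx + 0.5) * pixel_pitch))
        radii.append(r * pixel_pitch)
    return DetectionResult(centers, radii)


def concentration(
    result: DetectionResult,
    fov_area_mm2: float,
    chamber_depth_um: float,
) -> float:
    """Cell concentration in cells/mL from a count and the imaged volume.

    volume [mL] = fov_area [mm²] x chamber_depth [µm] x 1e-6.  Warns when
    the count is zero or the estimate falls outside the validated
    0.5–50 x 10⁶ cells/mL range.
    """
    if fov_area_mm2 <= 0 or chamber_depth_um <= 0:
        raise ValueError("field-of-view area and chamber depth must be positive")
    volume_ml = fov_area_mm2 * chamber_depth_um * 1e-6
    value = result.count / volume_ml
    if result.count == 0:
        warnings.warn("zero cells detected; concentration is 0", stacklevel=2)
    elif not VALIDATED_RANGE[0] <= value <= VALIDATED_RANGE[1]:
        warnings.warn(
            f"concentration {value:.3g} cells/mL lies outside the validated "
            f"range {VALIDATED_RANGE[0]:.1e}–{VALIDATED_RANGE[1]:.1e}",
            stacklevel=2,
        )
    result.fov_area_mm2 = fov_area_mm2
    result.chamber_depth_um = chamber_depth_um
    result.concentration_per_ml = value
    return value
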