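"""Resolution metrology: line profiles, Michelson contrast, MTF, PSF width.

The workflow mirrors standard three-bar target analysis: draw a fan of
parallel lines perpendicular to the bar pattern, extract bilinear
intensity profiles, compute the Michelson contrast

    C_M = (L_max - L_min) / (L_max + L_min)

of each profile, and plot the mean contrast per element against the
element's spatial frequency to obtain the modulation transfer function.
Edge responses yield a 10–90% PSF-width resolution proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ContractError, GeometryError, NoEdgeError, UndefinedContrastError
from .simulate import USAFSpec, usaf_frequency

__all__ = [
    "ProfileSet",
    "MTFCurve",
    "PSFEstimate",
    "extract_profiles",
    "mean_profile",
    "michelson_contrast",
    "build_mtf",
    "psf_width_10_90",
    "profiles_for_element",
]


@dataclass
class ProfileSet:
    """Parallel intensity profiles drawn across a pattern."""

    profiles: np.ndarray  # (n_lines, n_samples)
    sample_step: float  # µm per sample along each line
    roi: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=np.float64))
        if self.profiles.shape[0] < 1 or self.sample_step <= 0:
            raise ContractError("need >= 1 profile and a positive sample step")

    @property
    def n_lines(self) -> int:
        return self.profiles.shape[0]


class SmoothedProfile(np.ndarray):
    """Mean profile that was Gaussian-smoothed for display.

    Quantitative operations refuse it: smoothing biases extrema and edge
    slopes, so all measurements must run on raw data.
    """

    display_only = True


@dataclass
class MTFCurve:
    """Mean Michelson contrast per spatial frequency, with spread."""

    points: list[tuple[float, float, float]]  # (lp/mm, mean contrast, sd)
    position_label: str = ""

    def __post_init__(self) -> None:
        freqs = [p[0] for p in self.points]
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ContractError("MTF frequencies must be strictly increasing")
        for _, c, _ in self.points:
            if not 0.0 <= c <= 1.0:
                raise ContractError(f"contrast {c} outside [0, 1]")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def contrasts(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class PSFEstimate:
    """10–90% edge-response width, a point-spread-function proxy."""

    pos_10: float
    pos_90: float
    width: float
    threshold_levels: tuple[float, float]
    ambiguous: bool = False


def _reject_display_only(profile) -> np.ndarray:
    if getattr(profile, "display_only", False):
        raise ContractError(
            "profile is flagged display-only (smoothed); quantitative "
            "operations require raw data"
        )
    return np.asarray(profile, dtype=np.float64)


def extract_profiles(
    image: np.ndarray,
    line_start: tuple[float, float],
    line_end: tuple[float, float],
    n_lines: int = 20,
    spacing_px: float = 1.0,
    pixel_pitch: float = 1.0,
) -> ProfileSet:
    """Sample ``n_lines`` parallel intensity profiles across an image.

    ``line_start``/``line_end`` are (y, x) pixel coordinates of the central
    line; the remaining lines are offset perpendicular to it at
    ``spacing_px`` intervals, symmetrically.  Values are bilinearly
    interpolated at unit-pixel steps along the line, so the physical sample
    step is ``pixel_pitch`` µm.  Raises when any sample leaves the image.
    """
    image = np.asarray(image, dtype=np.float64)
    y0, x0 = line_start
    y1, x1 = line_end
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise GeometryError("line start and end coincide")
    n_samples = int(np.floor(length)) + 1
    t = np.linspace(0.0, length, n_samples)
    uy, ux = (y1 - y0) / length, (x1 - x0) / length
    # perpendicular unit vector
    py, px = -ux, uy

    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * spacing_px
    profiles = np.empty((n_lines, n_samples))
    for i, off in enumerate(offsets):
        ys = y0 + uy * t + py * off
        xs = x0 + ux * t + px * off
        if (ys.min() < 0 or xs.min() < 0 or ys.max() > image.shape[0] - 1
                or xs.max() > image.shape[1] - 1):
            raise GeometryError(
                f"profile line {i} (offset {off:+.1f} px) leaves the image bounds"
            )
        profiles[i] = ndimage.map_coordinates(image, [ys, xs], order=1)
    return ProfileSet(profiles, sample_step=pixel_pitch)


def mean_profile(profile_set: ProfileSet, smooth_sigma: float = 0.0) -> np.ndarray:
    """Pointwise mean of the profiles; optionally smoothed for display only.

    A positive ``smooth_sigma`` (in samples) returns a
    :class:`SmoothedProfile` that quantitative operations reject.
    """
    mean = profile_set.profiles.mean(axis=0)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter1d(mean, smooth_sigma)
        return smoothed.view(SmoothedProfile)
    return mean


def michelson_contrast(profile, mode: str = "extrema") -> float:
    """Michelson contrast (L_max - L_min) / (L_max + L_min) of a profile.

    ``mode='extrema'`` (default) uses the global max/min of the profile;
    ``mode='peaks'`` averages local peaks and valleys first, which is more
    robust on noisy multi-period patterns.
    """
    values = _reject_display_only(profile)
    if np.any(values < 0):
        raise UndefinedContrastError("profile must be nonnegative")
    if not np.any(values > 0):
        raise UndefinedContrastError("contrast undefined for an all-zero profile")
    if mode == "extrema":
        lmax, lmin = float(values.max()), float(values.min())
    elif mode == "peaks":
        hi, _ = signal.find_peaks(values)
        lo, _ = signal.find_peaks(-values)
        if len(hi) == 0 or len(lo) == 0:
            lmax, lmin = float(values.max()), float(values.min())
        else:
            lmax, lmin = float(values[hi].mean()), float(values[lo].mean())
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    return (lmax - lmin) / (lmax + lmin)


def build_mtf(
    element_profiles: dict[USAFSpec, ProfileSet],
    position_label: str = "",
    mode: str = "extrema",
) -> MTFCurve:
    """Assemble an MTF from per-element profile sets.

    For each element the Michelson contrast of every individual profile is
    computed, then averaged (mean and sd); the element's spatial frequency
    comes from the standard target formula.  Points are sorted by frequency.
    """
    if len(element_profiles) < 2:
        raise ContractError("an MTF needs at least two elements")
    points = []
    for spec, pset in element_profiles.items():
        if pset.n_lines < 1:
            raise ContractError(f"element {spec} has an empty profile set")
        contrasts = [michelson_contrast(p, mode=mode) for p in pset.profiles]
        points.append(
            (usaf_frequency(spec), float(np.mean(contrasts)), float(np.std(contrasts)))
        )
    points.sort(key=lambda p: p[0])
    return MTFCurve(points, position_label)


def profiles_for_element(
    image: np.ndarray,
    pixel_pitch: float,
    element_truth: dict,
    n_lines: int = 20,
    spacing_px: float = 1.0,
    image_origin_um: tuple[float, float] = (0.0, 0.0),
) -> ProfileSet:
    """Draw profiles perpendicular to a rendered three-bar element.

    ``element_truth`` is one entry of a resolution-target phantom's truth
    record (``roi_um`` as (y0, y1, x0, x1) and ``orientation``);
    ``image_origin_um`` locates image pixel (0, 0) in phantom coordinates,
    e.g. when the sensor window cropped a larger phantom.  Lines run along
    the modulation axis across the full triplet, centred in the bar length.
    """
    y0u, y1u, x0u, x1u = element_truth["roi_um"]
    oy, ox = image_origin_um

    def to_px(um: float, origin: float) -> float:
        return (um - origin) / pixel_pitch - 0.5

    if element_truth.get("orientation", "vertical") == "vertical":
        yc = to_px((y0u + y1u) / 2.0, oy)
        start = (yc, to_px(x0u, ox))
        end = (yc, to_px(x1u, ox))
    else:
        xc = to_px((x0u + x1u) / 2.0, ox)
        start = (to_px(y0u, oy), xc)
        end = (to_px(y1u, oy), xc)
    pset = extract_profiles(image, start, end, n_lines=n_lines,
                            spacing_px=spacing_px, pixel_pitch=pixel_pitch)
    pset.roi = (y0u, y1u, x0u, x1u)
    return pset


def _crossing(x: np.ndarray, y: np.ndarray, level: float,
              lo: int, hi: int, rising: bool) -> float | None:
    """First linear-interpolated crossing of ``level`` in y[lo:hi]."""
    for i in range(lo, hi):
        a, b = y[i], y[i + 1]
        if (a - level) * (b - level) <= 0 and a != b:
            if rising and b < a:
                continue
            if not rising and b > a:
                continue
            frac = (level - a) / (b - a)
            return float(x[i] + frac * (x[i + 1] - x[i]))
    return None


def psf_width_10_90(profile, sample_step: float) -> PSFEstimate:
    """Distance between the 10% and 90% crossings of an edge response.

    Threshold levels are ``min + 0.1 (max - min)`` and ``min + 0.9
    (max - min)``; crossing positions are found by linear interpolation
    between bracketing samples around the steepest transition.  A profile
    with several full transitions is measured at the steepest one and
    flagged ambiguous.
    """
    y = _reject_display_only(profile)
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    lo_v, hi_v = float(y.min()), float(y.max())
    if hi_v <= lo_v:
        raise NoEdgeError("profile is constant; no edge to measure")
    t10 = lo_v + 0.10 * (hi_v - lo_v)
    t90 = lo_v + 0.90 * (hi_v - lo_v)
    x = np.arange(len(y)) * sample_step

    # segment the profile into monotone runs and keep those spanning both
    # thresholds; measure the steepest
    grad = np.diff(y)
    candidates = []
    i = 0
    n = len(y)
    while i < n - 1:
        j = i
        sign = np.sign(grad[i]) or 1.0
        while j < n - 1 and (np.sign(grad[j]) == sign or grad[j] == 0):
            j += 1
        seg_lo, seg_hi = min(y[i], y[j]), max(y[i], y[j])
        if seg_lo <= t10 and seg_hi >= t90:
            steep = abs(y[j] - y[i]) / max(j - i, 1)
            candidates.append((steep, i, j, sign > 0))
        i = j
    if not candidates:
        raise NoEdgeError("no monotone transition spans both threshold levels")
    candidates.sort(reverse=True)
    _, i0, i1, rising = candidates[0]
    p10 = _crossing(x, y, t10, i0, i1, rising)
    p90 = _crossing(x, y, t90, i0, i1, rising)
    if p10 is None or p90 is None:
        raise NoEdgeError("threshold level never crossed within the transition")
    return PSFEstimate(
        pos_10=p10,
        pos_90=p90,
        width=abs(p90 - p10),
        threshold_levels=(t10, t90),
        ambiguous=len(candidates) > 1,
    )
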