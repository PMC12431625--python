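"""LED-grid planning, frame normalization and hologram stitching.

The light source is a 640 x 480 micro-LED display.  Firing a grid of LEDs
one at a time translates the in-line hologram across the fixed sensor by
the geometric shadow shift ``-Δsource * z1/z2``; normalizing each frame and
mosaicking the frames at those shifts produces a single composite hologram
covering a field of view larger than any single frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import ContractError, DegenerateFrameError, PlanningError
from .optics import OpticalConfig

__all__ = [
    "DISPLAY_SHAPE",
    "LEDGridPlan",
    "Hologram",
    "HologramSet",
    "CompositeHologram",
    "plan_grid",
    "normalize",
    "expected_shift",
    "stitch",
]

#: Micro-LED display size as (rows, cols) of addressable LEDs.
DISPLAY_SHAPE = (480, 640)


@dataclass(frozen=True)
class LEDGridPlan:
    """Which LEDs fire, in what order, and their physical displacements.

    ``step_leds`` LEDs between consecutive grid points at ``led_pitch`` µm
    per LED gives a physical step of ``step_leds * led_pitch`` µm between
    adjacent holograms.
    """

    rows: int
    cols: int
    step_leds: int
    led_pitch: float
    center_led: tuple[int, int] = (240, 320)
    ordering: str = "row_major"

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.step_leds) < 1:
            raise PlanningError("rows, cols and step_leds must all be >= 1")
        if self.led_pitch <= 0:
            raise PlanningError(f"led_pitch must be positive, got {self.led_pitch}")
        if self.ordering not in ("row_major", "serpentine"):
            raise PlanningError(f"unknown scan ordering {self.ordering!r}")
        for r, c in self.led_indices():
            if not (0 <= r < DISPLAY_SHAPE[0] and 0 <= c < DISPLAY_SHAPE[1]):
                raise PlanningError(
                    f"planned LED ({r}, {c}) lies off the "
                    f"{DISPLAY_SHAPE[0]}x{DISPLAY_SHAPE[1]} display"
                )

    @property
    def n_frames(self) -> int:
        return self.rows * self.cols

    @property
    def physical_step(self) -> float:
        """Source displacement between adjacent grid points, µm."""
        return self.step_leds * self.led_pitch

    def _grid_indices(self) -> list[tuple[int, int]]:
        out = []
        for i in range(self.rows):
            js = range(self.cols)
            if self.ordering == "serpentine" and i % 2 == 1:
                js = reversed(js)
            out.extend((i, j) for j in js)
        return out

    def led_indices(self) -> list[tuple[int, int]]:
        """Display (row, col) address of every planned LED, in scan order."""
        r0, c0 = self.center_led
        out = []
        for i, j in self._grid_indices():
            dr = round((i - (self.rows - 1) / 2) * self.step_leds)
            dc = round((j - (self.cols - 1) / 2) * self.step_leds)
            out.append((r0 + dr, c0 + dc))
        return out

    def offsets_um(self) -> list[tuple[float, float]]:
        """Physical (dx, dy) source displacement of every frame, µm.

        Measured from the grid centre so the central frame (odd grids) has
        offset (0, 0).  x follows display columns, y display rows.
        """
        out = []
        for i, j in self._grid_indices():
            dy = (i - (self.rows - 1) / 2) * self.physical_step
            dx = (j - (self.cols - 1) / 2) * self.physical_step
            out.append((dx, dy))
        return out


def plan_grid(
    rows: int,
    cols: int,
    step_leds: int,
    led_pitch: float,
    center_led: tuple[int, int] = (240, 320),
    ordering: str = "row_major",
) -> LEDGridPlan:
    """Plan a rows x cols LED acquisition grid centred on ``center_led``."""
    return LEDGridPlan(rows, cols, step_leds, led_pitch, center_led, ordering)


@dataclass
class Hologram:
    """A single nonnegative intensity frame tagged with its LED."""

    intensity: np.ndarray
    led_index: tuple[int, int] = (0, 0)
    led_offset_um: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ContractError("hologram intensity must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise ContractError("hologram intensity must be finite")
        if np.any(self.intensity < 0):
            raise ContractError("hologram intensity must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class HologramSet:
    """An ordered LED-grid acquisition plus its illumination-off background."""

    frames: list[Hologram]
    background: Hologram
    config: OpticalConfig
    plan: LEDGridPlan
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.frames) != self.plan.n_frames:
            raise ContractError(
                f"plan promises {self.plan.n_frames} frames, got {len(self.frames)}"
            )
        shape = self.background.shape
        for k, frame in enumerate(self.frames):
            if frame.shape != shape:
                raise ContractError(
                    f"frame {k} shape {frame.shape} differs from background {shape}"
                )


@dataclass
class CompositeHologram:
    """Mosaicked composite hologram representing the full field of view."""

    intensity: np.ndarray
    offsets_used: list[tuple[float, float]]
    config: OpticalConfig
    plan: LEDGridPlan
    flagged_pairs: list[int] = field(default_factory=list)


def normalize(holo_set: HologramSet) -> HologramSet:
    """Correct per-frame LED intensity variation and ambient light.

    Each frame is background-subtracted (clipped at zero), then divided by
    its own robust mean — the whole-frame median — so every frame ends up
    with unit median.  The median estimates the illumination level
    independently of where the (sparse, dark) sample sits in the frame, so
    frames that view shifted copies of the same scene normalize to a common
    scale; a region-restricted statistic would rescale them differently
    whenever the object straddles the region boundary.  Frames whose raw
    mean is below twice the background mean are flagged ``low_signal`` in
    their metadata.
    """
    bg = holo_set.background.intensity
    bg_mean = float(bg.mean())

    out_frames = []
    for k, frame in enumerate(holo_set.frames):
        sub = np.clip(frame.intensity - bg, 0.0, None)
        robust = float(np.median(sub))
        if robust <= 0:
            raise DegenerateFrameError(
                f"frame {k} has no signal above background (central median "
                f"{robust}); cannot normalize"
            )
        meta = dict(frame.metadata)
        if float(frame.intensity.mean()) < 2.0 * bg_mean:
            meta["low_signal"] = True
        out_frames.append(
            Hologram(sub / robust, frame.led_index, frame.led_offset_um, meta)
        )
    return HologramSet(out_frames, holo_set.background, holo_set.config,
                       holo_set.plan, normalized=True)


def expected_shift(
    led_displacement: tuple[float, float], config: OpticalConfig
) -> tuple[float, float]:
    """Geometric hologram shift on the sensor for a source displacement.

    A source displacement ``(dx, dy)`` µm moves the shadow by
    ``-(dx, dy) * z1/z2`` µm on the sensor (opposite the source).  Returned
    as (pixels_y, pixels_x) at the camera pixel pitch.
    """
    dx, dy = led_displacement
    gain = config.z_sample_sensor / config.z_source_sample
    return (
        -dy * gain / config.camera_pixel_pitch,
        -dx * gain / config.camera_pixel_pitch,
    )


def _feather_weights(shape: tuple[int, int]) -> np.ndarray:
    # separable triangular window: weight ~ distance to the nearest frame edge
    rows, cols = shape
    wy = np.minimum(np.arange(rows) + 1, rows - np.arange(rows))
    wx = np.minimum(np.arange(cols) + 1, cols - np.arange(cols))
    return wy[:, None] * wx[None, :].astype(np.float64)


def _refine_pair(
    ref: np.ndarray,
    mov: np.ndarray,
    rel_geo: tuple[float, float],
    window: float,
) -> tuple[float, float] | None:
    """Phase-correlation offset of ``mov`` relative to ``ref`` near ``rel_geo``.

    Crops the geometrically overlapping regions, registers them with
    upsampled phase correlation, and returns the refined relative offset, or
    None when the overlap is too small or the correction exceeds ``window``.
    """
    rows, cols = ref.shape
    gy, gx = int(round(rel_geo[0])), int(round(rel_geo[1]))
    # overlap of ref with mov placed at (gy, gx)
    y0, y1 = max(0, gy), min(rows, rows + gy)
    x0, x1 = max(0, gx), min(cols, cols + gx)
    if (y1 - y0) < 16 or (x1 - x0) < 16:
        return None
    a = ref[y0:y1, x0:x1]
    b = mov[y0 - gy : y1 - gy, x0 - gx : x1 - gx]
    try:
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=10, normalization=None)
    except Exception:  # registration failure -> geometric fallback
        return None
    refined = (gy + float(shift[0]), gx + float(shift[1]))
    if abs(refined[0] - rel_geo[0]) > window or abs(refined[1] - rel_geo[1]) > window:
        return None
    return refined


def stitch(
    holo_set: HologramSet,
    *,
    refine: bool = True,
    blend: str = "feather",
    refine_window: float = 8.0,
    min_overlap_fraction: float = 0.10,
) -> CompositeHologram:
    """Mosaic normalized frames into one composite hologram.

    Frames are placed at their geometric positions (the negated shadow
    shift of :func:`expected_shift`), refined per adjacent pair by
    upsampled phase correlation within ``±refine_window`` pixels, rounded to
    0.1 px, bilinearly resampled, and feather-blended over the overlaps.
    Pairs whose correlation correction exceeds the window fall back to the
    geometric placement and are recorded in ``flagged_pairs``.
    """
    if not holo_set.normalized and len(holo_set.frames) > 1:
        warnings.warn(
            "stitching a non-normalized hologram set; intensities may step at seams",
            RuntimeWarning,
            stacklevel=2,
        )
    frames = holo_set.frames
    config = holo_set.config
    plan = holo_set.plan
    n = len(frames)
    shape = frames[0].shape

    # frame placement = where the sensor window sits on the object-side
    # mosaic = minus the hologram shadow shift
    geo = []
    for frame in frames:
        sy, sx = expected_shift(frame.led_offset_um, config)
        geo.append((-sy, -sx))

    step_px = abs(plan.physical_step * config.z_sample_sensor
                  / config.z_source_sample / config.camera_pixel_pitch)
    if n > 1 and step_px > (1.0 - min_overlap_fraction) * min(shape):
        warnings.warn(
            f"adjacent frames overlap by less than {min_overlap_fraction:.0%} "
            "of the frame extent; stitching may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    offsets = list(geo)
    flagged: list[int] = []
    if refine and n > 1:
        # spanning tree over the scan order: refine each frame against the
        # previous one; row starts refine against the frame one row up
        order = plan._grid_indices()
        pos_of = {ij: k for k, ij in enumerate(order)}
        for k in range(1, n):
            i, j = order[k]
            parent = None
            for cand in ((i, j - 1), (i, j + 1), (i - 1, j)):
                if cand in pos_of and pos_of[cand] < k:
                    parent = pos_of[cand]
                    break
            if parent is None:
                parent = k - 1
            rel_geo = (geo[k][0] - geo[parent][0], geo[k][1] - geo[parent][1])
            refined = _refine_pair(
                frames[parent].intensity, frames[k].intensity, rel_geo, refine_window
            )
            if refined is None:
                offsets[k] = (offsets[parent][0] + rel_geo[0],
                              offsets[parent][1] + rel_geo[1])
                flagged.append(k)
            else:
                offsets[k] = (offsets[parent][0] + refined[0],
                              offsets[parent][1] + refined[1])

    # round to 0.1 px, then shift origin so all placements are nonnegative
    offsets = [(round(oy * 10) / 10, round(ox * 10) / 10) for oy, ox in offsets]
    oy_min = min(o[0] for o in offsets)
    ox_min = min(o[1] for o in offsets)
    placements = [(oy - oy_min, ox - ox_min) for oy, ox in offsets]

    canvas_rows = int(np.floor(max(p[0] for p in placements))) + shape[0]
    canvas_cols = int(np.floor(max(p[1] for p in placements))) + shape[1]
    acc = np.zeros((canvas_rows, canvas_cols))
    wacc = np.zeros((canvas_rows, canvas_cols))
    base_w = (_feather_weights(shape) if blend == "feather"
              else np.ones(shape, dtype=np.float64))

    for frame, (py, px) in zip(frames, placements):
        iy, ix = int(np.floor(py)), int(np.floor(px))
        fy, fx = py - iy, px - ix
        if fy or fx:
            # bilinear resample for the sub-pixel part of the placement
            img = ndimage.shift(frame.intensity, (fy, fx), order=1, mode="nearest")
        else:
            img = frame.intensity
        acc[iy : iy + shape[0], ix : ix + shape[1]] += img * base_w
        wacc[iy : iy + shape[0], ix : ix + shape[1]] += base_w

    composite = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
    return CompositeHologram(composite, offsets, config, plan, flagged)
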