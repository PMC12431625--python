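"""On-disk formats: TIFF hologram sets with YAML descriptors, float TIFF
reconstructions with JSON metadata, CSV/JSON metrology and detection output.

A hologram set is a directory holding ``frames.tif`` (multi-page 16-bit,
one page per LED), ``background.tif`` and ``descriptor.yaml``.  Frames are
quantized against the recorded ``data_max`` so that a written-then-read set
re-writes bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .acquisition import Hologram, HologramSet, LEDGridPlan
from .detect import DetectionResult
from .errors import FormatError
from .metrology import MTFCurve
from .optics import OpticalConfig
from .reconstruct import Reconstruction

__all__ = [
    "write_hologram_set",
    "read_hologram_set",
    "write_reconstruction",
    "read_reconstruction",
    "write_mtf_csv",
    "write_detections",
]

_FULL_SCALE = 65535


def _config_to_dict(config: OpticalConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sensor_shape"] = list(d["sensor_shape"])
    return d


def _plan_to_dict(plan: LEDGridPlan) -> dict:
    d = dataclasses.asdict(plan)
    d["center_led"] = list(d["center_led"])
    return d


def write_hologram_set(holo_set: HologramSet, directory: str | Path) -> Path:
    """Write frames + background as 16-bit TIFF with a YAML descriptor."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.intensity for f in holo_set.frames])
    data_max = float(max(stack.max(), holo_set.background.intensity.max(), 1e-30))
    quant = np.round(stack / data_max * _FULL_SCALE).astype(np.uint16)
    bg = np.round(holo_set.background.intensity / data_max * _FULL_SCALE).astype(np.uint16)
    # explicit photometric: a 3- or 4-frame stack must not be guessed as RGB
    tifffile.imwrite(directory / "frames.tif", quant, photometric="minisblack")
    tifffile.imwrite(directory / "background.tif", bg, photometric="minisblack")
    descriptor = {
        "n_frames": len(holo_set.frames),
        "data_max": data_max,
        "bit_depth": 16,
        "normalized": holo_set.normalized,
        "led_indices": [list(f.led_index) for f in holo_set.frames],
        "led_offsets_um": [list(f.led_offset_um) for f in holo_set.frames],
        "optical": _config_to_dict(holo_set.config),
        "plan": _plan_to_dict(holo_set.plan),
    }
    (directory / "descriptor.yaml").write_text(yaml.safe_dump(descriptor, sort_keys=False))
    return directory


def read_hologram_set(directory: str | Path) -> HologramSet:
    """Read a hologram-set directory back into memory.

    Accepts 8- or 16-bit frames; intensities are rescaled to the recorded
    physical scale (float).  Raises :class:`FormatError` on a missing
    descriptor, a frame-count mismatch, or mixed frame shapes.
    """
    directory = Path(directory)
    desc_path = directory / "descriptor.yaml"
    if not desc_path.exists():
        raise FormatError(f"missing descriptor: {desc_path}")
    descriptor = yaml.safe_load(desc_path.read_text())
    frames_path = directory / "frames.tif"
    if not frames_path.exists():
        raise FormatError(f"missing frame stack: {frames_path}")
    stack = tifffile.imread(frames_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.dtype == np.uint8:
        full_scale = 255
    elif stack.dtype == np.uint16:
        full_scale = _FULL_SCALE
    else:
        raise FormatError(
            f"{frames_path}: unsupported bit depth {stack.dtype}; expected 8/16-bit"
        )
    n_expected = int(descriptor["n_frames"])
    if stack.shape[0] != n_expected:
        raise FormatError(
            f"{frames_path}: descriptor promises {n_expected} frames, "
            f"file has {stack.shape[0]}"
        )
    bg_path = directory / "background.tif"
    if not bg_path.exists():
        raise FormatError(f"missing background frame: {bg_path}")
    bg = tifffile.imread(bg_path)
    if bg.shape != stack.shape[1:]:
        raise FormatError(
            f"{bg_path}: background shape {bg.shape} differs from frames "
            f"{stack.shape[1:]}"
        )
    data_max = float(descriptor.get("data_max", 1.0))
    scale = data_max / full_scale
    opt = dict(descriptor["optical"])
    opt["sensor_shape"] = tuple(opt["sensor_shape"])
    config = OpticalConfig(**opt)
    plan_d = dict(descriptor["plan"])
    plan_d["center_led"] = tuple(plan_d["center_led"])
    plan = LEDGridPlan(**plan_d)
    frames = [
        Hologram(
            stack[k].astype(np.float64) * scale,
            led_index=tuple(descriptor["led_indices"][k]),
            led_offset_um=tuple(descriptor["led_offsets_um"][k]),
        )
        for k in range(n_expected)
    ]
    background = Hologram(bg.astype(np.float64) * scale, metadata={"background": True})
    return HologramSet(frames, background, config, plan,
                       normalized=bool(descriptor.get("normalized", False)))


def write_reconstruction(recon: Reconstruction, directory: str | Path,
                         stem: str = "reconstruction") -> Path:
    """Write amplitude/phase as 32-bit float TIFF plus JSON run metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_amplitude.tif",
                     recon.amplitude.astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_phase.tif", recon.phase.astype(np.float32))
    meta = {
        "z_um": recon.z_used,
        "magnification": recon.magnification_applied,
        "pixel_pitch_um": recon.pixel_pitch,
        "iterations": recon.iterations,
        "residual_history": recon.residual_history,
        "diverged": recon.diverged,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_reconstruction(directory: str | Path,
                        stem: str = "reconstruction") -> Reconstruction:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    amplitude = tifffile.imread(directory / f"{stem}_amplitude.tif").astype(np.float64)
    phase = tifffile.imread(directory / f"{stem}_phase.tif").astype(np.float64)
    return Reconstruction(
        amplitude=amplitude,
        phase=phase,
        z_used=meta["z_um"],
        magnification_applied=meta["magnification"],
        pixel_pitch=meta["pixel_pitch_um"],
        iterations=meta["iterations"],
        residual_history=meta["residual_history"],
        diverged=meta["diverged"],
    )


def write_mtf_csv(curve: MTFCurve, path: str | Path) -> Path:
    path = Path(path)
    lines = ["frequency_lp_per_mm,mean_contrast,sd"]
    lines += [f"{f:.6g},{c:.6g},{s:.6g}" for f, c, s in curve.points]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_detections(result: DetectionResult, directory: str | Path,
                     stem: str = "detections") -> Path:
    """Write detections as CSV (x_um, y_um, radius_um) and a summary JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["x_um,y_um,radius_um"]
    lines += [
        f"{x:.4f},{y:.4f},{r:.4f}"
        for (y, x), r in zip(result.centers_um, result.radii_um)
    ]
    (directory / f"{stem}.csv").write_text("\n".join(lines) + "\n")
    summary = {
        "count": result.count,
        "fov_area_mm2": result.fov_area_mm2,
        "chamber_depth_um": result.chamber_depth_um,
        "concentration_per_ml": result.concentration_per_ml,
    }
    (directory / f"{stem}.json").write_text(json.dumps(summary, indent=2))
    return directory
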