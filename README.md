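# holoscope

Lensless in-line holographic microscopy in software: simulate the holograms a
chip-scale microscope records when a micro-LED array illuminates a sample from
sub-millimetre range, reconstruct them, and quantify what the instrument can
resolve and count.

## Who this is for

Developers of on-chip, lensless microscopes — continuous in-situ monitors for
cell culture, fermentation, or small-organism imaging — who need a testable
software pipeline before (or alongside) hardware: a seeded forward model with
ground truth, the reconstruction chain, and the standard metrology that goes
with it.

## The imaging model

A point-like LED at distance `z2` above the sample illuminates it; the bare
CMOS sensor at distance `z1` below records the interference of the scattered
and unscattered light — an in-line (Gabor) hologram.  Under the paraxial
equivalence for spherical-wave illumination this hologram equals a plane-wave
hologram of the object magnified by

```
M = (z1 + z2) / z2,        z_eff = z1·z2 / (z1 + z2)
```

recorded at the effective distance `z_eff`.  All computation runs on the
demagnified object-plane grid (pitch = camera pitch / M) with the band-limited
angular-spectrum propagator

```
U(z) = F⁻¹[ F[U(0)] · exp( i·2π·z·sqrt(1/λ² − f²) ) ]
```

Firing an LED grid one element at a time translates the hologram across the
sensor by `−Δsource·z1/z2`; background-subtracted, median-normalized frames
are mosaicked at those shifts (refined by phase correlation) into a composite
covering the full field of view.  Reconstruction backpropagates
`sqrt(intensity)` by `z_eff`; the twin image inherent to single-shot in-line
holography is suppressed by alternating projections between the measured
sensor amplitude and an object-plane physicality constraint (|t| ≤ 1, or
t ∈ [0,1] for purely absorbing targets).

Metrology follows standard three-bar-target practice: Michelson contrast
`C_M = (L_max − L_min)/(L_max + L_min)` of averaged line profiles per USAF
element (`f = 2^(group+(element−1)/6)` lp/mm) builds the MTF; the 10–90%
width of an edge response estimates the PSF width.  Cell-like objects are
counted with a circular Hough transform and converted to cells/mL through the
imaged chamber volume.

## Worked example

```python
import numpy as np
import holoscope as h

# geometry: sample 1.2 mm above the sensor, micro-LED display 0.6 mm above the sample
config = h.OpticalConfig(
    z_sample_sensor=1200.0,   # z1, µm
    z_source_sample=600.0,    # z2, µm
    sensor_shape=(512, 512),
)
geom = h.derive_geometry(config)
print(f"magnification M = {geom.magnification:.2f}, "
      f"effective distance = {geom.z_effective:.0f} µm")

# synthetic yeast-like sample: 25 partially absorbing disks with ground truth
pitch = h.object_plane_pitch(config)
phantom = h.make_disk_phantom(
    25, radius_range=(2.5, 4.0), pixel_pitch=pitch,
    field_size=(640, 640), seed=42, min_separation=25.0,
    edge_margin_um=(64 + 80) * pitch,
)

# acquire, normalize, stitch, reconstruct with twin-image suppression
plan = h.plan_grid(1, 1, 1, config.led_pitch)
holograms = h.simulate_grid_acquisition(phantom, config, plan, seed=42,
                                        noise=h.NoiseSpec())
composite = h.stitch(h.normalize(holograms))
recon = h.twin_image_remove(composite, z_object=1200.0, n_iter=50)
print(f"twin-image removal: {recon.iterations} iterations, "
      f"final residual {recon.residual_history[-1]:.4f}")

# count the cells and estimate the concentration
result = h.hough_circles(recon.amplitude, recon.pixel_pitch,
                         radius_range_um=(2.0, 5.0), border_px=32)
fov_mm2 = np.prod(recon.amplitude.shape) * (recon.pixel_pitch * 1e-3) ** 2
conc = h.concentration(result, fov_area_mm2=fov_mm2, chamber_depth_um=100.0)
print(f"detected {result.count} cells in {fov_mm2:.3f} mm² "
      f"-> {conc:.2e} cells/mL")
```

Output:

```
magnification M = 3.00, effective distance = 400 µm
twin-image removal: 50 iterations, final residual 0.0025
detected 25 cells in 0.168 mm² -> 1.49e+06 cells/mL
```

All 25 seeded cells are recovered; the residual is the RMS mismatch between
the re-propagated object estimate and the measured hologram amplitude, and
the concentration falls in the 0.5–50 × 10⁶ cells/mL range where Hough
counting is considered reliable.

The same pipeline is scriptable from a shell via the `holoscope` command
(`simulate`, `reconstruct`, `mtf`, `count`) driven by a validated YAML
configuration; every run appends a structured log entry with the
configuration hash and seed.

## Layout

| module | contents |
|---|---|
| `holoscope.optics` | geometry, `ComplexField`, angular-spectrum propagation |
| `holoscope.simulate` | phantoms (USAF bars, disks, edges), forward model, noise |
| `holoscope.acquisition` | LED grid plans, normalization, stitching |
| `holoscope.reconstruct` | backpropagation, twin-image removal, autofocus, z-stacks |
| `holoscope.metrology` | line profiles, Michelson contrast, MTF, PSF width |
| `holoscope.detect` | circular Hough counting, concentration |
| `holoscope.io`, `.config`, `.cli` | TIFF/YAML/CSV/JSON formats and the CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
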