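# Methods

This note documents the physical model behind `holoscope`, the defaults it
ships with, what the synthetic data does and does not emulate, and the
numerical choices a user may want to revisit.

## Geometry and propagation

The instrument is modelled as a point-like emitter at distance `z2` above the
sample and a bare sensor at `z1` below it, with `z2 < z1` (source-near-sample
regime; typical values `z2` = 100–600 µm, `z1` = 1–11 mm).  Rather than
sampling the diverging spherical wave explicitly — which at magnifications of
20–70 would require grids of billions of samples — the pipeline uses the
standard paraxial equivalence: the recorded hologram equals a plane-wave
hologram of the object magnified by `M = (z1+z2)/z2`, recorded at
`z_eff = z1·z2/(z1+z2)`.  Everything runs on the demagnified object-plane
grid whose pitch is the camera pitch divided by `M`; coordinates are
rescaled only at reporting boundaries.

Free-space propagation is the FFT-based angular-spectrum method with the
band-limited transfer function (per-axis frequency cap
`1/(λ·sqrt((2·Δf·z)² + 1))` plus the evanescent cutoff `|f| < 1/λ`), zero
2× padding per axis, and an optional Fresnel kernel.  Evanescent components
are zeroed on backpropagation rather than amplified.

**Aperture handling (load-bearing).**  A finite sensor window zero-padded
before the FFT behaves like a hard aperture and stamps its own diffraction
rings on every simulated hologram and every reconstruction; these rings
dominated background statistics in early versions.  The forward model and
single-pass backpropagation therefore pad with the *unit background* (the
normalized in-line hologram continues at ≈1 beyond the window), and the
iterative twin-image loop runs on a 2×-padded workspace whose border is a
free, unmeasured boundary: the measured-amplitude projection applies only
inside the sensor window.  Objects closer than roughly the fringe-support
radius (`~ z_eff·λ / feature size`, in pixels) to the window edge still lose
part of their fringes — physical vignetting that no padding can undo — which
is why detection examples keep objects in the interior of the field of view.

## Units and conventions

Micrometres for every length; spatial frequencies cycles/µm internally,
lp/mm (×1000) at reporting interfaces.  Arrays are row-major, origin top-left,
y down; DFT frequencies stay in standard layout with `fftshift` only at
display boundaries.  The default wavelength is 0.45 µm — a typical blue
InGaN micro-LED emission; the display's actual spectrum is a declared
assumption, configurable per run.  Default camera pitch 2.4 µm, LED pitch
4 µm on a 640×480 display, emitter diameter 1 µm.

## Forward model and the noise it includes

`simulate_hologram` propagates `amplitude·exp(i·phase)` over `z_eff`, takes
the intensity, and then applies, in order:

1. **Partial spatial coherence** — intensity convolution with the
   geometrically imaged source spot (a top-hat disk of diameter
   `Δs·z1/z2` at the sensor).  This is the exact paraxial limit of summing
   mutually incoherent source points and is what makes a 1 µm micro-LED
   outperform a 90–150 µm pinhole: the blur at object scale is
   `Δs·z1/(z1+z2) ≈ Δs`.
2. **LED-shift crop** — the hologram translates by `−Δsource·z1/z2` on the
   fixed sensor window; the frame is the (bilinearly resampled) window of the
   full-field pattern.
3. **Noise** — Poisson shot noise at a photon budget of 5,000 counts/pixel at
   unit intensity, Gaussian read noise σ = 2 counts, constant ambient offset
   20 counts; per-LED intensity jitter ±5% across a grid acquisition.  All
   stages are seeded and bitwise reproducible.

Not modelled: temporal coherence (LED bandwidth) by default — an optional
Gaussian wavelength average exists but is off, since the display bandwidth is
unknown; sensor MTF/fill factor; rolling shutter; laser speckle.  Passing
tests on this generator therefore demonstrates algorithmic correctness under
shot noise, read noise, jitter and finite spatial coherence, not robustness
to chromatic blur or sensor non-idealities.

Phantoms carry machine-readable ground truth (element ROIs and lp/mm for bar
targets, centres/radii for disks, the analytic 10–90% width for erf edges)
and render with area-weighted anti-aliasing, so sub-pixel metrology against
truth is meaningful.

## Acquisition processing

Frames are background-subtracted (clipped at zero) and divided by their own
whole-frame median, giving every frame unit median.  The median estimates the
illumination level independently of where the (sparse, dark) sample sits in
the frame; a statistic restricted to a central region rescales shifted frames
differently whenever the object straddles the region boundary and visibly
breaks stitching.  This removes the ±5% LED jitter exactly and flags frames
whose raw mean is under twice the background mean.

Stitching places frames at the geometric shadow shifts, refines each adjacent
pair by upsampled phase correlation (0.1 px, constrained to ±8 px of the
geometric prior with fallback and flagging), rounds placements to 0.1 px with
bilinear resampling, and feather-blends overlaps with a separable triangular
weight.  Mosaicking, not pixel-super-resolution fusion: the goal is field of
view, matching the instrument's own composite.  The ≥10% overlap warning
threshold is a package convention — the physical protocol only states that
its 10-LED step "ensured sufficient overlap".

## Reconstruction

`backpropagate` forms `sqrt(I)` with zero phase and propagates by `−z_eff`.
`twin_image_remove` is classic in-line alternating projection: object-plane
constraint, forward propagation, replace amplitude with the measurement, keep
phase.  Constraints:

- `absorption` (default): transmission magnitude clamped to ≤ 1 — a passive
  object cannot amplify light.  Phase is free, which means a *purely*
  absorbing object can be partly "explained" as a phase object; background
  ripple is still strongly suppressed (the Fig.-8-style benefit), but
  amplitude contrast of binary targets may be underestimated.
- `real`: transmission clamped to real `[0, 1]` — the right model for
  chrome-on-glass resolution targets, and the constraint used in the
  distance–contrast acceptance test.
- `positive_phase`, `none`, optional support mask.

Default 20 iterations, stop when the relative sensor-plane residual change
falls below 1e−4; a residual growing five consecutive iterations flags
divergence and returns the best iterate.  Amplitude (not intensity) is what
downstream analysis consumes; phase is retained and exported.

**Autofocus metric.**  The Tamura coefficient of the amplitude — a common
choice — turns out to be monotone in `z` on noiseless coherent
reconstructions: defocus chirps keep injecting amplitude texture, so the
curve never peaks.  The default metric is instead the excess kurtosis of the
amplitude-gradient magnitude (an edge-sparsity measure): at focus, gradients
are a few strong object edges over a quiet background (heavy-tailed
distribution); defocus spreads them into many moderate fringe gradients and
the kurtosis collapses.  The peak half-width is ≈1% of `z`, so the coarse
search uses a geometric grid at 0.75% relative spacing before golden-section
refinement to 1 µm.  Two practical notes: reconstructions very close to the
sensor retain sparse ring patterns and can produce a rival kurtosis maximum
at the bottom of a very wide bracket, and sparse scenes weaken the peak —
a field of a few dozen objects focuses much more reliably than one or two.
Note the magnification rescaling makes the recoverable focus parameter
`λ·z1·(z1+z2)/(p²·z2)` in pixel units — strongly sensitive to `z1` even when
`z_eff` saturates at `z2 ≪ z1`.

The pipeline stitches raw (normalized) holograms first and reconstructs the
composite — the stage order implied by the acquisition protocol; per-frame
reconstruction remains available for debugging.

## Metrology

Profiles are bilinear samples along 20 parallel lines (1 px spacing) drawn
perpendicular to the bar pattern; contrast is Michelson on the global
extrema within the pattern region (a local peak/valley-mean variant exists
behind a flag).  Gaussian smoothing of a mean profile is display-only: the
result carries a `display_only` flag and every quantitative operation rejects
it.  The 10%/90% thresholds of the PSF-width estimator are relative to the
profile's own extrema — the absolute intensity scale of any particular
readout is not reproducible — and crossings are linearly interpolated within
the steepest monotone transition, with an ambiguity flag when several
transitions span both thresholds.

## Detection

Cells appear as dark cores on a rippled unit background, and residual twin
ripple defeats a plain gradient→Hough chain, so the edge map is gated:
pixels below 0.65× the image median (minimum area: a third of the
smallest-radius disk) mark candidate cores; Canny edges within 1.5 max-radii
of a core vote in the circular Hough accumulator; peaks above 0.45× the
strongest peak survive non-maximum suppression at one detected radius, with
an optional border-exclusion zone for window-vignetting artifacts.  The
0.65/0.45 defaults were set so that 25 well-separated simulated cells are
recovered exactly under the default noise model; both are parameters.
Concentration is `count / (FOV area × chamber depth)` in cells/mL — the
chamber depth is configuration-required, deliberately without a default —
with a warning outside the 0.5–50 × 10⁶ cells/mL range in which Hough
counting has been validated against manual counts.

## Problem sizes in tests

The acceptance suite runs on 256²–512² sensor grids: 10-seed twin-image and
counting studies at 256²/512², MTF pairs at 512², autofocus at 512² over
three object distances, and 64² grids for the direct Rayleigh–Sommerfeld
quadrature oracle (an O(N⁴) sum).  These sizes keep each property readable
as a single deterministic experiment; all scale linearly in FFT cost if
enlarged.

## Known limitations

- The paraxial equivalence ignores aberrations of the true spherical wave at
  the field edges (relevant above M ≈ 50 with wide sensors).
- Twin-image suppression with the default constraint under-recovers the
  amplitude of strong binary absorbers (phase leakage, above); use `real`
  for chrome targets.
- The intensity-convolution coherence model is exact only in the paraxial
  incoherent-superposition limit; very large source diameters (≫100 µm) at
  very short `z2` would need explicit source-point sums.
- Stitching assumes pure translation between frames; the true per-LED
  perspective change is second-order at these geometries and is ignored.
- Counting assumes roughly circular, well-separated, absorbing objects;
  budding or touching cells merge or split detections.
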