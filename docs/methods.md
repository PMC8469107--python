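# Methods

This note records the models behind `osldose`, the defaults and why they
were chosen, and what the synthetic validation does and does not show.

## Measurement model

A stack of `n = 40` luminescent silicone foils (thickness 0.543 mm) sits
behind a 10 mm hemispherical cap; both materials have a water-equivalent
thickness (WET) factor of 1.05, so the foil mid-planes sample water depths

    z_i = (t_cap + (i - 1/2) t_foil) · 1.05 ,  i = 1..40,

from 10.79 mm to 33.02 mm, 0.570 mm apart, with a total water range of
(10 + 40·0.543)·1.05 = 33.31 mm. The per-foil thickness default is 0.543 mm
rather than the nominal 0.54 mm because only the former is consistent with
the stated total stack thickness of 31.72 mm; both are configurable on
`StackGeometry`. Depth is assigned at the foil mid-plane — the unbiased
location for a signal integrated through the foil — and the cap is treated
as a uniform WET shift (no curvature correction across the small lateral
field).

Each foil readout is modelled as

    counts = dark + gain · η(z) · D(x, y, z) · s(x, y) · v(x, y)   (in disc)

with `η` the luminescence efficiency (quenching), `D` the relative dose,
`s` the foil's sensitivity granularity and `v` the illumination pattern of
the stimulation optics; Poisson noise acts on the expected counts, Gaussian
read noise is added after.

## Synthetic beam and phantom

No functional forms are published for the measured beam — only its metrics
(R90 = 28.96 mm, modulation = 10 mm, distal fall-off Δ = 0.88 mm) — so the
generator uses the minimal parametric family that reproduces every quoted
metric exactly by construction:

    D(z) = [e + (1 − e) Φ((z − c)/σ_r)] · Φ((R50 − z)/σ_d)

with Φ the standard normal CDF, σ_d = Δ / (2 Φ⁻¹(0.9)) so the 90→10%
distance is Δ, R50 = R90 + Φ⁻¹(0.9) σ_d so the distal 90% crossing is at
R90, and the ramp centre `c` placed so the curve crosses 90% exactly at
R90 − modulation. Entrance ratio `e = 0.7` and ramp width `σ_r = 2 mm` are
plausible placeholders, never treated as ground truth of the clinical beam.
The pristine (single-energy) beam used for calibration is a saturating
residual-range rise times the same Gaussian-CDF edge, normalised to peak 1.

Quenching is a Birks-type saturation on a residual-range LET proxy,

    η(z) = 1 / (1 + k_B L(z)),   L(z) = L0 + a / (R_e − z + δ)  (clamped
    at R_e),

with defaults k_B = 0.15, L0 = 0.5, a = 1, R_e = 29.5 mm, δ = 0.3 mm,
giving ~8% under-response at the entrance rising to ~25% near the range
end — the magnitude and direction of the under-response seen in OSL
dosimetry. No measured LET-efficiency data exist for this phosphor, so the
generator and the calibration stage share this one synthetic physics; that
is exactly the approximation the real experiment makes when it transfers a
pristine-beam calibration to an SOBP as a pure function of depth.

The collimator aperture is a slightly irregular 12-gon (~13.5 mm across)
blurred with a 1 mm Gaussian penumbra. Camera defaults: 256×256 px at
0.1 mm/px, foil radius 100 px (20 mm foil), gain 20 000 counts per unit
dose (peak ~26 k counts on a 16-bit CCD), dark level 100, read noise 5
counts, flat-field level ~30 k counts. Nuisance amplitudes: 8% RMS
sensitivity granularity with 0.3 mm correlation length and a 15%
illumination fall-off, both *defined over the foil disc* (the amplitudes
describe the foil and the optics across the foil, not empty frame
corners); foil placement jitters uniformly by ±0.5 mm between readouts so
that registration does real work. The 13 calibration foils carry 0.5%
relative signal noise, matching the per-foil reproducibility the camera
model itself produces for window-averaged corrected signals.

## Correction chain

Fixed order, enforced through a provenance log on every image:
background subtraction (clamped at zero — later stages divide, and
sub-noise pixels are handled by the mask), ROI detection on the live view,
clipping, flat-field division, 3×3 median filtering, IRI division.

* The ROI threshold is the midpoint of the two class medians after an
  exact (unbinned) maximum between-class-variance split; centre is the
  intensity-weighted component centroid, radius is `sqrt(area/π)`. Both
  are offset-invariant. The mask keeps a half-pixel guard inside the
  detected radius: rim pixels straddling the physical foil edge carry no
  phosphor.
* Flat-field and IRI are dark-corrected, scaled to ROI mean 1 before
  division, and the result is rescaled to preserve the image's ROI mean:
  corrections change shape, never scale.
* The median kernel default is 3×3 — the smallest kernel that removes
  single-pixel outliers without blurring a 0.88 mm edge sampled at
  0.1 mm/px. Because the median is nonlinear it does not commute exactly
  with the IRI division when the granularity is rough at pixel scale; on
  noise-free frames this leaves residuals below 2% of maximum at the
  default pitch (below 0.5% without granularity), concentrated in the
  penumbra. It is exactly linear under global dose rescaling.
* IRI division is guarded against double application and against
  image/IRI centre mismatch above 2 px; the simulated IRI shares each
  foil's placement, as the physical foil does between its two readouts.

## Reconstruction and calibration

Slices are translated to the stack-mean ROI centre with bilinear
resampling (an exact integer fast path keeps already-aligned slices
bit-identical); validity masks propagate conservatively (a resampled pixel
is valid only if all contributors are valid); slices whose detected radius
deviates >10% from the median are rejected. No depth interpolation happens
at assembly — the grid holds one measured plane per foil, and
interpolation is deferred to metric extraction.

Calibration factors `k_i = D_ref(z_i) / S_foil(z_i)` (both series
max-normalised; the absolute scale is unrecoverable and irrelevant after
renormalisation) are fitted with a cubic smoothing spline whose smoothing
parameter is chosen by leave-one-out cross-validation on a geometric grid
that includes the interpolating limit. For the default conditions the CV
selects (near-)interpolation: the sharp distal rise of `k` carries more
structure than the 0.5% point noise, and smoothing it away costs more CV
error than interpolating the noise. Outside the measured depth range the
curve extrapolates as a constant — a ratio of two vanishing signals beyond
the range is not extrapolable — and the correction is applied slice-wise,
then the grid is renormalised under its recorded mode.

The clamped extrapolation leaves the last ~1 mm of the SOBP distal edge
slightly under-corrected, which sharpens the recovered fall-off by up to
~0.1 mm at default settings; this is the known cost of transferring a
pristine-beam calibration that ends near the range.

## Metrics

The central depth profile averages valid voxels in a 2 mm square window
around the field centroid (a single-column profile of foil data is
needlessly jittery; the window is configurable and recorded). SOBP levels
are relative to the plateau estimate — the iterated median between the
proximal and distal 90% crossings, replaced by the fitted erf-edge
amplitude when the two agree within 5% (the median is robust against the
ramp shoulder; the amplitude is the plateau the distal edge actually
sees). The distal edge is refined by fitting `A·Φ((R50 − z)/σ)` to the
distal segment whenever it holds ≥4 points with ≥2 strictly between 2%
and 98% of the plateau; with exact sampling this reproduces R90,
modulation and Δ to <1e-3 mm, and at the 0.570 mm foil pitch it recovers
R90 to ~0.05 mm and Δ to ~0.1 mm under default noise. Isodose contours
use marching squares with linear edge interpolation, in mm.

Grid comparisons require both grids to carry the same recorded
normalization mode. Under global-maximum normalization the single hottest
voxel of a noisy grid is extreme-value biased high by ~2–2.5% (maximum
over ~3·10⁴ effectively independent plateau voxels of ~0.5% residual
noise), so all normalized measured values sit correspondingly low; the
mean absolute lateral difference against ground truth inside the 50%
field area is 2–4% across seeds, of which the scale bias is the dominant
part. Scale-invariant quantities (all SOBP metrics, plateau flatness,
RMS *improvement*) are unaffected.

## Validation scale and what it shows

The test suite and the acceptance script run the identical code paths at
the full stack size (40 foils, 256×256 px frames): five seeds for the
recovery/improvement checks, three sub-seeded repeats in the acceptance
script, chosen to keep a full run in tens of seconds while averaging the
per-seed scatter. Smaller 96×96 scenes with the same physics back the
unit tests.

Passing these tests shows the chain is algebraically correct, that the
corrections remove the nuisances the generator injects, and that beam
metrics survive coarse depth sampling, noise and quenching. It does not
validate against real CCD data: lens distortion, dark-current drift with
exposure, bad pixels, stray light, spectral effects and true proton LET
spectra are all outside the generator (and the correction chain
deliberately has no modules for them). Agreement with a clinical
treatment-planning system is emulated by the synthetic ground-truth grid,
not reproduced.

## Known limitations

* The quench correction is a pure function of depth; any lateral LET
  variation (field edges, heterogeneities) is uncorrectable by design.
* `per_slice_max` normalization is undefined for slices without signal
  (deep beyond the range) and errors there.
* Registration is translation-only; rotations are not modelled or
  corrected.
* The gamma index and DVH statistics are deliberately out of scope; the
  comparison report covers profiles, widths and isodoses.
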