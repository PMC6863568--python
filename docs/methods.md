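# Methods

`polirkit` models the complete measurement chain of a low-cost camera-gantry
imaging robot for analytical microbiology — the class of instrument built
from CoreXY 3D-printer hardware with a Raspberry Pi camera — so that scan
planning, image formation and kinetic analysis can be developed and
validated entirely in software. This note records the models, their
assumptions, the shipped parameter values and the choices made where the
design was genuinely open.

## Deck, scanning and G-code

The deck is the gantry's x/y/z travel envelope (420 × 300 × 130 mm by
default), with the origin at the front-left home position, +x right, +y
back, absolute millimetre coordinates. Tiling distributes camera fields of
view evenly between the span's two ends, so adjacent tiles overlap by *at
least* the requested fraction; tiles are visited in serpentine row order to
minimise travel. Time-lapse cycles are anchored to ideal start times
t = k·interval; if one cycle's moves plus a configurable per-tile overhead
(default 2 s) cannot fit in the interval, planning fails loudly rather than
letting cycle starts drift.

The G-code dialect is deliberately minimal: `G21`/`G90` header, `G28`
homing per policy, `G0 X Y Z F` moves, `G4 S` settle dwells, and one
`;SNAP tile=<i> cycle=<c>` marker plus a configurable raw trigger command
(default `M118 SNAP <i> <c>`) per acquisition — real controllers differ in
how a camera is triggered, so the raw command is a template. A
`;POLIRKIT interval_min=` comment makes the program self-describing enough
to round-trip: `parse(emit(plan))` reproduces poses, order, dwells, homing
events and trigger count, and `emit∘parse∘emit` is byte-identical.

Capacity arithmetic is bookkeeping, not geometry: samples = placements ×
sites × subsites (10 capillaries per microcapillary-film strip, 1 per
well). The greedy packing estimator (axis-aligned grid, optional global 90°
rotation, margin on all sides) is flagged as an estimate; published device
counts are accepted as inputs because holder footprints vary.

## Optics and stage error

The default camera is a 3280 × 2464 sensor with a 96.5 × 72.5 mm field of
view at 80 mm working distance: 29.42 µm/pixel (reported rounded to 29).
Defocus is a flat-then-linear Gaussian PSF: σ(z) = σ_min inside the 10 mm
depth of focus, growing at `blur_slope` (0.3 px/mm) outside. σ_min = 1.28 px
was calibrated (scripts/calibrate.py) so a rendered three-bar target
resolves exactly 8 lp/mm in focus under the 0.1 Michelson-contrast
criterion — the physical instrument's measured resolution limit, equivalent
to a 62 µm line width (floored from 62.5; the integer convention is
declared, not inferred).

Stage repeatability is zero-mean Gaussian per axis, independent in x and y —
the minimal model consistent with per-axis mean-absolute-deviation (MAD)
summaries and roughly isotropic scatter. Calibration uses the closed form
E|X| = σ√(2/π): homed-once runs ship with MAD (20, 26) µm, homing every
cycle with (35, 29) µm. "Within 100 µm" is computed as Euclidean distance
from the 2-D mean; with the shipped calibration ≈99.7% of draws fall inside,
comfortably above the 98% benchmark. Sensor noise (Poisson shot + Gaussian
read) defaults off so renders are bit-reproducible unless noise is asked
for.

## Growth and resazurin kinetics

Growth is a lagged logistic: N(t) = N0 through the lag, then
K / (1 + (K/N0 − 1)e^(−r(t−lag))) with r = ln2/t_d. Defaults: inoculum
5×10⁵ CFU/mL (standard susceptibility-testing practice), lag 60 min,
K = 10⁹ CFU/mL. Shipped packs: the E. coli ATCC 25922 reference strain
(t_d = 16 min) and a slow, ampicillin-resistant Klebsiella mastitis isolate
(t_d = 49 min).

Dye chemistry is the minimal first-order per-cell scheme that reproduces
blue → pink → colourless and a transient fluorescence peak:

    dR/dt = −(k1·N·m_f + k0·milk)·R
    dF/dt =  (k1·N·m_f + k0·milk)·R − k2·N·m_f·F
    dD/dt =  k2·N·m_f·F

with R resazurin, F resorufin, D dihydroresorufin and m_f the metabolically
active fraction. R+F+D is conserved exactly (the right-hand side sums to
zero; the fixed-step RK4 integrator at ≤1 min steps preserves it to rounding,
and traces enforce 10⁻⁶·R0). k1 = 6.5×10⁻¹² mL·CFU⁻¹·min⁻¹ was chosen so the
reference pack is ~5% converted when growth saturates — this puts
colorimetric detection in the late exponential phase and completes
conversion overnight (99% by 16 h); k2 = k1/10 gives a resorufin peak near
77% of the dye load followed by a visible decay (the transient signal that
makes endpoint reads unreliable). Rate constants for these conditions are
not published; only relative/qualitative behaviour is validated.

Antibiotic exposure multiplies the growth rate *and* the metabolic fraction
by (1 − effect), effect = base_effect·(1 − matrix_inactivation·milk).
Bactericidal suppression of metabolism matters: a merely growth-arrested
inoculum would still reduce dye fast enough to cross the sensitive
fluorescence threshold within a screening window. With the defaults, clean
broth gives complete suppression (flat N, no conversion) and milk fractions
≥0.5 restore enough growth to flip a susceptible isolate to apparent
resistance — the reason raw milk samples must be diluted at least 1:10
before testing.

Milk acts three ways, each with its own coefficient: background dye
conversion (k0 = 2×10⁻⁵ min⁻¹ per unit milk fraction — slow, cell-free),
optical scattering, and antibiotic inactivation (default complete at 100%
milk).

## Optical signals

Per-channel extinction coefficients are derived from fixed transmitted-
colour endpoints — resazurin blue (60, 80, 190) and resorufin pink
(230, 105, 160) at 250 µg/mL through 1 mm — so Beer–Lambert absorbance
A_c = (ε_cR·R + ε_cF·F)·l reproduces those colours at the reference
condition and scales correctly with pathlength: the 206 µm capillary lumen
is visibly paler than a ~3 mm microtitre well for identical chemistry.
Scattering is a turbid veil: transmittance T_c = (1−w)e^(−A_c) + w with
w = 1 − exp(−c·milk·l), c = 0.4 mm⁻¹. At milk = 0 this is exact
Beer–Lambert; as milk rises every channel is compressed toward zero
apparent absorbance, shrinking the blue-to-pink index range the way an
opaque milky sample washes out. The colour index B = A_blue − A_red is this
package's definition of "absorbance" for an RGB camera (the field has no
standard one). Fluorescence is I = g·(F + φ·R)·e^(−a·milk) with φ = 0.001
(resazurin is weakly fluorescent), giving the non-zero baseline that
relative detection normalises against.

## Detection rules and estimators

Colorimetric positivity: baseline = first 3 frames; threshold = baseline
mean + max(5 × baseline SD, 5% of the series' dynamic range); a series
whose total range is below an optional absolute floor (`min_range`,
default off; milk workflows use 5% of the clear-broth full-conversion
swing) is never called positive — this keeps slow matrix-only conversion
from registering as growth. Fluorescence positivity: a 38% relative
increase over baseline, calibrated once (scripts/calibrate.py) so that
fluorescence detection leads colorimetric detection by 2.0 h on the
reference scenario. Times-to-positivity are linearly interpolated between
the bracketing frames.

Doubling times come from the serial-dilution identity: each ten-fold
dilution delays TTP by log₂10 ≈ 3.32 doublings, so t_d = slope of TTP vs
dilution index (decades) / log₂10, with the standard error propagated from
the regression; fewer than three detected dilutions, or a non-positive
slope, yields "nd". The estimator recovers the shipped 16 min and 49 min
truths within ~3% noiselessly and within 10% at the default 2% multiplicative
intensity noise. Susceptibility is binary growth/no-growth per lane (one
drug concentration per capillary): nd if no control lane grew, else R if
any drug lane grew.

Registration is per-tile rigid translation by normalized cross-correlation
of a geometry-derived template against the frame (on absolute deviation
from the median, so one template serves dark colorimetric and bright
fluorescent sites), refined by a parabolic peak fit; the ±150 µm search
radius is several times the jitter's P99. Rotation and scale are not
fitted — measured jitter is a few pixels at most. Colony counting uses
three-class Otsu (backlit surround / agar / stained colonies) with a
minimum-area filter and border exclusion; motility measures the radius at
which the radially averaged stain profile falls to half its central
elevation, and flags motility when the fitted radial speed exceeds
0.1 mm/h.

## What the simulator does and does not emulate

Rendered stacks reproduce geometry at the native pixel pitch (a 206 µm
lumen spans 7 px), defocus blur, per-acquisition stage jitter drawn from
the homing-policy calibration, optional sensor noise, and signal photometry
affine in the underlying kinetics. They do not attempt photorealism:
no lens distortion or vignetting, no Bayer demosaicing, no 3-D agar
translucency, no condensation, uniform backlight, fixed colour endpoints.
Passing loop-closure tests therefore demonstrates that the analysis
pipeline is correct *given this image-formation model* and calibrated
kinetics — not that it would survive every artefact of real micrographs.
Likewise the wet-lab magnitudes (real milk absorbance curves, strain
metabolism differences) are represented only qualitatively.

## Problem sizes and numerics

Tests and the reproduction script run at desk scale by design: miniature
sensors (e.g. 328 × 248) at the *native* pixel pitch so geometry and
registration behave identically to full frames; 10⁴ draws for positional
statistics; 1 min RK4 steps (relative error vs the closed form ≤10⁻⁴);
dilution series of four ten-fold steps at 30 min frame intervals. Rendering
supersamples geometry 2× (4× for bar targets) before box-downsampling, so
edge coverage is area-correct and deterministic. Seeds propagate from a
single master seed through `numpy` SeedSequence spawning; identical
(config, seed) pairs produce bit-identical stacks and artifacts.

## Known limitations

- The packing estimator cannot be validated against published device
  counts (holder footprints are not specified); those counts enter as
  inputs.
- Detection-rule constants and milk coefficients are design choices
  validated against qualitative behaviour, not fitted to data.
- The fluorescence excitation path is not modelled; the fluorescence
  channel is a proxy for a filtered monochrome view.
- `parse_gcode` round-trips the dialect emitted here; foreign G-code is
  preserved but only partially interpreted (moves, dwells, homing).
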