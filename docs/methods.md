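# Methods

## Optical model

The instrument is modelled as a paraxial thin-lens train: specimen plane →
free space $x_1$ → lens I ($F_1$) → free space $d$ → lens II ($F_2$) → free
space $x_2$ → image plane. The system ray-transfer matrix is the literal
product of the five translation/lens factors, so the unit-determinant
invariant holds by construction and the closed-form element expressions used
elsewhere can be cross-checked against it. Imaging requires the $B$ element
to vanish, which yields a Möbius (rational-linear) map $x_1 \mapsto x_2$;
composing it with the tilted-sensor projection gives the depth-to-column map
$c(x_1)$.

Assumptions and scope:

* thin lenses, paraxial rays; no aberrations, pupils, diffraction or
  thick-lens effects;
* the sensor's nominal centre column corresponds to an image plane at the
  rear focus of lens II;
* the tilt enters only through $\cos(\text{tilt})$; 45° is the validated
  prototype geometry, other angles are a geometric extrapolation.

Because the map is rational-linear, its inverse (`specimen_from_column`) is
computed in closed form for **any** lens separation rather than by bracketed
root-finding; the two poles of the map are detected explicitly and raised as
degenerate/no-solution errors. Sensitivity $dc/dx_1$ is analytic (quotient
rule on the Möbius map); tests verify it against a central finite difference
at $10^{-4}$ mm to 0.1% relative.

At the telecentric separation $d = F_1 + F_2$ everything collapses to
affine: $x_2 = F_2 + F_2^2/F_1 - (F_2/F_1)^2 x_1$, constant magnification
$-F_2/F_1$, constant sensitivity
$-(F_2/F_1)^2 N_c / (W \cos 45^\circ) \approx -201.13$ px/mm for the
prototype. The sensor-visible specimen range is then
$N_c / |dc/dx_1| \approx 6.36$ mm (reported as 6.4 mm at one decimal), i.e.
about 5 µm of axial travel per column.

## Synthetic scenes

The renderer emulates what the tilted sensor actually sees, as a sum of
three components:

1. **Stripe texture** — a sine grating along columns (default period 8 px)
   whose phase advances 0.05 cycle per row. A grating is used rather than a
   literal specimen image because only the spatial-frequency content matters
   to the estimator; the row-wise phase skew makes the per-row integer peaks
   sample different grating phases, which is what lets the row average
   resolve the stripe to a fraction of a pixel (the same role the pixel
   mosaic of a real specimen plays). The defaults put the dominant spectral
   energy at radius $\sqrt{(1280/8)^2 + (720 \cdot 0.05)^2} \approx 164$
   frequency px — mid-way through the filter passband — and an integer
   number of phase-skew cycles over 720 rows, so column means are unbiased.
2. **Defocus envelope** — full contrast within ±4 px of the true stripe
   column, elsewhere attenuated by the exact factor a Gaussian blur applies
   to a sinusoid, $\exp(-2\pi^2\sigma^2/T^2)$, with $\sigma$ growing
   linearly with distance from the stripe (0.08 σ-px per px by default).
   Linear growth is the simplest monotone blur law consistent with gradual
   defocus; no point-spread measurement exists to fit anything richer.
3. **Baseline + noise** — a degree-≤2 polynomial illumination field plus a
   broad Gaussian blob (default ≈12 grey levels of drift on a 90-level
   pedestal) and additive Gaussian read noise (sd 2 grey levels; a Poisson
   mode exists but is off by default since no sensor noise model was
   measured). Baseline-drift amplitude is kept small relative to the stripe
   (contrast 80) so that, as required of the default scene, ≥80% of a
   noiseless frame's non-DC spectral energy falls in the 20–300 px annulus;
   the bandpass removes far larger drifts regardless (tested up to 50 grey
   levels).

What the generator does **not** emulate: real tissue texture statistics,
magnification change with depth (the estimator ignores magnification, and the
telecentric prototype has none), photobleaching, vignetting dynamics, or
camera readout artefacts. Passing tests therefore demonstrate the pipeline's
correctness and noise/baseline robustness under controlled conditions, not
performance on any particular tissue.

Determinism: every stochastic element draws from one `numpy` Generator
seeded from the scene seed; identical configurations give bit-identical
stacks.

## Bandpass filter

The mask is radial: $T(r) = (1 - G_{lo}(r))\,G_{hi}(r)$ with $G_{lo}$ a
Gaussian of width $r_{low}(1+\text{rolloff})$ (so DC transmission is exactly
zero) and $G_{hi}$ flat to $r_{high}$ then falling as a Gaussian of width
$r_{high}\cdot\text{rolloff}$. Defaults $r_{low}=20$, $r_{high}=300$,
rolloff 0.1 come from the measured spectral split between baseline and
stripe. The exact edge profile is a documented implementation constant —
what is contracted (and tested) is band-interior/exterior behaviour: DC
blocked below 1%, ≥99% transmission at radius 160, closed again beyond the
outer edge. Transmission follows the standard convention (1 = pass).
Frames are transformed at their native size (no padding); the smooth mask
makes wrap-around effects negligible away from a ~20 px margin, and tests
compare interiors. Colour input is collapsed to Rec. 601 luminance before
filtering.

## Stripe localization

Per frame: bandpass → subtract each row's mean (median available) → take the
column of each row's largest **absolute** value (the filtered stripe
oscillates symmetrically about zero, so a signed max would bias toward
bright half-cycles; exact ties resolve to the lowest column) → average the
surviving rows' columns. No sub-pixel refinement of individual rows is done;
fractional precision comes from averaging hundreds of integer peaks. A row
quality gate (`amp_threshold`, default 0 = inert; `min_rows`, default 50)
guards against stripe-free frames — `threshold_from_blank` derives the
3×-median-peak threshold from a blank calibration frame when one is
available. Invalid frames become missing (NaN) trace entries, never silently
interpolated.

## Calibration and motion analysis

Column is regressed on stage displacement (ordinary least squares), matching
how the instrument is calibrated, and the line is inverted analytically for
conversion; `±` values are 1× standard error (two-point tables warn and
report 0). The *indication error* is the worst |inverse-predicted − true|
displacement over the calibration table itself. The synthetic calibration
run mirrors the physical protocol: start with the stripe one column inside
the right sensor edge, step the specimen 0.5 mm at a time, stop when the
stripe leaves the sensor.

Trace amplitude is **peak-to-peak** (quantile span with q = 0.01 by default
to shrug off tracking glitches; q = 0 is strict max−min). Dominant frequency
is the largest non-DC periodogram peak of the mean-subtracted trace, no
window by default (short physiological traces), reported with its bin width
`frame_rate / n`. Missing samples are linearly interpolated (with a warning)
before the periodogram only.

## Problem sizes and numerical choices

Synthetic validation uses full-width frames (1280 columns) at the native 720
rows for end-to-end checks and reduced row counts (96–240) where only the
column axis matters; sequence tests use 300 frames (10 s at 30 fps), and
Monte-Carlo calibration uses 200 replicates of 13-point staircases. Affinity
and constancy claims at the 4f separation are verified on 1000-point grids
at 10⁻⁶ relative tolerance; the imaging condition is checked to 10⁻⁹ of the
matrix scale. Stochastic guarantees are asserted as seeded fractions
(e.g. ≥90% of replicates within the instrument's single-run bounds) rather
than over every random draw.

## Known limitations

* Only the 45° tilt is validated against the physical prototype.
* The filter edge profile is a modelling choice; it is not a bit-for-bit
  reproduction of any specific plugin's mask.
* The renderer's texture is a stand-in; its period is a free parameter, not
  a measured tissue property.
* Frequencies at or above half the frame rate alias (a warning is emitted);
  30 fps covers respiration (~1–2 Hz) but not a rat's heartbeat (5–10 Hz).
* Off-telecentric configurations use the same linear calibration model;
  strong nonlinearity (large $d - F_1 - F_2$) would need a richer model that
  is deliberately out of scope.
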