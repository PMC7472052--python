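# stripescope

Tilted-sensor depth-from-focus stripe tracking: a compact image-based way to
measure the **longitudinal (Z) motion of living tissue** with a single camera.

Intravital fluorescence microscopy of a beating, breathing animal needs active
motion compensation, and that needs a fast, small displacement sensor. One
elegant option: take an ordinary two-lens wide-field fluorescence train and
tilt the image sensor 45° to the optical axis. The sensor then intersects the
image plane along a narrow **in-focus stripe**, and because the image-plane
position depends on specimen depth, the *column* of that stripe encodes the
specimen's axial position. Tissue moving up and down reads out as a stripe
moving left and right at full camera frame rate.

`stripescope` implements the complete measurement chain in software:

| module | what it does |
|---|---|
| `stripescope.optics` | paraxial ABCD (ray-transfer-matrix) model: image distance, magnification, depth→column map, sensitivity |
| `stripescope.synth` | seeded synthetic frame renderer (stripe + baseline drift + noise) with ground truth |
| `stripescope.filtering` | FFT Gaussian annular bandpass that removes baseline drift |
| `stripescope.stripe` | per-row peak-value stripe localization and stack tracking |
| `stripescope.calibration` | linear column-vs-displacement calibration (`y = ax + b`), indication error |
| `stripescope.motion` | trace analysis: peak-to-peak amplitude, dominant frequency, px→mm conversion |
| `stripescope.io` / `stripescope.cli` | TIFF/CSV/JSON/YAML I/O and the `stripescope` command line |

## The model in brief

With lenses of focal length $F_1, F_2$ separated by $d$, a specimen plane at
$x_1$ images to a plane at

$$x_2 = \frac{d x_1 F_2 - d F_1 F_2 - x_1 F_1 F_2}{F_1 F_2 - x_1 F_2 - x_1 F_1 - d F_1 + d x_1},$$

the condition that the $B$ element of the system matrix
$T(x_2)L(F_2)T(d)L(F_1)T(x_1)$ vanishes; the $A$ element is then the
magnification $M$. A sensor of width $W$ and $N_c$ columns tilted 45° about
the rear focus of lens II sees the stripe at column

$$c = \frac{x_2 - F_2 + W\cos 45^\circ/2}{\cos 45^\circ}\,\frac{N_c}{W}.$$

At the telecentric (4f) separation $d = F_1 + F_2$ the map $c(x_1)$ is exactly
affine and $M$ is constant. For the prototype geometry ($F_1=45$ mm,
$F_2=18$ mm, $d=63$ mm, $W=1.44$ mm, $N_c=1280$) the sensitivity is
$dc/dx_1 \approx -201$ px/mm, the measurement range 6.4 mm and the per-column
resolution 5 µm. Frames are cleaned with an annular Gaussian bandpass
(passband radii 20–300 frequency px) that blocks the low-frequency baseline
drift; the stripe is localized as the mean over rows of each row's
largest-|value| column; calibration fits column against stage displacement
and inverts the line to convert traces to millimetres.

## Worked example

```python
import numpy as np
from stripescope import optics, synth, filtering, stripe, calibration, motion

cfg = optics.PROTOTYPE                       # 45/18 mm lenses, 4f, 1280-col sensor

# 1. model predictions
optics.sensitivity(cfg, 45.0)                # -201.13 px/mm
optics.measurement_range(cfg)                # (41.818, 48.182, 6.364) mm

# 2. synthetic stage-staircase calibration (13 steps of 0.5 mm)
scene = synth.SceneConfig(seed=7)
table = calibration.simulate_calibration_run(cfg, scene, n_steps=13, step_mm=0.5)
fit = calibration.fit_calibration(table)

# 3. track a 1 Hz, 290 px peak-to-peak motion sequence end to end
wf = synth.make_waveform("sine", duration_s=10.0, frame_rate=30.0,
                         amplitude_mm=synth.amplitude_for_column_span(cfg, 290.0))
stack, truth = synth.render_sequence(cfg, scene, wf)
mask = filtering.build_mask(stack.shape[1:])
trace = stripe.track_stack(stack, mask, frame_rate=30.0)
report = motion.summarize(trace, fit)
```

Output of the accompanying script (printed values, same seed):

```
sensitivity dc/dx1 : -201.13 px/mm
measurement range  : x1 in [41.818, 48.182] mm (span 6.364 mm)
resolution         : 5.0 um/column
calibration fit    : a = -200.89 +/- 0.13 px/mm, b = 1278.00 +/- 0.45 px
pearson r          : -1.00000
max indication err : 11.8 um
tracked amplitude  : 289.0 px = 1.44 mm
dominant frequency : 1.0 Hz (resolution 0.1 Hz)
```

Reading it: the fitted calibration slope (−200.9 px/mm) recovers the model
sensitivity; the worst disagreement between stage displacement and what the
fitted sensor indicates is ~12 µm over the 6 mm staircase; and a rendered
1 Hz / 290 px motion is tracked back to within a fraction of a pixel, i.e.
1.44 mm of axial travel at this configuration's slope.

The same pipeline is available from the shell:

```bash
stripescope sweep --x1-min 41.8 --x1-max 48.2 --n-points 101 --out sweep.csv
stripescope simulate --waveform sine --freq 1 --amp-px 290 --duration 10 \
                     --seed 7 --out stack.tif
stripescope track --in stack.tif --fps 30 --out trace.csv
stripescope calibrate --table table.csv --out fit.json
stripescope convert --trace trace.csv --fit fit.json --out trace_mm.csv
stripescope analyze --trace trace_mm.csv --fit fit.json --out report.json
```

Conventions: 0-based indexing everywhere; column 0 is the leftmost sensor
column; the stripe column is a continuous coordinate (pixel *k* spans
[k, k+1)); all lengths are mm internally; `±` values on fits are 1× standard
error.

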