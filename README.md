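# pupilshift

Quantification and correction of the **pupil size artifact (PSA)** in
video-based eye tracking.

Video-based eye trackers locate gaze from the pupil center (usually
relative to a corneal reflection). Because the pupil does not dilate and
constrict perfectly concentrically, changes in pupil diameter shift the
*reported* gaze position even when the eye does not rotate. These apparent
gaze shifts can reach 1–2° as the pupil moves through its physiological
2–6 mm range — several characters of text horizontally, and most of a line
vertically, in a typical reading experiment. The artifact is idiosyncratic
(it differs between observers and eyes), spatially structured (horizontal
shifts follow a contralateral pattern; vertical shifts grow toward the
bottom of the screen and with pupil size), and invisible to ordinary
accuracy checks done at a single pupil size.

`pupilshift` is for vision scientists and reading researchers who want to
measure this artifact in their own setup and remove it from their data.

## The method

**Quantification.** Observers fixate known targets while background
luminance switches drive the pupillary light reflex, sweeping pupil
diameter across its range. The offset between measured gaze and target —
the apparent gaze shift — is smoothed against pupil diameter with LOWESS
(degree-1 local fits, tricube weights, adaptive span holding a constant
1-mm pupil window), normalized to zero at 3 mm. The **PSA slope** (deg/mm)
over a pupil range is the chord slope of this curve; the expected shift
for a pupil change Δp is |slope| × |Δp|.

**Recalibration.** A two-stage model maps (true position, pupil) to the
apparent shift:

1. per calibration target, OLS quadratics
   dx(p) = a₀ + a₁p + a₂p², dy(p) = b₀ + b₁p + b₂p²;
2. each of the six coefficients is fitted as a 2-D quadratic surface over
   screen position, interpolating the artifact continuously.

Because a measured sample only gives the *shifted* position, the forward
model is inverted through a dense 3-D lookup table (0.1° spatial,
0.1 mm pupil steps): each true-grid node's offset is stored at the
measured-space node nearest to `true + offset`; collisions keep the
smallest offset, holes are nearest-neighbor filled, and out-of-domain
queries extrapolate by nearest neighbor. Correction subtracts the stored
offset. Models are fitted per eye and evaluated on a held-out validation
target grid using pupil-binned median gaze positions (absolute offset to
target, and 68% bivariate contour ellipse area across bins).

The package also provides standard data-quality metrics (windowed RMS-S2S
precision, data loss), a pupillometric blink pipeline (±20% moving-window
detection, slope-scan margin refinement, 100-ms episode merging), reading
comparisons against nearest-line ("attach") assignment, and a synthetic
data generator with a parametric ground-truth artifact field for
end-to-end testing.

## Worked example

```python
import numpy as np
import pupilshift as ps

# simulate a calibration and a validation PLR phase for one eye
field = ps.make_field(seed=11, eye="left", magnitude=0.4, noise_sd=0.1)
calib, calib_epochs, _ = ps.simulate_plr_phase(field, ps.CALIBRATION_GRID, seed=21)
valid, valid_epochs, _ = ps.simulate_plr_phase(field, ps.VALIDATION_GRID, seed=22)

# fit the two-stage model and evaluate on the held-out grid
model = ps.fit_psa_model(calib, ps.CALIBRATION_GRID, calib_epochs)
result = ps.validate_model(model, valid, ps.VALIDATION_GRID, valid_epochs)

print(f"median absolute offset: {np.nanmedian(result.offset_before):.2f} deg "
      f"-> {np.nanmedian(result.offset_after):.2f} deg")
print(f"median offset reduction: {100*np.nanmedian(result.offset_reductions):.1f}%")
print(f"median BCEA reduction:   {100*np.nanmedian(result.bcea_reductions):.1f}%")

series = ps.compute_offsets(calib, ps.CALIBRATION_GRID, calib_epochs)[4]
curve_x, _ = ps.lowess_adaptive(series)
slope = ps.psa_slope(curve_x, ps.pupil_range_95(series.pupil))
shift = ps.shift_estimate(slope, 1.0)
chars, lines = ps.unit_conversion_report(shift)
print(f"horizontal PSA slope at screen center: {slope:.2f} deg/mm")
print(f"apparent shift for a 1-mm pupil change: {shift:.2f} deg "
      f"(~{chars:.1f} characters, ~{lines:.2f} lines)")
```

Output:

```
median absolute offset: 2.14 deg -> 0.03 deg
median offset reduction: 98.9%
median BCEA reduction:   95.0%
horizontal PSA slope at screen center: 0.46 deg/mm
apparent shift for a 1-mm pupil change: 0.46 deg (~2.9 characters, ~0.37 lines)
```

The simulated artifact (0.4 deg/mm, pupil swinging 2–6 mm) displaces gaze
by ~2° before correction; after recalibration the residual error is at the
level of the lookup grid and the fixation noise. The PSA slope at the
central target translates a 1-mm pupil fluctuation — typical within a
constant-luminance reading session — into roughly three characters of
horizontal error in a 0.16°/character layout.

A command-line interface mirrors the library
(`pupilshift convert | preprocess | quality | fit | correct | validate |
simulate | compare`); run `pupilshift --help`.

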