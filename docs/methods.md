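# Methods

## Coordinate and unit conventions

Gaze is expressed in degrees of visual angle relative to the screen
center, using a per-axis tangent mapping (`deg = atan(cm / d)`) that
assumes a flat screen viewed perpendicularly at fixed distance `d`. This
is exact under that geometry; a small-angle linearized mapping is
available behind a flag for comparison with pipelines that assume it. The
y axis is positive **downward** (screen convention), so "bottom of the
screen" means larger y; tests enforce this. Pupil diameter is in mm,
recovered from tracker-reported area as `scale · sqrt(area)` — the disc
model implied by dot-calibration recordings — with `scale` fitted through
the origin by least squares. Missing samples carry NaN plus a false
validity flag, never zeros.

## Blink pipeline

Blinks appear as data loss flanked by artifactual ramps where the eyelid
partially occludes the pupil. Detection flags (a) all data-loss gaps and
(b) samples whose pupil deviates more than ±20% from a centered 60-s
moving average computed over valid samples only. At stream edges the
window is truncated rather than padded (padding would fabricate data);
streams shorter than the window fall back to the whole-stream average.
Margins are then refined by a slope scan on a 10-ms boxcar-smoothed first
difference: an interval grows outward while the signal is still falling
into, or recovering from, the blink (|diff| > 0.002 mm/sample), at most
200 ms per side. These two numbers are this package's documented defaults
for the refinement step, which the literature specifies only by reference
to noise-based reconstruction algorithms; both are overridable. Episodes
closer than 100 ms are merged. Intervals are half-open `[onset, offset)`
ms so that stages compose without double counting; the refine and merge
stages can only grow total flagged time, never unmark a gap.

The detector's operating characteristics are validated on simulated
streams with injected blinks under modest pupil variation (≈±10% around
the mean). Under extreme pupillary-light-reflex sweeps (2–6 mm) the ±20%
rule also flags genuine luminance-driven excursions relative to the 60-s
local mean; in the end-to-end benchmark blinks are therefore handled as
the data-loss gaps they create (skipped by all downstream estimators),
and the deviation rule is characterized separately where its assumptions
hold.

## Quality metrics

RMS-S2S uses 100-ms windows sliding by one sample; windows containing any
missing sample are skipped, not shortened, and the median across windows
is reported (robust to residual artifacts; the mean is available). For
iid Gaussian position noise with per-axis SD σ the statistic converges to
2σ, which the tests exploit. BCEA uses `2kπσxσy√(1−ρ²)` with
`k = −ln(1−P)` for coverage P (0.68 by default); numerically collinear
point sets (1−ρ² < 1e-12) return exactly 0. Data loss is missing over
expected samples given rate and span.

## Artifact quantification

Apparent gaze shift is the offset between measured gaze and the fixated
target, taken per sample (the artifact acts on sample timescales, not
only at fixation level). LOWESS smoothing uses degree-1 local fits with
tricube weights and an adaptive span holding a constant 1-mm pupil
window (±0.5 mm around each evaluation point, clipped at the data range,
50 evaluation points); no robustness iterations. Degree-1 locality
guarantees exact reproduction of a linear artifact, which anchors the
tests. Curves are normalized to zero at 3 mm so recordings are comparable
regardless of the pupil size at initial tracker calibration; a reference
outside the curve support uses the nearest endpoint. The mean slope over
a pupil range is the chord slope of the smoothed curve (identical to the
average local derivative); a zero-width range falls back to the local
finite difference. Pupil ranges are 2.5th–97.5th percentile spans ("95%
range"). Pupil-binned medians (0.1-mm bins spanning the 95% range)
equalize the contribution of unevenly visited pupil sizes.

## Recalibration model

Stage 1 fits, per calibration target and axis, OLS quadratics of offset
on pupil diameter — the smallest family that captures the observed
acceleration of vertical slopes with pupil size. Stage 2 fits each of
the six local coefficients as a 2-D polynomial over screen position,
default full quadratic (6 terms against 9 targets, leaving 3 residual
degrees of freedom per coefficient). The degree is configurable; the
quadratic is the smallest smooth family able to express the contralateral
horizontal gradient and the vertical bottom-of-screen gradient without
interpolating target noise exactly.

The inverse problem — a measured sample contains the unknown offset — is
solved by a dense lookup table: for every (true x, true y, pupil) node
(0.1° and 0.1 mm steps over the calibration grid plus a 2° margin and the
observed pupil span) the forward offset is computed and stored at the
measured-space node nearest to `true + offset`. Collisions (several true
nodes mapping to one measured node, possible where the field folds) keep
the smallest-|offset| entry — the most conservative correction; holes are
filled from the nearest populated node per pupil slice. Both rules are
recorded in the model metadata. Queries outside the domain, in space or
pupil, use the nearest in-domain node (nearest-neighbor extrapolation),
so a correction can never exceed the largest stored offset. Pupil values
are clamped to the observed support before evaluating the quadratics, to
avoid polynomial blow-up outside the calibrated range. Construction is
fully deterministic; model files store surfaces, domain and
configuration as versioned JSON, and the table is rebuilt on load.

Models are per eye. Validation must use a target grid with role
`validation`, disjoint from and interior to the calibration grid, so the
evaluation probes spatial interpolation at unseen positions rather than
memorization; the harness raises on a role mismatch. Accuracy is the
median over pupil bins of the Euclidean distance from the per-bin median
position to the target; dispersion is the 68% BCEA across per-bin
medians; reductions are `1 − after/before`, undefined (NaN) when the
before value is zero.

## Synthetic data

The generator defines the study conditions under which everything is
tested. The ground-truth artifact field uses the same
surface-coefficient family as the model (quadratic in position, quadratic
in pupil), so noiseless two-stage recovery is exact by construction and
testable to 1e-6. Fields are built with the qualitative structure seen in
real recordings — contralateral horizontal slope gradient, vertical slope
positive, growing toward the screen bottom and with pupil size, small
random baseline offsets — at a configurable magnitude (default
0.4 deg/mm, matching reported median horizontal slopes).

PLR phases use two 9-target grids (calibration ±13.5°/±6.4°, validation
±11.9°/±4.8°), visited left→right, top→bottom, each with 2 s white and
8 s black stable-fixation windows separated by 1-s pulsing gaps (excluded
from epochs), at 1000 Hz. The pupil relaxes exponentially toward
luminance asymptotes (defaults 2 mm bright / 6 mm dark) with
τ_constrict = 0.4 s and τ_dilate = 2.0 s — values inside physiological
ranges expressing that constriction is faster than dilation — plus slow
Ornstein–Uhlenbeck wander (0.05 mm SD). Fixational noise is iid Gaussian
per sample; the default SD of 0.007° puts simulated RMS-S2S at ≈0.014°,
inside the 0.012–0.016° band of a well-set-up 1000-Hz tracker. The
benchmark configuration raises noise to 0.1° to represent accuracy-level
error. Blinks are Poisson (default 2/min) dropouts of 100–250 ms with
40-ms descent and 60-ms recovery ramps; true intervals are returned.

Reading simulation advances fixations left→right with 0.8–1.8° saccades,
wrapping across lines (1.25° default spacing), with optional regressions.
Pupil wanders across fixations as an autocorrelated path standardized to
its sample moments so the realized 95% range tracks the configured target
(default 1.0 mm, within the 0.78–1.38 mm spans observed under constant
luminance). Not emulated: microsaccades and drift within fixations,
saccadic samples between fixations (the stream is a concatenation of
fixation plateaus), word-level reading behavior (word frequency,
skipping), tracker-specific nonlinearities beyond the polynomial family,
and head movement. Passing tests therefore demonstrate correctness of
the estimators and the self-consistency of the method under its own
assumptions, not performance on any particular hardware.

## Reading comparison

Attach assigns each fixation to the nearest line, ties broken to the
upper (smaller-index) line — a deterministic, documented choice.
Correction magnitude (mean |vertical corrective offset| per sample) and
pupil-size sensitivity (|OLS slope| of offset on pupil diameter) are
computed per cell of a 3×3 grid over the stimulus text area (not the full
screen: corrections only exist where text is) and averaged unweighted
across non-empty cells; absolute values are taken before averaging
because the artifact's sign varies across positions and observers.
Regions with fewer than two distinct pupil values are skipped and logged.
External line-assignment algorithms integrate through a one-function
adapter (fixations + layout → line indices); none are bundled.
Mixed-effects group modelling is out of scope; reports give per-subject
descriptives.

## Problem sizes

The test suite and the acceptance script use one eye, one simulated
phase per grid (9 targets × 12 s at 1000 Hz ≈ 108k samples), 300-fixation
reading blocks, 1000-draw round-trip checks, and 1e5-sample Monte-Carlo
checks of the closed-form metric identities; the full suite completes in
well under a minute of compute on one core. These sizes give Monte-Carlo
error comfortably below the asserted tolerances.

## Known limitations

- The polynomial-in-pupil, polynomial-in-position family is the model's
  inductive bias; artifacts with sharper spatial structure would need a
  higher surface degree (configurable) or more targets.
- The lookup inversion is exact only to the grid step (0.1°); residual
  error after correction is bounded by the step times the local field
  gradient.
- The ±20% blink rule assumes the pupil's genuine dynamic range within a
  60-s window is modest; under extreme luminance protocols it over-flags,
  and data-loss-based removal should be preferred there.
- Epochs (stable-fixation windows) are inputs, driven by display timing;
  no event detection is performed.
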