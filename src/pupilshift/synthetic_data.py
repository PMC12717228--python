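"""Synthetic gaze/pupil data with a known pupil-size-artifact field.

The generators emulate the structure of a pupillary-light-reflex (PLR)
calibration experiment and a multi-line reading task:

* a **ground-truth artifact field** ``offset(x, y, pupil)`` per eye, with
  the qualitative spatial structure reported for real trackers: the
  horizontal component has a *contralateral* pattern (larger signed
  slopes for targets on the side opposite the measured eye), and the
  vertical component grows toward the bottom of the screen and with pupil
  size;
* **PLR phases** over a 9-target grid with bright→dark transitions (2 s
  white, 8 s black per target) driving first-order exponential pupil
  constriction/dilation, constriction faster than dilation;
* **reading scanpaths** over a multi-line page with left→right,
  top→bottom fixation sequences and slow pupil wander with a
  configurable 95% range, as observed under constant luminance.

Everything is a pure function of its seed and configuration, and all
ground truth (field parameters, epochs, blink intervals, line labels) is
returned so that detection and recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import InvalidInputError, SampleStream, TargetGrid
from .preprocess import BlinkInterval, Fixation
from .psa_quantify import Epoch
from .psa_recalibration import (CoefficientSurface, predict_offset,
                                surface_exponents)
from .reading_compare import LineLayout

__all__ = [
    "GroundTruthField",
    "PlrSchedule",
    "PupilDynamics",
    "make_field",
    "simulate_plr_phase",
    "simulate_reading",
]

# Per-sample fixational noise SD (deg).  Chosen so that the simulated
# RMS-S2S (~2*sigma for iid Gaussian noise) lands in the 0.012-0.016 deg
# band typical of a well-set-up 1000-Hz video eye tracker.
DEFAULT_NOISE_SD_DEG = 0.007


@dataclass
class GroundTruthField:
    """True artifact field offset(x, y, pupil) for one eye.

    Uses the same coefficient-surface family as the recalibration model
    (six 2-D polynomial surfaces feeding per-position pupil quadratics),
    so noiseless parameter recovery is exactly testable.
    """

    eye: str
    surfaces: CoefficientSurface
    noise_sd: float
    seed: int

    def offset(self, x, y, pupil) -> tuple[np.ndarray, np.ndarray]:
        return predict_offset(self.surfaces, x, y, pupil)

    def horizontal_slope(self, x, y, pupil) -> np.ndarray:
        """d(dx)/dp at the given position and pupil size."""
        a1 = self.surfaces.evaluate("a1", x, y)
        a2 = self.surfaces.evaluate("a2", x, y)
        return a1 + 2.0 * a2 * np.asarray(pupil, float)

    def vertical_slope(self, x, y, pupil) -> np.ndarray:
        b1 = self.surfaces.evaluate("b1", x, y)
        b2 = self.surfaces.evaluate("b2", x, y)
        return b1 + 2.0 * b2 * np.asarray(pupil, float)


@dataclass(frozen=True)
class PlrSchedule:
    """Per-target timing of the bright→dark fixation sequence (seconds).

    Each target shows a white fixation period, then a black one; pulsing
    gaps (blink opportunities, excluded from analysis epochs) separate
    the stable periods and the targets.
    """

    white_s: float = 2.0
    black_s: float = 8.0
    gap_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.white_s, self.black_s) <= 0 or self.gap_s < 0:
            raise InvalidInputError("schedule durations must be positive")

    @property
    def per_target_s(self) -> float:
        return self.gap_s + self.white_s + self.gap_s + self.black_s


@dataclass(frozen=True)
class PupilDynamics:
    """First-order pupil response to luminance steps plus slow wander."""

    p_bright: float = 2.0       # asymptotic diameter on white, mm
    p_dark: float = 6.0         # asymptotic diameter on black, mm
    tau_constrict: float = 0.4  # s; light response is fast
    tau_dilate: float = 2.0     # s; dilation in darkness is slow
    wander_sd: float = 0.05     # mm, slow ornstein-uhlenbeck wander

    def __post_init__(self) -> None:
        if not self.p_bright < self.p_dark:
            raise InvalidInputError("need p_bright < p_dark")
        if not self.tau_constrict < self.tau_dilate:
            raise InvalidInputError(
                "constriction must be faster than dilation "
                "(tau_constrict < tau_dilate)")


def make_field(seed: int, eye: str = "left", magnitude: float = 0.4,
               asymmetry: float = 0.5, half_x: float = 13.5,
               half_y: float = 6.4, noise_sd: float = DEFAULT_NOISE_SD_DEG
               ) -> GroundTruthField:
    """Construct a ground-truth artifact field with realistic structure.

    ``magnitude`` (deg/mm) sets the typical pupil slope of the offsets;
    real setups show median horizontal slopes around 0.4 deg/mm.
    ``asymmetry`` in [0, 1] controls how strongly the horizontal slope
    grows toward the contralateral side.  Construction guarantees the
    documented invariants: for the left eye the signed horizontal slope
    is larger at x > 0 (mirrored for the right eye), and the vertical
    slope is non-negative, non-decreasing toward the screen bottom
    (larger y) and with pupil size.
    """
    if eye not in ("left", "right"):
        raise InvalidInputError("eye must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    side = 1.0 if eye == "left" else -1.0
    exps = surface_exponents(2)
    idx = {e: i for i, e in enumerate(exps)}
    n = len(exps)

    def jitter(scale):
        return rng.normal(0.0, scale)

    # horizontal pupil slope a1(x, y): base + contralateral gradient
    a1 = np.zeros(n)
    a1[idx[(0, 0)]] = magnitude * (1.0 + jitter(0.08))
    a1[idx[(1, 0)]] = side * asymmetry * magnitude / half_x * (1.0 + jitter(0.1))
    a1[idx[(0, 1)]] = magnitude / half_y * jitter(0.05)
    # horizontal curvature in pupil: small
    a2 = np.zeros(n)
    a2[idx[(0, 0)]] = 0.02 * magnitude * (1.0 + jitter(0.2))
    # vertical slope b1(x, y): positive, increasing with y (screen bottom)
    b1 = np.zeros(n)
    b1[idx[(0, 0)]] = 0.6 * magnitude * (1.0 + jitter(0.08))
    b1[idx[(0, 1)]] = 0.35 * magnitude / half_y * (1.0 + jitter(0.1))
    # vertical slope grows with pupil size: positive quadratic term
    b2 = np.zeros(n)
    b2[idx[(0, 0)]] = 0.03 * magnitude * (1.0 + jitter(0.2))
    # baseline (pupil-independent) miscalibration offsets, small
    a0 = np.zeros(n)
    a0[idx[(0, 0)]] = jitter(0.1 * magnitude)
    b0 = np.zeros(n)
    b0[idx[(0, 0)]] = jitter(0.1 * magnitude)
    if magnitude == 0:
        a0[:] = b0[:] = a1[:] = a2[:] = b1[:] = b2[:] = 0.0
    surfaces = CoefficientSurface(
        degree=2, exponents=exps,
        coeffs={"a0": a0, "a1": a1, "a2": a2, "b0": b0, "b1": b1, "b2": b2})
    return GroundTruthField(eye=eye, surfaces=surfaces, noise_sd=noise_sd,
                            seed=seed)


def _ou_wander(n: int, dt: float, sd: float, tau_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path with marginal SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau_s)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), size=n)
    w = np.empty(n)
    w[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        w[i] = rho * w[i - 1] + eps[i]
    return w


def _inject_blinks(pupil: np.ndarray, valid: np.ndarray, rate_hz: float,
                   blink_rate_per_min: float, rng: np.random.Generator
                   ) -> list[BlinkInterval]:
    """Dropouts with sloped partial-occlusion margins; returns true episodes."""
    n = len(pupil)
    dt_ms = 1000.0 / rate_hz
    n_blinks = rng.poisson(blink_rate_per_min * n * dt_ms / 60000.0)
    intervals: list[BlinkInterval] = []
    desc = int(round(40 * rate_hz / 1000.0))    # 40-ms lid descent
    reco = int(round(60 * rate_hz / 1000.0))    # 60-ms recovery
    for _ in range(n_blinks):
        gap = int(round(rng.uniform(100, 250) * rate_hz / 1000.0))
        start = int(rng.integers(desc, max(n - gap - reco, desc + 1)))
        d0, d1 = start - desc, start
        r0, r1 = start + gap, min(start + gap + reco, n)
        # descent ramp: reported pupil collapses toward zero
        ramp = np.linspace(1.0, 0.0, d1 - d0, endpoint=False)
        pupil[d0:d1] = pupil[d0:d1] * ramp
        pupil[d1:r0] = np.nan
        valid[d1:r0] = False
        rr = np.linspace(0.0, 1.0, r1 - r0, endpoint=False)
        pupil[r0:r1] = pupil[r0:r1] * rr
        intervals.append(BlinkInterval(d0 * dt_ms, r1 * dt_ms))
    # merge overlapping injected episodes into disjoint sorted truth
    intervals.sort()
    merged: list[BlinkInterval] = []
    for iv in intervals:
        if merged and iv.onset_ms <= merged[-1].offset_ms:
            merged[-1] = BlinkInterval(merged[-1].onset_ms,
                                       max(merged[-1].offset_ms, iv.offset_ms))
        else:
            merged.append(iv)
    return merged


def simulate_plr_phase(field: GroundTruthField, grid: TargetGrid,
                       schedule: PlrSchedule = PlrSchedule(),
                       dynamics: PupilDynamics = PupilDynamics(),
                       rate_hz: float = 1000.0,
                       noise_sd: float | None = None,
                       blink_rate_per_min: float = 2.0,
                       seed: int = 0,
                       ) -> tuple[SampleStream, list[Epoch],
                                  list[BlinkInterval]]:
    """Simulate one PLR phase over a target grid.

    The pupil relaxes exponentially toward the luminance-appropriate
    asymptote (white → ``p_bright`` with ``tau_constrict``; black/gaps →
    ``p_dark`` with ``tau_dilate``) plus slow wander.  Gaze sits on the
    current target, displaced by the true artifact field evaluated at the
    target and instantaneous pupil size, plus iid Gaussian fixational
    noise.  Blinks are injected as dropouts with sloped margins.  Returns
    the stream, the stable-fixation epochs (white and black, pulsing gaps
    excluded), and the true blink intervals.
    """
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = field.noise_sd
    dt = 1.0 / rate_hz
    per_target = schedule.per_target_s
    n_total = int(round(per_target * len(grid.points) * rate_hz))
    t_ms = np.arange(n_total) * (1000.0 * dt)

    # luminance trace: white only during the white window of each target
    bright = np.zeros(n_total, dtype=bool)
    epochs: list[Epoch] = []
    tgt_idx = np.empty(n_total, dtype=np.int64)
    for k in range(len(grid.points)):
        t0 = k * per_target
        i0 = int(round(t0 * rate_hz))
        i1 = int(round((t0 + per_target) * rate_hz))
        tgt_idx[i0:i1] = k
        w0 = int(round((t0 + schedule.gap_s) * rate_hz))
        w1 = int(round((t0 + schedule.gap_s + schedule.white_s) * rate_hz))
        bright[w0:w1] = True
        b0 = int(round((t0 + 2 * schedule.gap_s + schedule.white_s) * rate_hz))
        epochs.append(Epoch(k, "white", w0 * dt * 1000.0, w1 * dt * 1000.0))
        epochs.append(Epoch(k, "black", b0 * dt * 1000.0, i1 * dt * 1000.0))

    # first-order relaxation toward the luminance asymptote
    pupil = np.empty(n_total)
    p = dynamics.p_dark  # screens start black
    targets_p = np.where(bright, dynamics.p_bright, dynamics.p_dark)
    taus = np.where(bright, dynamics.tau_constrict, dynamics.tau_dilate)
    alpha = 1.0 - np.exp(-dt / taus)
    for i in range(n_total):
        p = p + alpha[i] * (targets_p[i] - p)
        pupil[i] = p
    pupil = pupil + _ou_wander(n_total, dt, dynamics.wander_sd, 5.0, rng)

    pts = grid.as_array()
    tx = pts[tgt_idx, 0]
    ty = pts[tgt_idx, 1]
    dx, dy = field.offset(tx, ty, pupil)
    x = tx + dx + rng.normal(0.0, noise_sd, n_total)
    y = ty + dy + rng.normal(0.0, noise_sd, n_total)

    valid = np.ones(n_total, dtype=bool)
    blinks = _inject_blinks(pupil, valid, rate_hz, blink_rate_per_min, rng)
    x[~valid] = np.nan
    y[~valid] = np.nan

    stream = SampleStream(field.eye, rate_hz, t_ms, x, y, pupil, valid)
    return stream, epochs, blinks


def simulate_reading(field: GroundTruthField, layout: LineLayout,
                     pupil_mean_mm: float = 4.0,
                     pupil_range_95_mm: float = 1.0,
                     n_fixations: int = 300,
                     fixation_ms: tuple[float, float] = (120.0, 400.0),
                     saccade_deg: tuple[float, float] = (0.8, 1.8),
                     regression_prob: float = 0.0,
                     noise_sd: float | None = None,
                     rate_hz: float = 1000.0,
                     seed: int = 0,
                     ) -> tuple[SampleStream, list[Fixation], np.ndarray]:
    """Simulate a multi-line reading scanpath under constant luminance.

    Fixations advance left→right within a line and wrap top→bottom across
    lines (restarting at the top after the last line), with optional
    leftward regressions.  The pupil wanders slowly around
    ``pupil_mean_mm`` with a marginal spread calibrated so the realized
    95% range (2.5th–97.5th percentile span) matches
    ``pupil_range_95_mm``.  Measured positions are the true fixation
    positions displaced by the artifact field plus fixational noise.

    Returns the sample stream, the measured fixation events, and the true
    line index per fixation.
    """
    if n_fixations < 1:
        raise InvalidInputError("need at least one fixation")
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = field.noise_sd
    line_ys = np.asarray(layout.line_ys, dtype=float)
    x_min, x_max = layout.x_extent

    # true scanpath
    true_x = np.empty(n_fixations)
    true_y = np.empty(n_fixations)
    line_idx = np.empty(n_fixations, dtype=np.int64)
    cur_line = 0
    cx = x_min
    for i in range(n_fixations):
        true_x[i] = cx
        true_y[i] = line_ys[cur_line]
        line_idx[i] = cur_line
        if rng.uniform() < regression_prob and cx > x_min + saccade_deg[1]:
            cx -= rng.uniform(*saccade_deg)
        else:
            cx += rng.uniform(*saccade_deg)
        if cx > x_max:
            cx = x_min
            cur_line = (cur_line + 1) % len(line_ys)

    # slow pupil wander across fixations; 95% range of a normal is
    # (z_97.5 - z_2.5) * sd = 3.9199 * sd.  The finite path is standardized
    # to its sample moments so the realized spread tracks the target range
    # despite autocorrelation.
    sd = pupil_range_95_mm / 3.9199
    w = _ou_wander(n_fixations, 1.0, 1.0, 3.0, rng)
    if n_fixations > 1 and np.std(w) > 0:
        w = (w - np.mean(w)) / np.std(w)
    fix_pupil = pupil_mean_mm + sd * w

    durations = rng.uniform(*fixation_ms, size=n_fixations)
    n_per_fix = np.maximum((durations * rate_hz / 1000.0).astype(int), 2)
    n_total = int(n_per_fix.sum())
    dt_ms = 1000.0 / rate_hz
    t_ms = np.arange(n_total) * dt_ms

    fx = np.repeat(true_x, n_per_fix)
    fy = np.repeat(true_y, n_per_fix)
    fp = np.repeat(fix_pupil, n_per_fix)
    fp = fp + rng.normal(0.0, 0.001, n_total)  # tracker pupil noise
    dx, dy = field.offset(fx, fy, fp)
    x = fx + dx + rng.normal(0.0, noise_sd, n_total)
    y = fy + dy + rng.normal(0.0, noise_sd, n_total)
    stream = SampleStream(field.eye, rate_hz, t_ms, x, y, fp)

    fixations: list[Fixation] = []
    starts = np.concatenate([[0], np.cumsum(n_per_fix)])
    for i in range(n_fixations):
        s0, s1 = starts[i], starts[i + 1]
        fixations.append(Fixation(
            onset_ms=float(t_ms[s0]), offset_ms=float(t_ms[s1 - 1] + dt_ms),
            x=float(np.mean(x[s0:s1])), y=float(np.mean(y[s0:s1])),
            pupil=float(np.median(fp[s0:s1])), eye=field.eye))
    return stream, fixations, line_idx
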