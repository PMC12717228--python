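"""Quantifying the pupil size artifact from pupillary-light-reflex data.

During stable fixation on a known target, any offset between measured gaze
and the target is *apparent* gaze shift.  When luminance changes drive the
pupil through a wide diameter range, plotting that offset against pupil
diameter exposes the pupil size artifact (PSA): the systematic drift of
the reported gaze position with pupil size.

The offset–pupil relationship is summarized by locally weighted linear
regression (LOWESS) with an *adaptive span* that keeps a constant 1-mm
pupil-diameter window, so that smoothing bandwidth is uniform in pupil
units regardless of how samples are distributed.  Curves are normalized to
zero at a reference pupil size (3 mm) so they can be compared across
recordings regardless of initial tracker calibration.  The *PSA slope*
(deg/mm) over a pupil range is the chord slope of the smoothed curve,
which equals the average local derivative over that range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry_io import InvalidInputError, SampleStream, TargetGrid

__all__ = [
    "Epoch",
    "OffsetSeries",
    "PsaCurve",
    "PupilRange",
    "InsufficientDataError",
    "compute_offsets",
    "lowess_constant_window",
    "lowess_adaptive",
    "normalize_curve",
    "psa_slope",
    "pupil_range_95",
    "shift_estimate",
    "bin_median_positions",
    "unit_conversion_report",
]

REF_PUPIL_MM = 3.0


class InsufficientDataError(ValueError):
    """Raised when data cannot support the requested estimate."""


@dataclass(frozen=True)
class Epoch:
    """A stable-fixation window on one target (half-open, ms)."""

    target_index: int
    label: str          # e.g. "white" | "black"
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise InvalidInputError("epoch needs onset < offset")


@dataclass
class OffsetSeries:
    """Apparent gaze shift records for one eye and one target.

    ``dx``/``dy`` are measured gaze minus target coordinates, drawn from
    valid samples during stable fixation epochs on that target.
    """

    eye: str
    target: tuple[float, float]
    pupil: np.ndarray
    dx: np.ndarray
    dy: np.ndarray

    def __len__(self) -> int:
        return len(self.pupil)


@dataclass
class PsaCurve:
    """Smoothed apparent-gaze-shift vs. pupil-size curve for one axis."""

    axis: str                   # "horizontal" | "vertical"
    pupil: np.ndarray           # strictly increasing knot pupil sizes (mm)
    shift: np.ndarray           # shift at each knot (deg)
    ref_pupil: float = REF_PUPIL_MM

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if len(self.pupil) < 2 or np.any(np.diff(self.pupil) <= 0):
            raise InvalidInputError("curve knots must be strictly increasing")

    def __call__(self, p) -> np.ndarray:
        """Interpolate shift at pupil size(s) p, clamped to the knot range."""
        return np.interp(p, self.pupil, self.shift)


@dataclass(frozen=True)
class PupilRange:
    """A pupil-diameter interval, typically the 2.5th–97.5th percentile span."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise InvalidInputError("pupil range needs low <= high")

    @property
    def width(self) -> float:
        return self.high - self.low


def compute_offsets(stream: SampleStream, grid: TargetGrid,
                    epochs: Sequence[Epoch]) -> list[OffsetSeries]:
    """One offset series per target, from valid samples in its epochs."""
    t = stream.t_ms
    out = []
    for k, (tx, ty) in enumerate(grid.points):
        mask = np.zeros(len(t), dtype=bool)
        for ep in epochs:
            if ep.target_index == k:
                mask |= (t >= ep.onset_ms) & (t < ep.offset_ms)
        mask &= stream.valid
        out.append(OffsetSeries(
            eye=stream.eye, target=(tx, ty),
            pupil=stream.pupil[mask],
            dx=stream.x[mask] - tx,
            dy=stream.y[mask] - ty,
        ))
    return out


def lowess_constant_window(pupil: np.ndarray, shift: np.ndarray,
                           window_mm: float = 1.0,
                           n_grid: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """LOWESS with a constant pupil-diameter window.

    Degree-1 locally weighted least squares with tricube weights,
    evaluated on an evenly spaced pupil grid.  At each evaluation point
    the span is the records within ±window_mm/2 (clipped at the data
    range); no robustness iterations.  Local linear fitting reproduces a
    globally linear relationship exactly.
    """
    p = np.asarray(pupil, dtype=float)
    s = np.asarray(shift, dtype=float)
    ok = np.isfinite(p) & np.isfinite(s)
    p, s = p[ok], s[ok]
    if len(p) < 10 or (p.max() - p.min()) <= window_mm:
        raise InsufficientDataError(
            f"need >= 10 records spanning more than {window_mm} mm of pupil "
            f"range; got {len(p)} records over "
            f"{(p.max() - p.min()) if len(p) else 0:.3f} mm")
    order = np.argsort(p, kind="stable")
    p, s = p[order], s[order]
    grid = np.linspace(p[0], p[-1], n_grid)
    half = window_mm / 2.0
    out = np.empty(n_grid)
    for i, g in enumerate(grid):
        lo = np.searchsorted(p, g - half, side="left")
        hi = np.searchsorted(p, g + half, side="right")
        pp, ss = p[lo:hi], s[lo:hi]
        u = np.abs(pp - g) / half
        w = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, None) ** 3
        # at the data edges the window is one-sided; weights can vanish if
        # all in-window points sit at distance >= half — fall back to uniform
        if w.sum() <= 0:
            w = np.ones_like(pp)
        sw = w.sum()
        pm = np.dot(w, pp) / sw
        sm = np.dot(w, ss) / sw
        var = np.dot(w, (pp - pm) ** 2)
        if var > 1e-12:
            beta = np.dot(w, (pp - pm) * (ss - sm)) / var
            out[i] = sm + beta * (g - pm)
        else:
            out[i] = sm
    return grid, out


def lowess_adaptive(series: OffsetSeries, window_mm: float = 1.0,
                    n_grid: int = 50, normalize: bool = True,
                    ref_pupil: float = REF_PUPIL_MM
                    ) -> tuple[PsaCurve, PsaCurve]:
    """Smoothed PSA curves (horizontal, vertical) for one offset series."""
    gx, sx = lowess_constant_window(series.pupil, series.dx, window_mm, n_grid)
    gy, sy = lowess_constant_window(series.pupil, series.dy, window_mm, n_grid)
    cx = PsaCurve("horizontal", gx, sx, ref_pupil)
    cy = PsaCurve("vertical", gy, sy, ref_pupil)
    if normalize:
        cx = normalize_curve(cx, ref_pupil)
        cy = normalize_curve(cy, ref_pupil)
    return cx, cy


def normalize_curve(curve: PsaCurve, ref_pupil: float = REF_PUPIL_MM
                    ) -> PsaCurve:
    """Shift the curve so it passes through zero at ``ref_pupil``.

    If ``ref_pupil`` lies outside the knot range the nearest endpoint value
    is used (np.interp clamps).  Idempotent and invariant to constant
    offsets of the input.
    """
    ref_val = float(np.interp(ref_pupil, curve.pupil, curve.shift))
    return PsaCurve(curve.axis, curve.pupil.copy(), curve.shift - ref_val,
                    ref_pupil)


def psa_slope(curve: PsaCurve, prange: PupilRange) -> float:
    """Mean local slope (deg/mm) of the curve over a pupil range.

    Implemented as the chord slope of the smoothed curve between the
    range endpoints (interpolated), which equals the average derivative.
    The range is clipped to the curve's support.  A zero-width range
    returns the local finite-difference derivative at the point.
    """
    lo = max(prange.low, float(curve.pupil[0]))
    hi = min(prange.high, float(curve.pupil[-1]))
    if lo > hi:
        raise InsufficientDataError("pupil range does not overlap curve support")
    if hi - lo < 1e-12:
        # degenerate range: derivative from the adjacent knots
        i = int(np.clip(np.searchsorted(curve.pupil, lo) - 1, 0,
                        len(curve.pupil) - 2))
        return float((curve.shift[i + 1] - curve.shift[i]) /
                     (curve.pupil[i + 1] - curve.pupil[i]))
    return float((curve(hi) - curve(lo)) / (hi - lo))


def pupil_range_95(pupil: np.ndarray) -> PupilRange:
    """The 2.5th–97.5th percentile span of a pupil-diameter series."""
    p = np.asarray(pupil, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise InsufficientDataError("no finite pupil samples")
    lo, hi = np.percentile(p, [2.5, 97.5])
    return PupilRange(float(lo), float(hi))


def shift_estimate(slope: float, delta_pupil: float) -> float:
    """Expected apparent gaze shift magnitude: |slope| x |Δpupil| (deg)."""
    return abs(slope) * abs(delta_pupil)


def mean_shift_estimate(slopes: Sequence[float],
                        delta_pupils: Sequence[float]) -> float:
    """Average |slope|x|Δpupil| across eyes/regions (paired sequences)."""
    if len(slopes) != len(delta_pupils) or len(slopes) == 0:
        raise InvalidInputError("need equal-length non-empty sequences")
    return float(np.mean([shift_estimate(s, d)
                          for s, d in zip(slopes, delta_pupils)]))


def bin_median_positions(stream: SampleStream, epochs: Sequence[Epoch],
                         target_index: int, bin_width: float = 0.1,
                         clip: tuple[float, float] = (2.5, 97.5)
                         ) -> np.ndarray:
    """Per-pupil-bin median gaze positions during fixation on one target.

    Resamples the data into fixed-width pupil-diameter bins (default
    0.1 mm) spanning the clip percentiles (default 2.5th–97.5th) so that
    unevenly distributed pupil sizes contribute equally.  Returns an array
    of rows ``(bin_center_pupil, median_x, median_y)``; empty bins are
    omitted.
    """
    t = stream.t_ms
    mask = np.zeros(len(t), dtype=bool)
    for ep in epochs:
        if ep.target_index == target_index:
            mask |= (t >= ep.onset_ms) & (t < ep.offset_ms)
    mask &= stream.valid
    p = stream.pupil[mask]
    x = stream.x[mask]
    y = stream.y[mask]
    if len(p) == 0:
        return np.empty((0, 3))
    lo, hi = np.percentile(p, clip)
    keep = (p >= lo) & (p <= hi)
    p, x, y = p[keep], x[keep], y[keep]
    if len(p) == 0:
        return np.empty((0, 3))
    edges = np.arange(np.floor(lo / bin_width) * bin_width,
                      hi + bin_width, bin_width)
    idx = np.digitize(p, edges) - 1
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        center = edges[b] + bin_width / 2.0
        rows.append((center, float(np.median(x[sel])),
                     float(np.median(y[sel]))))
    return np.asarray(rows)


def unit_conversion_report(shift_deg: float, char_width_deg: float = 0.16,
                           line_spacing_deg: float = 1.25
                           ) -> tuple[float, float]:
    """Express an angular shift in reading-layout units (characters, lines)."""
    if char_width_deg <= 0 or line_spacing_deg <= 0:
        raise InvalidInputError("layout dimensions must be positive")
    return shift_deg / char_width_deg, shift_deg / line_spacing_deg
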