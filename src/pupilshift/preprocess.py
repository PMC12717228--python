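"""Blink detection/removal and fixation-duration filtering.

Blinks in video-based pupillometry show up as data loss (the pupil is not
detected at all) flanked by short artifactual ramps where the eyelid
partially occludes the pupil and the reported size collapses or recovers.
The pipeline here follows standard pupillometric practice:

1. flag samples whose pupil deviates by more than ±20% from a local
   (60-s moving window) average, plus all data-loss gaps;
2. refine interval margins outward over the occlusion ramps with a
   slope-scan (in the spirit of noise-based blink-reconstruction
   algorithms);
3. merge episodes separated by less than 100 ms.

All intervals are half-open ``[onset, offset)`` in milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry_io import InvalidInputError, SampleStream

__all__ = [
    "BlinkInterval",
    "Fixation",
    "detect_blinks_window",
    "refine_blink_margins",
    "merge_blinks",
    "remove_blinks",
    "filter_fixations",
    "blink_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class BlinkInterval:
    """Half-open blink episode [onset_ms, offset_ms)."""

    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise InvalidInputError(
                f"blink interval needs onset < offset, got "
                f"[{self.onset_ms}, {self.offset_ms})")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Fixation:
    """A fixation event: centroid position, median pupil, and timing."""

    onset_ms: float
    offset_ms: float
    x: float
    y: float
    pupil: float
    eye: str

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise InvalidInputError("fixation duration must be positive")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _runs_to_intervals(mask: np.ndarray, t: np.ndarray,
                       rate_hz: float) -> list[BlinkInterval]:
    """Maximal True-runs of ``mask`` as half-open intervals in ms."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    dt = 1000.0 / rate_hz
    out = []
    for i0, i1 in zip(starts, stops):
        onset = t[i0]
        # offset is one sample past the last flagged sample (half-open)
        offset = t[i1] if i1 < len(t) else t[-1] + dt
        out.append(BlinkInterval(float(onset), float(offset)))
    return out


def _moving_average_excluding_missing(p: np.ndarray, ok: np.ndarray,
                                      win: int) -> np.ndarray:
    """Centered moving average over valid samples, truncated at the edges."""
    half = win // 2
    vals = np.where(ok, p, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    n = len(p)
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    s = cs[hi] - cs[lo]
    c = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def detect_blinks_window(stream: SampleStream, window_s: float = 60.0,
                         threshold: float = 0.20) -> list[BlinkInterval]:
    """Flag blink candidates as pupil deviations beyond ±threshold.

    The local reference is a centered moving average over ``window_s``
    seconds, computed excluding already-missing samples (window truncated
    at stream edges).  Data-loss gaps (missing pupil) are always included
    as candidates; this catches full blinks, while the relative-deviation
    rule catches partial blinks with reduced but non-missing pupil size.
    """
    if len(stream) == 0:
        raise InvalidInputError("empty stream")
    p = stream.pupil
    ok = np.isfinite(p)
    win = int(round(window_s * stream.rate_hz))
    if win >= len(p):
        log.info("stream shorter than %.0f-s window; using whole-stream "
                 "average", window_s)
        win = len(p)
    ma = _moving_average_excluding_missing(p, ok, win)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(p - ma) / ma
    flagged = ~ok | (np.isfinite(dev) & (dev > threshold))
    return _runs_to_intervals(flagged, stream.t_ms, stream.rate_hz)


def _smooth_diff(p: np.ndarray, rate_hz: float, smooth_ms: float = 10.0
                 ) -> np.ndarray:
    """First difference of a boxcar-smoothed pupil signal (mm/sample)."""
    k = max(int(round(smooth_ms * rate_hz / 1000.0)), 1)
    filled = np.where(np.isfinite(p), p, 0.0)
    w = np.isfinite(p).astype(float)
    num = np.convolve(filled, np.ones(k), mode="same")
    den = np.convolve(w, np.ones(k), mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    d = np.diff(sm, prepend=sm[:1])
    return d


def refine_blink_margins(stream: SampleStream,
                         intervals: Sequence[BlinkInterval],
                         slope_eps: float = 0.002,
                         max_extend_ms: float = 200.0
                         ) -> list[BlinkInterval]:
    """Extend intervals outward over the gradual pupil ramps flanking blinks.

    Each interval grows backward while the smoothed pupil signal is still
    falling into the blink, and forward while it is still recovering
    (|first difference| > ``slope_eps`` mm/sample with the matching sign),
    up to ``max_extend_ms`` per side.  Refined intervals always contain the
    originals; the operation is idempotent.
    """
    if not intervals:
        return []
    t = stream.t_ms
    d = _smooth_diff(stream.pupil, stream.rate_hz)
    max_ext = int(round(max_extend_ms * stream.rate_hz / 1000.0))
    out = []
    for iv in intervals:
        i0 = int(np.searchsorted(t, iv.onset_ms, side="left"))
        i1 = int(np.searchsorted(t, iv.offset_ms, side="left"))
        j0 = i0
        # descend: pupil falling (negative slope) just before onset
        while j0 > 0 and i0 - j0 < max_ext and np.isfinite(d[j0 - 1]) \
                and d[j0 - 1] < -slope_eps:
            j0 -= 1
        j1 = i1
        n = len(t)
        # recovery: pupil rising (positive slope) just after offset
        while j1 < n and j1 - i1 < max_ext and np.isfinite(d[j1]) \
                and d[j1] > slope_eps:
            j1 += 1
        onset = float(t[j0]) if j0 < n else iv.onset_ms
        offset = float(t[j1]) if j1 < n else float(
            t[-1] + 1000.0 / stream.rate_hz)
        out.append(BlinkInterval(min(onset, iv.onset_ms),
                                 max(offset, iv.offset_ms)))
    return _coalesce_overlapping(sorted(out))


def _coalesce_overlapping(ivs: list[BlinkInterval]) -> list[BlinkInterval]:
    """Union of sorted intervals that may overlap after margin extension."""
    if not ivs:
        return []
    out = [ivs[0]]
    for iv in ivs[1:]:
        if iv.onset_ms <= out[-1].offset_ms:
            out[-1] = BlinkInterval(out[-1].onset_ms,
                                    max(out[-1].offset_ms, iv.offset_ms))
        else:
            out.append(iv)
    return out


def merge_blinks(intervals: Sequence[BlinkInterval],
                 min_gap_ms: float = 100.0) -> list[BlinkInterval]:
    """Coalesce consecutive episodes separated by less than ``min_gap_ms``.

    Input must be sorted and disjoint.  Idempotent and associative.
    """
    ivs = list(intervals)
    for a, b in zip(ivs, ivs[1:]):
        if b.onset_ms < a.onset_ms or b.onset_ms < a.offset_ms:
            raise InvalidInputError("intervals must be sorted and disjoint")
    if not ivs:
        return []
    out = [ivs[0]]
    for iv in ivs[1:]:
        gap = iv.onset_ms - out[-1].offset_ms
        if gap < min_gap_ms:
            out[-1] = BlinkInterval(out[-1].onset_ms,
                                    max(out[-1].offset_ms, iv.offset_ms))
        else:
            out.append(iv)
    return out


def remove_blinks(stream: SampleStream,
                  intervals: Sequence[BlinkInterval]) -> SampleStream:
    """Mark samples inside the (half-open) intervals as missing."""
    out = stream.copy()
    if not intervals:
        return out
    t = out.t_ms
    mask = np.zeros(len(t), dtype=bool)
    for iv in intervals:
        mask |= (t >= iv.onset_ms) & (t < iv.offset_ms)
    out.valid &= ~mask
    out.x[mask] = np.nan
    out.y[mask] = np.nan
    out.pupil[mask] = np.nan
    log.info("removed %d samples in %d blink episodes",
             int(mask.sum()), len(intervals))
    return out


def blink_pipeline(stream: SampleStream, *, window_s: float = 60.0,
                   threshold: float = 0.20, slope_eps: float = 0.002,
                   max_extend_ms: float = 200.0, min_gap_ms: float = 100.0
                   ) -> tuple[SampleStream, list[BlinkInterval]]:
    """detect → refine → merge → remove; returns the cleaned stream and episodes."""
    raw = detect_blinks_window(stream, window_s, threshold)
    refined = refine_blink_margins(stream, raw, slope_eps, max_extend_ms)
    merged = merge_blinks(refined, min_gap_ms)
    return remove_blinks(stream, merged), merged


def filter_fixations(fixations: Sequence[Fixation], min_ms: float = 80.0,
                     max_ms: float = 800.0) -> list[Fixation]:
    """Drop implausibly short (<min_ms) and long (>max_ms) fixations.

    Boundaries are inclusive: a fixation of exactly ``min_ms`` or
    ``max_ms`` is kept.
    """
    return [f for f in fixations if min_ms <= f.duration_ms <= max_ms]
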