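"""Data-quality and fixation-stability metrics.

Three standard eye-tracking metrics:

* **RMS-S2S** — root mean square of sample-to-sample displacements within
  a sliding window (default 100 ms), aggregated by the median across
  windows; a precision (noise) measure.  For iid Gaussian position noise
  with per-axis SD σ, the expected 2-D RMS-S2S is 2σ.
* **data loss** — fraction of expected samples that are missing.
* **BCEA** — bivariate contour ellipse area, the area of the ellipse
  containing a stated fraction (default 68%) of points under a
  bivariate-normal model:  ``2 k π σx σy sqrt(1 − ρ²)`` with
  ``k = −ln(1 − P)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import InvalidInputError, SampleStream

__all__ = ["QualityReport", "UndefinedMetricError", "rms_s2s", "data_loss",
           "bcea", "quality_report"]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value for the given data."""


@dataclass(frozen=True)
class QualityReport:
    rms_s2s_gaze: float      # deg
    rms_s2s_pupil: float     # mm
    data_loss: float         # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.rms_s2s_gaze < 0 or self.rms_s2s_pupil < 0:
            raise InvalidInputError("RMS-S2S must be non-negative")
        if not 0 <= self.data_loss <= 1:
            raise InvalidInputError("data loss must be in [0, 1]")


def rms_s2s(stream: SampleStream, window_ms: float = 100.0,
            signal: str = "gaze", aggregate: str = "median") -> float:
    """Windowed RMS of sample-to-sample distances.

    Distances are Euclidean for ``signal='gaze'`` and absolute differences
    for ``signal='pupil'``.  The window slides by one sample; any window
    containing a missing sample is skipped (not shortened).  The median
    (configurable to mean) across windows is returned.
    """
    if signal == "gaze":
        d2 = np.diff(stream.x) ** 2 + np.diff(stream.y) ** 2
    elif signal == "pupil":
        d2 = np.diff(stream.pupil) ** 2
    else:
        raise InvalidInputError(f"unknown signal {signal!r}")
    ok = np.isfinite(d2)
    n_win = int(round(window_ms * stream.rate_hz / 1000.0))
    n_diff = max(n_win - 1, 1)  # displacements per window
    if len(d2) < n_diff:
        raise UndefinedMetricError("stream shorter than one window")
    # rolling sums over n_diff consecutive displacements
    cs = np.concatenate([[0.0], np.cumsum(np.where(ok, d2, 0.0))])
    cn = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    sums = cs[n_diff:] - cs[:-n_diff]
    cnts = cn[n_diff:] - cn[:-n_diff]
    complete = cnts == n_diff
    if not complete.any():
        raise UndefinedMetricError("no window free of missing samples")
    vals = np.sqrt(sums[complete] / n_diff)
    if aggregate == "median":
        return float(np.median(vals))
    if aggregate == "mean":
        return float(np.mean(vals))
    raise InvalidInputError(f"unknown aggregate {aggregate!r}")


def data_loss(stream: SampleStream) -> float:
    """Missing samples as a fraction of samples expected from rate and span."""
    expected = int(round(stream.duration_ms * stream.rate_hz / 1000.0)) + 1
    missing = int((~stream.valid).sum()) + max(expected - len(stream), 0)
    return missing / expected


def bcea(points: np.ndarray, coverage: float = 0.68) -> float:
    """Bivariate contour ellipse area (deg²) of a 2-D point set.

    ``points`` is (n, 2).  Requires at least 3 points; collinear point
    sets give area 0.  Invariant under rotation and translation.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise UndefinedMetricError("BCEA needs at least 3 finite 2-D points")
    if not 0 < coverage < 1:
        raise InvalidInputError("coverage must be in (0, 1)")
    k = -np.log(1.0 - coverage)
    sx = np.std(pts[:, 0], ddof=1)
    sy = np.std(pts[:, 1], ddof=1)
    if sx == 0 or sy == 0:
        return 0.0
    rho = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
    rho2 = min(rho * rho, 1.0)
    if 1.0 - rho2 < 1e-12:  # numerically collinear: degenerate ellipse
        return 0.0
    return float(2.0 * k * np.pi * sx * sy * np.sqrt(1.0 - rho2))


def quality_report(stream: SampleStream,
                   window_ms: float = 100.0) -> QualityReport:
    """RMS-S2S (gaze and pupil) and data loss for one stream."""
    return QualityReport(
        rms_s2s_gaze=rms_s2s(stream, window_ms, "gaze"),
        rms_s2s_pupil=rms_s2s(stream, window_ms, "pupil"),
        data_loss=data_loss(stream),
    )
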