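"""Screen geometry, unit conversions, and sample-stream I/O.

Coordinate conventions used throughout the package:

* Gaze positions are expressed in degrees of visual angle relative to the
  screen center, computed with a per-axis tangent mapping that assumes
  perpendicular viewing of a flat screen at a fixed distance.
* x is positive rightward, y is positive **downward** (screen convention),
  so "bottom of the screen" means larger y.
* Pupil size is expressed as diameter in millimeters.  Video-based trackers
  report pupil *area* in arbitrary units; diameter is recovered as
  ``scale * sqrt(area)`` with a setup-specific scale obtained from
  recordings of printed dots of known diameter.
* Missing samples (blinks, data loss) carry NaN in x, y and pupil and a
  False validity flag — never zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "PupilConversion",
    "TargetGrid",
    "SampleStream",
    "InvalidGeometryError",
    "InvalidInputError",
    "SampleParseError",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "pupil_area_to_mm",
    "fit_pupil_conversion",
    "read_samples",
    "write_samples",
]

SAMPLE_COLUMNS = ["t_ms", "eye", "x_deg", "y_deg", "pupil_mm", "valid"]
RAW_COLUMNS = ["t_ms", "eye", "x_px", "y_px", "pupil_area", "valid"]


class InvalidGeometryError(ValueError):
    """Raised for non-positive or otherwise unusable screen geometry."""


class InvalidInputError(ValueError):
    """Raised for inputs that violate an operation's preconditions."""


class SampleParseError(ValueError):
    """Raised when a sample file cannot be parsed; carries context."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and viewing geometry.

    Defaults correspond to a common lab setup: a 24" 1920x1080 monitor
    (53.1 x 29.1 cm) viewed from 93 cm.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 53.1
    height_cm: float = 29.1
    viewing_distance_cm: float = 93.0

    def __post_init__(self) -> None:
        vals = (self.width_px, self.height_px, self.width_cm,
                self.height_cm, self.viewing_distance_cm)
        if any(v <= 0 for v in vals):
            raise InvalidGeometryError(
                f"all geometry fields must be positive, got {vals}")
        aspect_px = self.width_px / self.height_px
        aspect_cm = self.width_cm / self.height_cm
        if abs(aspect_px - aspect_cm) / aspect_cm > 0.10:
            warnings.warn(
                "pixel aspect ratio differs from physical aspect ratio by "
                f"more than 10% ({aspect_px:.3f} vs {aspect_cm:.3f}); "
                "check width/height units", stacklevel=2)

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenGeometry":
        return cls(**{k: d[k] for k in (
            "width_px", "height_px", "width_cm", "height_cm",
            "viewing_distance_cm")})


@dataclass(frozen=True)
class PupilConversion:
    """Scale mapping sqrt(pupil area in arbitrary units) to diameter in mm."""

    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InvalidInputError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class TargetGrid:
    """Ordered fixation-target positions for a calibration/validation phase.

    Order encodes the presentation sequence (left to right, top to bottom).
    """

    role: str  # "calibration" | "validation"
    points: tuple  # of (x_deg, y_deg)

    def __post_init__(self) -> None:
        if self.role not in ("calibration", "validation"):
            raise InvalidInputError(f"unknown grid role {self.role!r}")
        if len(self.points) == 0:
            raise InvalidInputError("target grid needs at least one point")
        object.__setattr__(
            self, "points", tuple((float(x), float(y)) for x, y in self.points))

    @classmethod
    def nine_point(cls, role: str, half_x: float, half_y: float) -> "TargetGrid":
        """3x3 grid spanning ±half_x, ±half_y, ordered left→right, top→bottom.

        y positive downward, so the top row has y = -half_y.
        """
        pts = [(x, y)
               for y in (-half_y, 0.0, half_y)
               for x in (-half_x, 0.0, half_x)]
        return cls(role=role, points=tuple(pts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


# Standard grids from the pupillary-light-reflex protocol: a peripheral
# grid for fitting the artifact model and a more central, disjoint grid
# for validating it at unseen positions.
CALIBRATION_GRID = TargetGrid.nine_point("calibration", 13.5, 6.4)
VALIDATION_GRID = TargetGrid.nine_point("validation", 11.9, 4.8)


@dataclass
class SampleStream:
    """Per-eye gaze/pupil time series, the package's universal currency.

    Arrays are aligned: ``t_ms`` strictly increasing timestamps (ms),
    ``x``/``y`` gaze in degrees (screen-centered), ``pupil`` diameter in mm,
    ``valid`` boolean flags.  Invalid samples hold NaN in x, y, pupil.
    """

    eye: str
    rate_hz: float
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise InvalidInputError(f"eye must be 'left' or 'right', got {self.eye!r}")
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.pupil) == n):
            raise InvalidInputError("sample arrays must have equal length")
        if n == 0:
            raise InvalidInputError("empty sample stream")
        if np.any(np.diff(self.t_ms) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.isfinite(self.pupil) & np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise InvalidInputError("valid flags must match sample count")
        # invalid samples always carry the missing marker
        inv = ~self.valid
        if inv.any():
            self.x[inv] = np.nan
            self.y[inv] = np.nan
            self.pupil[inv] = np.nan

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def copy(self) -> "SampleStream":
        return SampleStream(self.eye, self.rate_hz, self.t_ms.copy(),
                            self.x.copy(), self.y.copy(), self.pupil.copy(),
                            self.valid.copy())

    def with_gaze(self, x: np.ndarray, y: np.ndarray) -> "SampleStream":
        return SampleStream(self.eye, self.rate_hz, self.t_ms.copy(),
                            np.asarray(x, float).copy(),
                            np.asarray(y, float).copy(),
                            self.pupil.copy(), self.valid.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms, "eye": self.eye, "x_deg": self.x,
            "y_deg": self.y, "pupil_mm": self.pupil,
            "valid": self.valid.astype(int),
        })


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def pixels_to_degrees(p, g: ScreenGeometry, *, small_angle: bool = False):
    """Convert pixel coordinates to degrees relative to the screen center.

    Parameters
    ----------
    p
        ``(x_px, y_px)`` scalars or arrays.
    g
        Screen geometry.  Points outside the screen raise a warning but
        are converted anyway (the mapping is defined on the whole plane).
    small_angle
        If True use the linearized mapping ``deg = cm * 180 / (pi * d)``
        instead of the exact ``atan``; documented alternative for
        comparison with pipelines that assume small angles.
    """
    px = np.asarray(p[0], dtype=float)
    py = np.asarray(p[1], dtype=float)
    with np.errstate(invalid="ignore"):
        if (np.any((px < 0) | (px > g.width_px)) or
                np.any((py < 0) | (py > g.height_px))):
            warnings.warn("pixel coordinates outside the screen area",
                          stacklevel=2)
    cx = g.width_px / 2.0
    cy = g.height_px / 2.0
    dx_cm = (px - cx) * g.cm_per_px_x
    dy_cm = (py - cy) * g.cm_per_px_y
    if small_angle:
        x_deg = np.degrees(dx_cm / g.viewing_distance_cm)
        y_deg = np.degrees(dy_cm / g.viewing_distance_cm)
    else:
        x_deg = np.degrees(np.arctan2(dx_cm, g.viewing_distance_cm))
        y_deg = np.degrees(np.arctan2(dy_cm, g.viewing_distance_cm))
    return x_deg, y_deg


def degrees_to_pixels(p, g: ScreenGeometry, *, small_angle: bool = False):
    """Inverse of :func:`pixels_to_degrees` (exact on the screen domain)."""
    x_deg = np.asarray(p[0], dtype=float)
    y_deg = np.asarray(p[1], dtype=float)
    if small_angle:
        dx_cm = np.radians(x_deg) * g.viewing_distance_cm
        dy_cm = np.radians(y_deg) * g.viewing_distance_cm
    else:
        dx_cm = np.tan(np.radians(x_deg)) * g.viewing_distance_cm
        dy_cm = np.tan(np.radians(y_deg)) * g.viewing_distance_cm
    px = g.width_px / 2.0 + dx_cm / g.cm_per_px_x
    py = g.height_px / 2.0 + dy_cm / g.cm_per_px_y
    return px, py


def pupil_area_to_mm(area, c: PupilConversion):
    """Pupil diameter in mm from tracker-reported area in arbitrary units.

    Models the pupil as a disc: diameter is proportional to sqrt(area).
    """
    a = np.asarray(area, dtype=float)
    if np.any(a[np.isfinite(a)] < 0):
        raise InvalidInputError("pupil area must be non-negative")
    return c.scale * np.sqrt(a)


def fit_pupil_conversion(
        pairs: Sequence[tuple[float, float]]) -> PupilConversion:
    """Least-squares scale for ``diameter = scale * sqrt(area)`` (no intercept).

    ``pairs`` holds (true diameter mm, measured area units) from recordings
    of printed dots of known diameter.
    """
    if len(pairs) == 0:
        raise InvalidInputError("need at least one calibration pair")
    d = np.asarray([p[0] for p in pairs], dtype=float)
    a = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(d <= 0) or np.any(a <= 0):
        raise InvalidInputError("diameters and areas must be positive")
    s = np.sqrt(a)
    # one-parameter OLS through the origin
    scale = float(np.dot(s, d) / np.dot(s, s))
    return PupilConversion(scale=scale)


# ---------------------------------------------------------------------------
# Sample-stream files
# ---------------------------------------------------------------------------

def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_samples(path, *, rate_hz: float = 1000.0,
                 geometry: ScreenGeometry | None = None,
                 conversion: PupilConversion | None = None,
                 ) -> dict[str, SampleStream]:
    """Read a delimited sample file into per-eye :class:`SampleStream` s.

    Two dialects are accepted, distinguished by the header:

    * processed: ``t_ms,eye,x_deg,y_deg,pupil_mm,valid``
    * raw:       ``t_ms,eye,x_px,y_px,pupil_area,valid`` — requires
      ``geometry`` and ``conversion`` to convert on load.

    Missing values are empty fields.  Comma and tab separators are both
    accepted.  Returns ``{eye: stream}``.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise SampleParseError(f"{path}: {exc}") from exc

    cols = list(df.columns)
    if cols == SAMPLE_COLUMNS:
        raw = False
    elif cols == RAW_COLUMNS:
        raw = True
        if geometry is None or conversion is None:
            raise SampleParseError(
                f"{path}: raw pixel/area dialect requires geometry and "
                "pupil conversion")
    else:
        missing = [c for c in SAMPLE_COLUMNS if c not in cols]
        raise SampleParseError(
            f"{path}: unexpected header {cols}; missing columns {missing}")

    for col in cols:
        if col == "eye":
            continue
        bad = pd.to_numeric(df[col], errors="coerce")
        # rows that are non-numeric and non-empty are malformed
        malformed = bad.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if malformed.any():
            line = int(malformed.idxmax()) + 2  # +1 header, +1 1-based
            raise SampleParseError(
                f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = bad

    out: dict[str, SampleStream] = {}
    for eye, sub in df.groupby("eye", sort=True):
        t = sub["t_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(
                f"{path}: timestamps for eye {eye!r} not strictly increasing")
        if raw:
            x, y = pixels_to_degrees(
                (sub["x_px"].to_numpy(float), sub["y_px"].to_numpy(float)),
                geometry)
            pupil = pupil_area_to_mm(sub["pupil_area"].to_numpy(float),
                                     conversion)
        else:
            x = sub["x_deg"].to_numpy(dtype=float)
            y = sub["y_deg"].to_numpy(dtype=float)
            pupil = sub["pupil_mm"].to_numpy(dtype=float)
        valid = sub["valid"].to_numpy()
        valid = np.where(np.isnan(valid.astype(float)), 0, valid).astype(bool)
        out[str(eye)] = SampleStream(str(eye), rate_hz, t, x, y, pupil, valid)
    if not out:
        raise SampleParseError(f"{path}: no samples")
    return out


def write_samples(streams, path) -> None:
    """Write one or several streams to a delimited file (lossless round trip).

    ``streams`` may be a single :class:`SampleStream`, an iterable of them,
    or the dict returned by :func:`read_samples`.
    """
    if isinstance(streams, SampleStream):
        streams = [streams]
    elif isinstance(streams, Mapping):
        streams = list(streams.values())
    frames = [s.to_frame() for s in streams]
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
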