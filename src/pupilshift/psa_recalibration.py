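"""Pupil-size-artifact recalibration: fit, invert, correct, validate.

The correction model is a mapping from (true gaze position, pupil
diameter) to the apparent gaze shift the tracker will report, fitted from
calibration data in which observers fixate known targets while luminance
changes sweep the pupil through its range.  Fitting is two-stage:

1. **Local fits** — for each calibration target, ordinary least squares
   of offset on pupil diameter with a 2nd-order polynomial, separately
   for the horizontal and vertical offset:
   ``dx(p) = a0 + a1 p + a2 p²`` and ``dy(p) = b0 + b1 p + b2 p²``.
2. **Coefficient surfaces** — each of the six local coefficients is
   modelled as a 2-D polynomial (default full quadratic, six terms) over
   screen position, fitted by least squares across the targets.  This
   interpolates the artifact continuously across the screen.

The fitted surfaces predict the offset at a *true* position, but a
measured sample only provides the *shifted* position.  The inverse
problem is solved with a dense 3-D lookup table (default 0.1° spatial and
0.1-mm pupil steps): for every (true x, true y, pupil) node the forward
offset is computed, and the offset is recorded at the measured-grid node
nearest to ``true + offset``.  Collisions keep the smallest-|offset|
entry; holes are filled by nearest neighbor.  Correction subtracts the
offset stored at the node nearest to a measured sample; queries outside
the table domain use nearest-neighbor extrapolation.

Models are fitted per eye, since the artifact is idiosyncratic and
mirrored between eyes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import InvalidInputError, SampleStream, TargetGrid
from .psa_quantify import (Epoch, InsufficientDataError, OffsetSeries,
                           bin_median_positions, compute_offsets)
from .quality_metrics import bcea

__all__ = [
    "LocalFit",
    "CoefficientSurface",
    "LookupDomain",
    "LookupTable",
    "PsaModel",
    "ValidationResult",
    "COEFF_NAMES",
    "surface_exponents",
    "fit_local",
    "fit_surfaces",
    "predict_offset",
    "build_lookup",
    "correct_sample",
    "correct_stream",
    "fit_psa_model",
    "validate_model",
]

COEFF_NAMES = ("a0", "a1", "a2", "b0", "b1", "b2")


def surface_exponents(degree: int = 2) -> list[tuple[int, int]]:
    """Exponent pairs (i, j) for the 2-D polynomial basis x^i y^j, i+j<=degree."""
    return [(i, j) for tot in range(degree + 1)
            for i in range(tot, -1, -1) for j in (tot - i,)]


def _design_2d(x: np.ndarray, y: np.ndarray,
               exps: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.stack([x ** i * y ** j for i, j in exps], axis=-1)


@dataclass
class LocalFit:
    """Per-target pupil polynomials for the two offset axes."""

    target: tuple[float, float]
    coeffs_x: np.ndarray        # (a0, a1, a2): deg, deg/mm, deg/mm²
    coeffs_y: np.ndarray        # (b0, b1, b2)
    pupil_support: tuple[float, float]
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        if not (np.all(np.isfinite(self.coeffs_x))
                and np.all(np.isfinite(self.coeffs_y))):
            raise InvalidInputError("local-fit coefficients must be finite")
        if not self.pupil_support[0] < self.pupil_support[1]:
            raise InvalidInputError("pupil support must have positive width")


@dataclass
class CoefficientSurface:
    """2-D polynomial per local coefficient, mapping (x, y) → coefficient.

    ``coeffs[name]`` aligns with ``exponents``; ``residuals[name]`` stores
    the per-target stage-2 least-squares residuals.
    """

    degree: int
    exponents: list[tuple[int, int]]
    coeffs: dict[str, np.ndarray]
    residuals: dict[str, np.ndarray] = field(default_factory=dict)

    def evaluate(self, name: str, x, y) -> np.ndarray:
        X = _design_2d(np.asarray(x, float), np.asarray(y, float),
                       self.exponents)
        return X @ self.coeffs[name]


@dataclass(frozen=True)
class LookupDomain:
    """Bounds of the lookup table in measured-gaze and pupil space."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    pupil_min: float
    pupil_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max
                and self.pupil_min < self.pupil_max):
            raise InvalidInputError("degenerate lookup domain")


@dataclass
class LookupTable:
    """Dense inverse map: measured (x, y, pupil) node → corrective offset."""

    domain: LookupDomain
    spatial_step: float
    pupil_step: float
    x_grid: np.ndarray
    y_grid: np.ndarray
    pupil_grid: np.ndarray
    offset_dx: np.ndarray       # shape (nx, ny, np)
    offset_dy: np.ndarray

    @property
    def max_abs_offset(self) -> float:
        return float(np.max(np.hypot(self.offset_dx, self.offset_dy)))


@dataclass
class PsaModel:
    """Fitted recalibration model for one eye."""

    eye: str
    local_fits: list[LocalFit]
    surfaces: CoefficientSurface
    lookup: LookupTable
    metadata: dict = field(default_factory=dict)

    # -- serialization: surfaces + domain + config; the lookup table is
    #    rebuilt deterministically on load rather than stored. --
    def to_json(self, path) -> None:
        d = {
            "format": "pupilshift-psa-model",
            "version": 1,
            "eye": self.eye,
            "surface_degree": self.surfaces.degree,
            "surface_exponents": self.surfaces.exponents,
            "surface_coeffs": {k: v.tolist()
                               for k, v in self.surfaces.coeffs.items()},
            "local_fits": [
                {"target": list(lf.target),
                 "coeffs_x": lf.coeffs_x.tolist(),
                 "coeffs_y": lf.coeffs_y.tolist(),
                 "pupil_support": list(lf.pupil_support),
                 "n_samples": lf.n_samples} for lf in self.local_fits],
            "domain": vars(self.lookup.domain),
            "spatial_step": self.lookup.spatial_step,
            "pupil_step": self.lookup.pupil_step,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "PsaModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "pupilshift-psa-model":
            raise InvalidInputError(f"{path}: not a PSA model file")
        surfaces = CoefficientSurface(
            degree=d["surface_degree"],
            exponents=[tuple(e) for e in d["surface_exponents"]],
            coeffs={k: np.asarray(v)
                    for k, v in d["surface_coeffs"].items()})
        local_fits = [LocalFit(tuple(lf["target"]),
                               np.asarray(lf["coeffs_x"]),
                               np.asarray(lf["coeffs_y"]),
                               tuple(lf["pupil_support"]),
                               lf.get("n_samples", 0))
                      for lf in d["local_fits"]]
        domain = LookupDomain(**d["domain"])
        lookup = build_lookup(surfaces, domain, d["spatial_step"],
                              d["pupil_step"])
        return cls(d["eye"], local_fits, surfaces, lookup,
                   d.get("metadata", {}))


@dataclass
class ValidationResult:
    """Before/after accuracy and dispersion on held-out validation targets."""

    targets: list[tuple[float, float]]
    offset_before: np.ndarray   # per target, deg
    offset_after: np.ndarray
    bcea_before: np.ndarray     # per target, deg²
    bcea_after: np.ndarray

    @staticmethod
    def _reduction(before: np.ndarray, after: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 1.0 - after / before
        return np.where(before > 0, r, np.nan)

    @property
    def offset_reductions(self) -> np.ndarray:
        return self._reduction(self.offset_before, self.offset_after)

    @property
    def bcea_reductions(self) -> np.ndarray:
        return self._reduction(self.bcea_before, self.bcea_after)

    def summary(self) -> dict:
        def med_iqr(v):
            v = v[np.isfinite(v)]
            if len(v) == 0:
                return {"median": None, "iqr": [None, None]}
            q25, q50, q75 = np.percentile(v, [25, 50, 75])
            return {"median": float(q50), "iqr": [float(q25), float(q75)]}
        return {
            "offset_before": med_iqr(self.offset_before),
            "offset_after": med_iqr(self.offset_after),
            "offset_reduction": med_iqr(self.offset_reductions),
            "bcea_before": med_iqr(self.bcea_before),
            "bcea_after": med_iqr(self.bcea_after),
            "bcea_reduction": med_iqr(self.bcea_reductions),
        }


# ---------------------------------------------------------------------------
# Stage 1: per-target pupil polynomials
# ---------------------------------------------------------------------------

def fit_local(series: OffsetSeries) -> LocalFit:
    """OLS 2nd-order polynomials of offset on pupil diameter for one target."""
    p = series.pupil
    ok = np.isfinite(p) & np.isfinite(series.dx) & np.isfinite(series.dy)
    p, dx, dy = p[ok], series.dx[ok], series.dy[ok]
    if len(np.unique(p)) < 3:
        raise InsufficientDataError(
            "need >= 3 distinct pupil values for a quadratic fit, got "
            f"{len(np.unique(p))}")
    X = np.stack([np.ones_like(p), p, p * p], axis=1)
    cx, *_ = np.linalg.lstsq(X, dx, rcond=None)
    cy, *_ = np.linalg.lstsq(X, dy, rcond=None)
    return LocalFit(target=series.target, coeffs_x=cx, coeffs_y=cy,
                    pupil_support=(float(p.min()), float(p.max())),
                    n_samples=int(len(p)))


def local_fit_standard_errors(series: OffsetSeries
                              ) -> tuple[np.ndarray, np.ndarray]:
    """OLS standard errors of the stage-1 coefficients (per axis)."""
    p = series.pupil
    ok = np.isfinite(p) & np.isfinite(series.dx) & np.isfinite(series.dy)
    p, dx, dy = p[ok], series.dx[ok], series.dy[ok]
    X = np.stack([np.ones_like(p), p, p * p], axis=1)
    XtX_inv = np.linalg.inv(X.T @ X)
    dof = len(p) - 3
    out = []
    for yv in (dx, dy):
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        s2 = float(resid @ resid) / dof
        out.append(np.sqrt(s2 * np.diag(XtX_inv)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Stage 2: coefficient surfaces over screen position
# ---------------------------------------------------------------------------

def fit_surfaces(local_fits: Sequence[LocalFit],
                 degree: int = 2) -> CoefficientSurface:
    """Least-squares 2-D polynomial surfaces through the local coefficients."""
    exps = surface_exponents(degree)
    n_terms = len(exps)
    if len(local_fits) < n_terms:
        raise InsufficientDataError(
            f"degree-{degree} surfaces need >= {n_terms} targets, got "
            f"{len(local_fits)}")
    tx = np.asarray([lf.target[0] for lf in local_fits])
    ty = np.asarray([lf.target[1] for lf in local_fits])
    X = _design_2d(tx, ty, exps)
    coeffs: dict[str, np.ndarray] = {}
    residuals: dict[str, np.ndarray] = {}
    stacked = {
        "a0": [lf.coeffs_x[0] for lf in local_fits],
        "a1": [lf.coeffs_x[1] for lf in local_fits],
        "a2": [lf.coeffs_x[2] for lf in local_fits],
        "b0": [lf.coeffs_y[0] for lf in local_fits],
        "b1": [lf.coeffs_y[1] for lf in local_fits],
        "b2": [lf.coeffs_y[2] for lf in local_fits],
    }
    for name, vals in stacked.items():
        v = np.asarray(vals, dtype=float)
        c, *_ = np.linalg.lstsq(X, v, rcond=None)
        coeffs[name] = c
        residuals[name] = v - X @ c
    return CoefficientSurface(degree=degree, exponents=exps, coeffs=coeffs,
                              residuals=residuals)


def predict_offset(surfaces: CoefficientSurface, x, y, pupil,
                   pupil_domain: tuple[float, float] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: apparent gaze shift at true position (x, y), pupil p.

    Evaluates the six coefficient surfaces at the position, then the two
    pupil polynomials at p.  If ``pupil_domain`` is given, p is clamped to
    it first (guards against extrapolating the quadratic in pupil).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(pupil, dtype=float)
    if pupil_domain is not None:
        p = np.clip(p, pupil_domain[0], pupil_domain[1])
    a0 = surfaces.evaluate("a0", x, y)
    a1 = surfaces.evaluate("a1", x, y)
    a2 = surfaces.evaluate("a2", x, y)
    b0 = surfaces.evaluate("b0", x, y)
    b1 = surfaces.evaluate("b1", x, y)
    b2 = surfaces.evaluate("b2", x, y)
    dx = a0 + a1 * p + a2 * p * p
    dy = b0 + b1 * p + b2 * p * p
    return dx, dy


# ---------------------------------------------------------------------------
# Stage 3: dense inverse lookup table
# ---------------------------------------------------------------------------

def build_lookup(surfaces: CoefficientSurface, domain: LookupDomain,
                 spatial_step: float = 0.1, pupil_step: float = 0.1
                 ) -> LookupTable:
    """Invert the forward offset map onto a dense measured-space grid.

    For every (true x, true y, pupil) node the forward offset is computed
    and recorded at the measured-grid node nearest to ``true + offset``.
    Where several true nodes land on one measured node, the entry with the
    smallest |offset| wins; measured nodes hit by no true node are filled
    from their nearest populated neighbor (per pupil slice).  The
    construction is fully deterministic.
    """
    if spatial_step <= 0 or pupil_step <= 0:
        raise InvalidInputError("grid steps must be positive")
    xg = np.arange(domain.x_min, domain.x_max + spatial_step / 2, spatial_step)
    yg = np.arange(domain.y_min, domain.y_max + spatial_step / 2, spatial_step)
    pg = np.arange(domain.pupil_min, domain.pupil_max + pupil_step / 2,
                   pupil_step)
    nx, ny, npp = len(xg), len(yg), len(pg)
    off_dx = np.full((nx, ny, npp), np.nan)
    off_dy = np.full((nx, ny, npp), np.nan)

    X, Y = np.meshgrid(xg, yg, indexing="ij")
    xf, yf = X.ravel(), Y.ravel()
    pupil_domain = (domain.pupil_min, domain.pupil_max)
    for k, p in enumerate(pg):
        dx, dy = predict_offset(surfaces, xf, yf, p, pupil_domain)
        mx, my = xf + dx, yf + dy
        ix = np.rint((mx - xg[0]) / spatial_step).astype(np.int64)
        iy = np.rint((my - yg[0]) / spatial_step).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix, iy = ix[inside], iy[inside]
        dxi, dyi = dx[inside], dy[inside]
        mag = np.hypot(dxi, dyi)
        flat = ix * ny + iy
        # sort by descending |offset| so the smallest overwrites last
        order = np.lexsort((-mag, flat))
        slice_dx = np.full(nx * ny, np.nan)
        slice_dy = np.full(nx * ny, np.nan)
        slice_dx[flat[order]] = dxi[order]
        slice_dy[flat[order]] = dyi[order]
        filled = np.isfinite(slice_dx)
        if not filled.all() and filled.any():
            # nearest-neighbor hole filling within the slice
            fx = (np.arange(nx * ny) // ny)
            fy = (np.arange(nx * ny) % ny)
            tree = cKDTree(np.stack([fx[filled], fy[filled]], axis=1))
            holes = ~filled
            _, nn = tree.query(np.stack([fx[holes], fy[holes]], axis=1), k=1)
            src = np.flatnonzero(filled)[nn]
            slice_dx[holes] = slice_dx[src]
            slice_dy[holes] = slice_dy[src]
        off_dx[:, :, k] = slice_dx.reshape(nx, ny)
        off_dy[:, :, k] = slice_dy.reshape(nx, ny)

    return LookupTable(domain=domain, spatial_step=spatial_step,
                       pupil_step=pupil_step, x_grid=xg, y_grid=yg,
                       pupil_grid=pg, offset_dx=off_dx, offset_dy=off_dy)


def correct_sample(lookup: LookupTable, x, y, pupil
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the stored offset at the nearest lookup node.

    Out-of-domain queries (position or pupil) use the nearest in-domain
    node, i.e. nearest-neighbor extrapolation.  Vectorized; NaNs pass
    through unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(pupil, dtype=float)
    with np.errstate(invalid="ignore"):
        ix = np.clip(np.rint((x - lookup.x_grid[0]) / lookup.spatial_step),
                     0, len(lookup.x_grid) - 1)
        iy = np.clip(np.rint((y - lookup.y_grid[0]) / lookup.spatial_step),
                     0, len(lookup.y_grid) - 1)
        ip = np.clip(np.rint((p - lookup.pupil_grid[0]) / lookup.pupil_step),
                     0, len(lookup.pupil_grid) - 1)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(p)
    ix = np.where(ok, ix, 0).astype(np.int64)
    iy = np.where(ok, iy, 0).astype(np.int64)
    ip = np.where(ok, ip, 0).astype(np.int64)
    dx = lookup.offset_dx[ix, iy, ip]
    dy = lookup.offset_dy[ix, iy, ip]
    cx = np.where(ok, x - dx, x)
    cy = np.where(ok, y - dy, y)
    return cx, cy


def correct_stream(model: PsaModel, stream: SampleStream) -> SampleStream:
    """Apply the lookup correction element-wise to a whole stream."""
    cx, cy = correct_sample(model.lookup, stream.x, stream.y, stream.pupil)
    return stream.with_gaze(cx, cy)


# ---------------------------------------------------------------------------
# End-to-end fit and validation
# ---------------------------------------------------------------------------

def fit_psa_model(stream: SampleStream, grid: TargetGrid,
                  epochs: Sequence[Epoch], *, surface_degree: int = 2,
                  spatial_step: float = 0.1, pupil_step: float = 0.1,
                  domain_margin_deg: float = 2.0) -> PsaModel:
    """Fit the full two-stage model and build its lookup table.

    The lookup domain covers the calibration grid plus
    ``domain_margin_deg`` on each side, and the pupil range observed
    across targets.
    """
    if grid.role != "calibration":
        raise InvalidInputError("model must be fitted on a calibration grid")
    series = compute_offsets(stream, grid, epochs)
    local_fits = [fit_local(s) for s in series]
    surfaces = fit_surfaces(local_fits, degree=surface_degree)
    pts = grid.as_array()
    domain = LookupDomain(
        x_min=float(pts[:, 0].min() - domain_margin_deg),
        x_max=float(pts[:, 0].max() + domain_margin_deg),
        y_min=float(pts[:, 1].min() - domain_margin_deg),
        y_max=float(pts[:, 1].max() + domain_margin_deg),
        pupil_min=min(lf.pupil_support[0] for lf in local_fits),
        pupil_max=max(lf.pupil_support[1] for lf in local_fits),
    )
    lookup = build_lookup(surfaces, domain, spatial_step, pupil_step)
    meta = {
        "calibration_role": grid.role,
        "surface_degree": surface_degree,
        "spatial_step": spatial_step,
        "pupil_step": pupil_step,
        "domain_margin_deg": domain_margin_deg,
        "collision_rule": "smallest-abs-offset",
        "hole_fill": "nearest-neighbor",
    }
    return PsaModel(eye=stream.eye, local_fits=local_fits, surfaces=surfaces,
                    lookup=lookup, metadata=meta)


def validate_model(model: PsaModel, stream: SampleStream, grid: TargetGrid,
                   epochs: Sequence[Epoch], *, bin_width: float = 0.1
                   ) -> ValidationResult:
    """Accuracy/dispersion before vs. after correction on held-out targets.

    For each validation target, gaze samples are resampled into fixed-width
    pupil bins; per-bin median positions give (a) the absolute offset
    (median over bins of the Euclidean distance to the target) and (b) the
    dispersion (68% BCEA over the per-bin medians).  Validation must use a
    grid disjoint from calibration to avoid circularity.
    """
    if grid.role == model.metadata.get("calibration_role", "calibration") \
            and grid.role == "calibration":
        raise InvalidInputError(
            "validation requires a grid with role 'validation', disjoint "
            "from the calibration grid")
    corrected = correct_stream(model, stream)
    targets = list(grid.points)
    ob, oa, bb, ba = [], [], [], []
    for k, (tx, ty) in enumerate(targets):
        before = bin_median_positions(stream, epochs, k, bin_width)
        after = bin_median_positions(corrected, epochs, k, bin_width)
        for med, accu, disp in ((before, ob, bb), (after, oa, ba)):
            if len(med) == 0:
                accu.append(np.nan)
                disp.append(np.nan)
                continue
            dist = np.hypot(med[:, 1] - tx, med[:, 2] - ty)
            accu.append(float(np.median(dist)))
            disp.append(bcea(med[:, 1:3]) if len(med) >= 3 else np.nan)
    return ValidationResult(targets=targets,
                            offset_before=np.asarray(ob),
                            offset_after=np.asarray(oa),
                            bcea_before=np.asarray(bb),
                            bcea_after=np.asarray(ba))
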