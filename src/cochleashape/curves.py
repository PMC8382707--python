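"""Canonical representation of open 3D semi-landmark curves.

A cochlear midline is digitized as an ordered polyline from the basal turn to
the apex.  This module owns resampling to a fixed number of semi-landmarks,
translation/size normalisation, the square-root-velocity (SRVF) transform and
its inverse, and the CSV dialect used to exchange curves between stages.

Conventions
-----------
* Curves are OPEN, oriented base -> apex.
* Left-side curves are mirrored across the x = 0 plane before analysis so all
  specimens share chirality (see :func:`mirror_x`).
* Size removal scales a curve to unit arc length; the SRVF of a unit-length
  curve has (discrete) unit L2 norm, putting shapes on the unit sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Curve3D",
    "SRVFCurve",
    "DegenerateCurveError",
    "arc_length",
    "resample_by_arclength",
    "center_and_scale",
    "mirror_x",
    "to_srvf",
    "from_srvf",
    "read_curves_csv",
    "write_curves_csv",
]

CURVE_CSV_COLUMNS = ["specimen_id", "side", "point_index", "x", "y", "z"]


class DegenerateCurveError(ValueError):
    """Raised when a curve has zero total arc length (invalid specimen)."""


@dataclass(frozen=True)
class Curve3D:
    """Ordered 3D polyline with specimen metadata.

    Parameters
    ----------
    points
        (N, 3) array of coordinates, N >= 3, all finite.
    specimen_id
        Specimen identifier used in file exchange and tie-breaking.
    side
        One of ``left``, ``right``, ``unknown``.
    """

    points: np.ndarray
    specimen_id: str = ""
    side: str = "unknown"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] < 3:
            raise ValueError("a curve needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("curve coordinates must be finite")
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"invalid side {self.side!r}")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "Curve3D":
        return replace(self, points=points)


@dataclass(frozen=True)
class SRVFCurve:
    """Square-root-velocity representation q(t) = c'(t)/sqrt(|c'(t)|).

    ``q`` is sampled on the uniform grid on [0, 1].  ``norm_flag`` records
    whether the discrete L2 norm has been scaled to exactly 1 (shape-sphere
    convention after size removal).
    """

    q: np.ndarray
    norm_flag: bool = False
    specimen_id: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[1] != 3:
            raise ValueError("q must be an (N, 3) array")
        object.__setattr__(self, "q", q)
        if self.norm_flag and abs(l2_norm(q) - 1.0) > 1e-9:
            raise ValueError("norm_flag set but ||q|| != 1")

    @property
    def n_points(self) -> int:
        return self.q.shape[0]


def _grid(n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def l2_inner(q1: np.ndarray, q2: np.ndarray) -> float:
    """Discrete L2 inner product on the uniform [0, 1] grid (trapezoid rule)."""
    prod = np.einsum("ij,ij->i", q1, q2)
    return float(np.trapezoid(prod, _grid(len(prod))))


def l2_norm(q: np.ndarray) -> float:
    return float(np.sqrt(max(l2_inner(q, q), 0.0)))


def arc_length(curve: Curve3D | np.ndarray) -> float:
    """Total chord length of the polyline."""
    pts = curve.points if isinstance(curve, Curve3D) else np.asarray(curve, float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _cumulative_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_by_arclength(curve: Curve3D, n_points: int) -> Curve3D:
    """Resample to ``n_points`` equally spaced in cumulative chord length.

    The endpoints of the input are preserved exactly.  Raises
    :class:`DegenerateCurveError` for zero-length curves.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = curve.points
    s = _cumulative_arclength(pts)
    total = s[-1]
    if total <= 0.0:
        raise DegenerateCurveError(
            f"curve {curve.specimen_id!r} has zero arc length"
        )
    # collapse exactly-duplicated consecutive points so interp is well defined
    keep = np.concatenate([[True], np.diff(s) > 0])
    s, pts = s[keep], pts[keep]

    def _at(params):
        return np.column_stack(
            [np.interp(params, s, pts[:, k]) for k in range(3)])

    # fixed-point iteration: choose parameters along the input polyline so
    # that the OUTPUT polyline has exactly equal chord lengths (this makes
    # the operation idempotent to machine precision)
    target = np.linspace(0.0, total, n_points)
    for _ in range(20):
        new = _at(target)
        chord = np.linalg.norm(np.diff(new, axis=0), axis=1)
        C = np.concatenate([[0.0], np.cumsum(chord)])
        if np.abs(np.diff(C) - C[-1] / (n_points - 1)).max() < 1e-13 * total:
            break
        want = np.linspace(0.0, C[-1], n_points)
        target = np.interp(want, C, target)
    new[0], new[-1] = curve.points[0], curve.points[-1]
    return curve.with_points(new)


def center_and_scale(curve: Curve3D) -> Curve3D:
    """Translate the centroid to the origin and scale to unit arc length."""
    total = arc_length(curve)
    if total <= 0.0:
        raise DegenerateCurveError(
            f"curve {curve.specimen_id!r} has zero arc length"
        )
    pts = curve.points / total
    return curve.with_points(pts - pts.mean(axis=0))


def mirror_x(curve: Curve3D) -> Curve3D:
    """Reflect across the x = 0 plane (used to pool left/right sides)."""
    pts = curve.points.copy()
    pts[:, 0] *= -1.0
    new_side = {"left": "right", "right": "left"}.get(curve.side, "unknown")
    return replace(curve, points=pts, side=new_side)


def _derivative(pts: np.ndarray, h: float) -> np.ndarray:
    """Fourth-order finite differences (one-sided stencils at the edges)."""
    n = pts.shape[0]
    d = np.empty_like(pts)
    if n >= 5:
        d[2:-2] = (pts[:-4] - 8 * pts[1:-3] + 8 * pts[3:-1] - pts[4:]) / (12 * h)
        d[0] = (-25 * pts[0] + 48 * pts[1] - 36 * pts[2]
                + 16 * pts[3] - 3 * pts[4]) / (12 * h)
        d[1] = (-3 * pts[0] - 10 * pts[1] + 18 * pts[2]
                - 6 * pts[3] + pts[4]) / (12 * h)
        d[-2] = (3 * pts[-1] + 10 * pts[-2] - 18 * pts[-3]
                 + 6 * pts[-4] - pts[-5]) / (12 * h)
        d[-1] = (25 * pts[-1] - 48 * pts[-2] + 36 * pts[-3]
                 - 16 * pts[-4] + 3 * pts[-5]) / (12 * h)
    else:
        d[1:-1] = (pts[2:] - pts[:-2]) / (2 * h)
        d[0] = (pts[1] - pts[0]) / h
        d[-1] = (pts[-1] - pts[-2]) / h
    return d


def to_srvf(curve: Curve3D) -> SRVFCurve:
    """SRVF transform on the uniform parameter grid.

    Derivatives are centred finite differences (fourth order in the
    interior, one-sided at the endpoints); at points of vanishing speed q is
    set to zero.
    """
    pts = curve.points
    n = pts.shape[0]
    deriv = _derivative(pts, 1.0 / (n - 1))
    speed = np.linalg.norm(deriv, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = deriv / np.sqrt(speed)[:, None]
    q[speed == 0.0] = 0.0
    return SRVFCurve(q=q, norm_flag=False, specimen_id=curve.specimen_id)


def normalize_srvf(q: SRVFCurve) -> SRVFCurve:
    """Scale q to exact unit L2 norm (projection onto the shape sphere)."""
    nrm = l2_norm(q.q)
    if nrm <= 0.0:
        raise DegenerateCurveError("cannot normalise a zero SRVF")
    return SRVFCurve(q=q.q / nrm, norm_flag=True, specimen_id=q.specimen_id)


def from_srvf(q: SRVFCurve, start_point=(0.0, 0.0, 0.0)) -> Curve3D:
    """Integrate an SRVF back to a curve anchored at ``start_point``.

    Round trip ``from_srvf(to_srvf(c), c[0])`` reproduces ``c`` up to
    resampling error.  A zero q yields a degenerate curve and raises.
    """
    qa = q.q
    n = qa.shape[0]
    speed = np.linalg.norm(qa, axis=1)
    deriv = qa * speed[:, None]  # c'(t) = q |q|
    t = _grid(n)
    # smooth antiderivative (cubic-spline quadrature): unlike the trapezoid
    # rule its error does not oscillate point-to-point, so the reconstructed
    # curve is clean at the derivative (SRVF) level too
    from scipy.interpolate import CubicSpline

    pts = CubicSpline(t, deriv, axis=0).antiderivative()(t)
    pts = pts + np.asarray(start_point, dtype=float)
    if arc_length(pts) <= 0.0:
        raise DegenerateCurveError("zero SRVF integrates to a degenerate curve")
    return Curve3D(points=pts, specimen_id=q.specimen_id)


def shape_srvf(curve: Curve3D, n_points: int = 200) -> SRVFCurve:
    """Full preprocessing: resample, centre/scale, SRVF, unit-norm projection."""
    c = resample_by_arclength(curve, n_points)
    c = center_and_scale(c)
    return normalize_srvf(to_srvf(c))


# ---------------------------------------------------------------------------
# CSV dialect: specimen_id,side,point_index,x,y,z


def write_curves_csv(curves, path) -> None:
    rows = []
    for c in curves:
        for i, (x, y, z) in enumerate(c.points):
            rows.append((c.specimen_id, c.side, i, x, y, z))
    pd.DataFrame(rows, columns=CURVE_CSV_COLUMNS).to_csv(path, index=False)


def read_curves_csv(path) -> list[Curve3D]:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve CSV missing columns {missing}")
    curves = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"specimen {sid!r}: point_index must be 0..N-1 without gaps"
            )
        side = grp["side"].iloc[0]
        curves.append(
            Curve3D(
                points=grp[["x", "y", "z"]].to_numpy(float),
                specimen_id=str(sid),
                side=str(side),
            )
        )
    return curves
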