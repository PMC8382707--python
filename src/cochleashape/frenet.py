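"""Curvature and torsion profiles along a 3D curve (Frenet-Serret maps).

kappa(s) measures local bending (rate of change of the unit tangent), tau(s)
the twist of the osculating plane out of itself.  Both are estimated from
smoothing-spline derivatives fitted per coordinate against arc length:

    kappa = |c' x c''| / |c'|^3
    tau   = (c' x c'') . c''' / |c' x c''|^2

Torsion is undefined where curvature vanishes; such points (and the first
and last three samples, where spline derivatives are one-sided in spirit)
are flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .curves import Curve3D, DegenerateCurveError, _cumulative_arclength

__all__ = ["FrenetProfile", "frenet_profile", "profile_of_mean",
           "export_profile", "read_profile"]

_EDGE_FLAG = 3  # samples flagged lower-confidence at each end


@dataclass(frozen=True)
class FrenetProfile:
    """Arc-length-indexed curvature/torsion map of one curve."""

    s: np.ndarray            # normalized arc-length positions in [0, 1]
    kappa: np.ndarray        # curvature, 1/length units, >= 0 where valid
    tau: np.ndarray          # torsion, signed, 1/length units
    kappa_valid: np.ndarray  # bool flags
    tau_valid: np.ndarray

    def __len__(self) -> int:
        return len(self.s)


def frenet_profile(
    curve: Curve3D,
    smoothing: float = 0.0,
    kappa_floor: float | None = None,
) -> FrenetProfile:
    """Curvature/torsion profile of one curve.

    Parameters
    ----------
    smoothing
        Smoothing factor of the per-coordinate spline (scipy ``s`` residual
        budget, in squared length units).  0 interpolates — appropriate for
        noiseless or pre-smoothed curves; raise it for digitisation noise.
    kappa_floor
        Curvature below which torsion is flagged undefined.  Defaults to
        ``1e-6 / arc_length`` (torsion's denominator vanishes with kappa).
    """
    pts = curve.points
    n = pts.shape[0]
    if n < 7:
        raise ValueError("Frenet estimation needs at least 7 points")
    s_raw = _cumulative_arclength(pts)
    total = s_raw[-1]
    if total <= 0:
        raise DegenerateCurveError("degenerate curve: zero arc length")
    if kappa_floor is None:
        kappa_floor = 1e-6 / total
    # strictly increasing abscissa for the spline
    keep = np.concatenate([[True], np.diff(s_raw) > 0])
    s_fit, pts_fit = s_raw[keep], pts[keep]
    k = 5 if len(s_fit) > 5 else 3
    d1 = np.empty((n, 3))
    d2 = np.empty((n, 3))
    d3 = np.empty((n, 3))
    for dim in range(3):
        spl = UnivariateSpline(s_fit, pts_fit[:, dim], k=k, s=smoothing)
        d1[:, dim] = spl.derivative(1)(s_raw)
        d2[:, dim] = spl.derivative(2)(s_raw)
        d3[:, dim] = spl.derivative(3)(s_raw)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(d1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = cross_norm / speed**3
        tau = np.einsum("ij,ij->i", cross, d3) / cross_norm**2
    kappa_valid = np.isfinite(kappa)
    tau_valid = kappa_valid & np.isfinite(tau) & (kappa > kappa_floor)
    edge = np.zeros(n, dtype=bool)
    edge[:_EDGE_FLAG] = edge[-_EDGE_FLAG:] = True
    kappa_valid &= ~edge
    tau_valid &= ~edge
    kappa = np.where(np.isfinite(kappa), kappa, 0.0)
    tau = np.where(np.isfinite(tau), tau, 0.0)
    return FrenetProfile(
        s=s_raw / total, kappa=kappa, tau=tau,
        kappa_valid=kappa_valid, tau_valid=tau_valid,
    )


def profile_of_mean(curves: list[Curve3D], smoothing: float = 0.0,
                    n_points: int = 200) -> FrenetProfile:
    """Frenet profile of the Fréchet mean of a group of curves."""
    from .elastic import frechet_mean

    if len(curves) < 2:
        raise ValueError("need at least two curves")
    mean = frechet_mean(curves, n_points=n_points)
    return frenet_profile(mean, smoothing=smoothing)


def export_profile(profile: FrenetProfile, path) -> None:
    """Write ``s,kappa,tau,kappa_valid,tau_valid`` CSV (lossless round trip)."""
    pd.DataFrame(
        {
            "s": profile.s,
            "kappa": profile.kappa,
            "tau": profile.tau,
            "kappa_valid": profile.kappa_valid.astype(int),
            "tau_valid": profile.tau_valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_profile(path) -> FrenetProfile:
    df = pd.read_csv(path)
    expected = ["s", "kappa", "tau", "kappa_valid", "tau_valid"]
    if list(df.columns) != expected:
        raise ValueError(f"profile CSV must have columns {expected}")
    return FrenetProfile(
        s=df["s"].to_numpy(float),
        kappa=df["kappa"].to_numpy(float),
        tau=df["tau"].to_numpy(float),
        kappa_valid=df["kappa_valid"].to_numpy(bool),
        tau_valid=df["tau_valid"].to_numpy(bool),
    )
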