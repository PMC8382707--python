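"""Linear/angular bony-labyrinth indices and measurement-error statistics.

The labyrinth measurement table carries, per specimen, the transverse
labyrinthine index (TLI), two inclination angles of the ampular line and the
cochlear basal turn relative to the lateral semicircular canal plane
(APA_LSCm, COs_LSCm, degrees), the arc lengths of the horizontal, posterior
and anterior semicircular canals (HZL, POL, ANL, mm) and the cochlear length
(ECL, mm).  TLI and the angles are measured on images and arrive here as
numbers; this module derives the seven ratio indices, their standardized
PCA, repeatability statistics (ICC, Procrustes permutation test) and the
generalized-Procrustes + PCA baseline used to contrast with tangent PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabyrinthMeasurements",
    "MEASUREMENT_COLUMNS",
    "INDEX_COLUMNS",
    "read_measurements_csv",
    "compute_indices",
    "index_pca",
    "icc",
    "procrustes_permutation_test",
    "gpa",
    "gpa_pca",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["TLI", "APA_LSCm", "COs_LSCm", "HZL", "POL", "ANL", "ECL"]
INDEX_COLUMNS = [
    "TLI", "APA_LSCm", "COs_LSCm",
    "HZL/ANL", "HZL/POL", "POL/ANL",
    "ECL/HZL", "ECL/POL", "ECL/ANL",
]
_LENGTHS = ["HZL", "POL", "ANL", "ECL"]
_ANGLES = ["APA_LSCm", "COs_LSCm"]


@dataclass(frozen=True)
class LabyrinthMeasurements:
    """Per-specimen measurement table (NaN marks missing values)."""

    table: pd.DataFrame  # indexed by specimen_id, columns MEASUREMENT_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        for c in _LENGTHS:
            vals = self.table[c].dropna()
            if (vals <= 0).any():
                raise ValueError(f"nonpositive arc length in column {c}")
        for c in _ANGLES:
            vals = self.table[c].dropna()
            if ((vals <= 0) | (vals >= 180)).any():
                raise ValueError(f"angle out of (0, 180) in column {c}")


def read_measurements_csv(path) -> LabyrinthMeasurements:
    df = pd.read_csv(path).set_index("specimen_id")
    return LabyrinthMeasurements(table=df[MEASUREMENT_COLUMNS].astype(float))


def compute_indices(m: LabyrinthMeasurements) -> pd.DataFrame:
    """The two angles, TLI and the six ratio indices per specimen.

    Ratios are exact arithmetic on the inputs; a missing measurement masks
    (NaN) every index that depends on it — e.g. a damaged anterior canal
    (missing ANL) masks HZL/ANL, POL/ANL and ECL/ANL while the remaining
    columns stay usable.
    """
    t = m.table
    out = pd.DataFrame(index=t.index)
    out["TLI"] = t["TLI"]
    out["APA_LSCm"] = t["APA_LSCm"]
    out["COs_LSCm"] = t["COs_LSCm"]
    out["HZL/ANL"] = t["HZL"] / t["ANL"]
    out["HZL/POL"] = t["HZL"] / t["POL"]
    out["POL/ANL"] = t["POL"] / t["ANL"]
    out["ECL/HZL"] = t["ECL"] / t["HZL"]
    out["ECL/POL"] = t["ECL"] / t["POL"]
    out["ECL/ANL"] = t["ECL"] / t["ANL"]
    return out


def index_pca(table: pd.DataFrame, columns=None, standardize: bool = True):
    """PCA of the index table on complete rows of the selected columns.

    Columns are z-standardized by default (angles and ratios live on very
    different scales).  Constant columns are dropped with a warning.
    Returns ``(scores, loadings, variance_fractions)``; loadings are indexed
    by variable and ordered PC1, PC2, ...; rank variables by ``|PC1|`` to
    read off the dominant contributors.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols].dropna(axis=0, how="any")
    if len(sub) < 3:
        raise ValueError("index PCA needs at least 3 complete specimens")
    X = sub.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    const = sd <= 1e-12 * (np.abs(X).mean(axis=0) + 1.0)
    if const.any():
        dropped = [c for c, flag in zip(cols, const) if flag]
        warnings.warn(f"dropping constant columns {dropped}")
        cols = [c for c, flag in zip(cols, const) if not flag]
        X, sd = X[:, ~const], sd[~const]
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    scores = pd.DataFrame(
        Xc @ Vt.T, index=sub.index,
        columns=[f"PC{i+1}" for i in range(Vt.shape[0])],
    )
    loadings = pd.DataFrame(
        Vt.T, index=cols, columns=[f"PC{i+1}" for i in range(Vt.shape[0])]
    )
    return scores, loadings, fractions


def icc(session1: pd.DataFrame, session2: pd.DataFrame) -> pd.Series:
    """ICC(2,1) per variable across two measurement sessions.

    Two-way random effects, absolute agreement, single rater:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with n specimens, k = 2 sessions, MS_R/MS_C/MS_E the row (specimen),
    column (session) and residual mean squares.  Zero between-specimen
    variance makes the coefficient undefined (returned as NaN).
    """
    if not session1.index.equals(session2.index):
        raise ValueError("sessions must cover the same specimens")
    if len(session1) < 3:
        raise ValueError("ICC needs at least 3 specimens")
    out = {}
    k = 2
    for col in session1.columns:
        y = np.column_stack([session1[col].to_numpy(float),
                             session2[col].to_numpy(float)])
        mask = np.all(np.isfinite(y), axis=1)
        y = y[mask]
        n = y.shape[0]
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        ss_r = k * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_c = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_e = ss_tot - ss_r - ss_c
        ms_r = ss_r / (n - 1)
        ms_c = ss_c / (k - 1)
        ms_e = ss_e / ((n - 1) * (k - 1))
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        if denom <= 0:
            out[col] = np.nan
            logger.warning("ICC undefined for %s (no between-specimen variance)", col)
        else:
            out[col] = (ms_r - ms_e) / denom
    return pd.Series(out)


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    g = X @ X.T
    d = np.diag(g)
    return np.maximum(d[:, None] + d[None, :] - 2 * g, 0.0)


def procrustes_permutation_test(
    distance_matrix: np.ndarray,
    specimen_ids: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Between- vs within-repeat shape distance permutation test.

    ``distance_matrix`` holds pairwise shape distances between 2*n curve
    placements (each specimen placed twice); ``specimen_ids`` labels each
    placement with its specimen.  The statistic is the mean between-specimen
    distance minus the mean within-repeat distance; the null permutes the
    placement-to-specimen assignment.  Returns ``(statistic, p)`` with
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    D = np.asarray(distance_matrix, float)
    ids = np.asarray(specimen_ids)
    n = D.shape[0]
    if D.shape != (n, n) or len(ids) != n:
        raise ValueError("distance matrix / ids size mismatch")
    uniq = np.unique(ids)
    if len(uniq) < 5:
        raise ValueError("need at least 5 specimens with repeats")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    iu = np.triu_indices(n, k=1)

    def stat(labels):
        same = labels[iu[0]] == labels[iu[1]]
        d = D[iu]
        return d[~same].mean() - d[same].mean()

    observed = stat(ids)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ids)
        if stat(perm) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, p


def gpa(configs: np.ndarray, tol: float = 1e-11, max_iter: int = 400):
    """Generalized Procrustes superimposition of landmark configurations.

    Each configuration is translated to the origin, scaled to unit centroid
    size and rotated (no reflections) to the running consensus; iterated to
    convergence of the consensus.  Returns ``(aligned, consensus)``.
    """
    X = np.asarray(configs, float)
    if X.ndim != 3:
        raise ValueError("configs must be (n_configs, n_landmarks, dim)")
    if X.shape[0] < 3:
        raise ValueError("GPA needs at least 3 configurations")
    Xc = X - X.mean(axis=1, keepdims=True)
    size = np.sqrt((Xc**2).sum(axis=(1, 2)))
    Xc = Xc / size[:, None, None]
    consensus = Xc[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(Xc)
        for i in range(Xc.shape[0]):
            A = consensus.T @ Xc[i]
            U, _, Vt = np.linalg.svd(A)
            d = np.sign(np.linalg.det(U @ Vt))
            D = np.diag([1.0] * (A.shape[0] - 1) + [d])
            R = U @ D @ Vt
            aligned[i] = Xc[i] @ R.T
        new = aligned.mean(axis=0)
        new = new / np.sqrt((new**2).sum())
        if np.abs(new - consensus).max() < tol:
            consensus = new
            break
        consensus = new
        Xc = aligned
    return aligned, consensus


def gpa_pca(configs: np.ndarray, n_components: int | None = None):
    """GPA followed by PCA of the aligned coordinates (the 3DGM baseline).

    Returns ``(scores, variance_fractions, consensus)``.
    """
    aligned, consensus = gpa(configs)
    X = aligned.reshape(aligned.shape[0], -1)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        return np.zeros((X.shape[0], 1)), np.array([1.0]), consensus
    keep = Vt.shape[0] if n_components is None else min(n_components, Vt.shape[0])
    return Xc @ Vt[:keep].T, var[:keep] / total, consensus
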