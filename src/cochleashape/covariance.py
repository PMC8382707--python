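"""Selection vs drift inference from between/within covariance structure.

Under neutral divergence the covariance matrix of taxon means (B) is
expected to be proportional to the pooled within-taxon covariance matrix
(W, the working estimate of the ancestral covariance).  The relative
eigenvalues of B with respect to W (the generalized eigenproblem
B v = lambda W v) quantify direction-specific departures: dispersion of the
log eigenvalues away from a common constant indicates that some directions
diverged more than drift alone allows.  The maximum-likelihood
proportionality test referred to here is a Mauchly-type likelihood-ratio
statistic on that log-eigenvalue dispersion; covariance matrices are
ordinated by the log-eigenvalue Riemannian distance; and eigenvalues are
compared against neutral expectations expressed on the F_ST scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "CovComparison",
    "DriftThresholds",
    "pooled_within",
    "between_means_covariance",
    "relative_eigenanalysis",
    "proportionality_test_ml",
    "covariance_distance",
    "covariance_ordination",
    "drift_comparison",
    "compare_taxon_covariances",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftThresholds:
    """F_ST ranges expected under pure genetic drift in hominoids.

    Between-group variance fractions among extant humans and African apes:
    0.09-0.42 within species, 0.49-0.94 among species.
    """

    fst_within: tuple = (0.09, 0.42)
    fst_between: tuple = (0.49, 0.94)

    def __post_init__(self) -> None:
        for lo, hi in (self.fst_within, self.fst_between):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("F_ST bounds must be ordered within [0, 1]")


@dataclass(frozen=True)
class CovComparison:
    """Bundle of per-taxon covariances with their pooled/between summaries."""

    taxa: list
    S_g: dict                 # taxon -> covariance matrix
    n_g: dict                 # taxon -> sample size
    W: np.ndarray
    B: np.ndarray
    relative_eigenvalues: np.ndarray
    relative_eigenvectors: np.ndarray


def pooled_within(scores: np.ndarray, labels, min_n: int = 2):
    """Pooled within-taxon covariance W = sum (n_g-1) S_g / sum (n_g-1).

    Singleton taxa carry no covariance information and are excluded with a
    warning.  Returns ``(W, S_g dict, n_g dict)``.
    """
    X = np.asarray(scores, float)
    labs = np.asarray(labels, dtype=object)
    S_g, n_g = {}, {}
    num = None
    den = 0
    for taxon in pd.unique(labs):
        sub = X[labs == taxon]
        if sub.shape[0] < min_n:
            logger.warning("taxon %r has %d specimen(s); excluded from W",
                           taxon, sub.shape[0])
            continue
        S = np.cov(sub, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        S_g[taxon] = S
        n_g[taxon] = sub.shape[0]
        num = S * (sub.shape[0] - 1) if num is None else num + S * (sub.shape[0] - 1)
        den += sub.shape[0] - 1
    if len(S_g) < 2:
        raise ValueError("need at least 2 taxa with >= 2 specimens")
    return num / den, S_g, n_g


def between_means_covariance(scores: np.ndarray, labels, min_n: int = 1):
    """Covariance of the taxon mean vectors (unweighted, divisor G-1)."""
    X = np.asarray(scores, float)
    labs = np.asarray(labels, dtype=object)
    means = []
    for taxon in pd.unique(labs):
        sub = X[labs == taxon]
        if sub.shape[0] >= min_n:
            means.append(sub.mean(axis=0))
    if len(means) < 3:
        raise ValueError("between-means covariance needs >= 3 taxa")
    return np.cov(np.asarray(means), rowvar=False, ddof=1)


def relative_eigenanalysis(B: np.ndarray, W: np.ndarray):
    """Generalized eigen-decomposition B v = lambda W v, sorted descending.

    Raises for an ill-conditioned W (advice: retain fewer PCs).
    """
    B = np.asarray(B, float)
    W = np.asarray(W, float)
    if np.linalg.cond(W) > 1e10:
        raise ValueError(
            "W is ill-conditioned (cond > 1e10); retain fewer PCs"
        )
    vals, vecs = linalg.eigh(B, W)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def proportionality_test_ml(
    B: np.ndarray,
    W: np.ndarray,
    n_eff: float | None = None,
    n1: float | None = None,
    n2: float | None = None,
):
    """Likelihood-ratio test of H0: B = c W (c fitted by ML).

    The statistic is the Mauchly-type log-eigenvalue dispersion of the
    relative eigenvalues lambda_i of B with respect to W,

        T = (n_eff - c_box) * (p * log(mean lambda) - sum log lambda),

    referred to chi-square with df = p(p+1)/2 - 1, where
    c_box = (2 p^2 + p + 2)/(6 p) is the standard Box small-sample
    correction for sphericity-type likelihood ratios.  ``n_eff`` is the
    effective degrees of freedom of the comparison; when both matrices are
    estimates with df n1 and n2 it defaults to n1*n2/(n1+n2) (the variance
    of each log relative eigenvalue is the sum of the two Wishart
    contributions).  Pass ``n_eff`` directly when one matrix is treated as
    known.  Returns ``(statistic, df, p)``.
    """
    vals, _ = relative_eigenanalysis(B, W)
    p = len(vals)
    if p < 2:
        raise ValueError("proportionality test undefined for p = 1 (df = 0)")
    if np.any(vals <= 0):
        raise ValueError("relative eigenvalues must be positive (B not PD?)")
    if n_eff is None:
        if n1 is None or n2 is None:
            raise ValueError("give n_eff, or both n1 and n2")
        n_eff = n1 * n2 / (n1 + n2)
    c_box = (2 * p**2 + p + 2) / (6 * p)
    T = max(n_eff - c_box, 1.0) \
        * (p * np.log(vals.mean()) - np.sum(np.log(vals)))
    df = p * (p + 1) // 2 - 1
    pval = float(stats.chi2.sf(T, df))
    return float(T), int(df), pval


def covariance_distance(S1: np.ndarray, S2: np.ndarray) -> float:
    """Riemannian distance sqrt(sum log^2 lambda_i(S1 relative to S2))."""
    vals, _ = relative_eigenanalysis(S1, S2)
    if np.any(vals <= 0):
        raise ValueError("matrices must be positive definite")
    return float(np.sqrt(np.sum(np.log(vals) ** 2)))


def covariance_ordination(matrices: dict):
    """Principal-coordinate (classical MDS) embedding of covariance matrices.

    ``matrices`` maps a name (taxon, "W", "B", ...) to an SPD matrix on a
    shared variable set.  Returns a DataFrame of the first two principal
    coordinates indexed by name.
    """
    names = list(matrices)
    for name, S in matrices.items():
        S = np.asarray(S, float)
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError(f"matrix {name!r} is not positive definite")
    m = len(names)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = covariance_distance(
                matrices[names[i]], matrices[names[j]]
            )
    # classical MDS: double-centre -D^2/2 and eigendecompose
    J = np.eye(m) - np.ones((m, m)) / m
    Bmat = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=names, columns=["PCo1", "PCo2"])


def fst_to_eigenvalue(fst: float) -> float:
    """Map an F_ST value to the relative-eigenvalue scale, F/(1-F).

    F_ST is the fraction of variance between groups, so the corresponding
    between/within variance ratio — the scale of the relative eigenvalues —
    is F/(1-F).
    """
    if not 0 <= fst < 1:
        raise ValueError("F_ST must be in [0, 1)")
    return fst / (1.0 - fst)


def drift_comparison(
    relative_eigenvalues: np.ndarray,
    thresholds: DriftThresholds = DriftThresholds(),
) -> pd.DataFrame:
    """Compare each relative eigenvalue with neutral (drift) expectations.

    Each F_ST band maps to an eigenvalue band via F/(1-F).  An eigenvalue is
    flagged ``exceeds_drift`` when it exceeds the lower edge of the
    among-species band — i.e. when the between/within ratio in that
    direction is at least as large as the smallest ratio drift produces
    between species; directions flagged this way diverged more than neutral
    expectation allows.  Raw values and both mapped bands are always
    reported so the comparison is transparent.
    """
    vals = np.asarray(relative_eigenvalues, float)
    w_lo, w_hi = (fst_to_eigenvalue(f) for f in thresholds.fst_within)
    b_lo, b_hi = (fst_to_eigenvalue(f) for f in thresholds.fst_between)
    rows = []
    for i, lam in enumerate(vals, start=1):
        rows.append(
            {
                "eigenvalue_rank": i,
                "relative_eigenvalue": lam,
                "drift_band_within_lo": w_lo,
                "drift_band_within_hi": w_hi,
                "drift_band_between_lo": b_lo,
                "drift_band_between_hi": b_hi,
                "exceeds_drift": bool(lam > b_lo),
                "exceeds_between_band": bool(lam > b_hi),
            }
        )
    report = pd.DataFrame(rows)
    if len(vals) >= 2 and vals[1] > 0:
        report.attrs["lambda1_over_lambda2"] = float(vals[0] / vals[1])
    return report


def compare_taxon_covariances(scores, labels) -> CovComparison:
    """One-call W/B/relative-eigenanalysis bundle from labeled scores."""
    W, S_g, n_g = pooled_within(scores, labels)
    B = between_means_covariance(scores, labels, min_n=1)
    vals, vecs = relative_eigenanalysis(B, W)
    return CovComparison(
        taxa=list(S_g), S_g=S_g, n_g=n_g, W=W, B=B,
        relative_eigenvalues=vals, relative_eigenvectors=vecs,
    )
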