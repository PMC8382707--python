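"""Classification and clustering of tangent-PCA scores.

Leave-one-out K-nearest-neighbour classification scored by balanced accuracy
(the mean of per-class true-positive rates, which is insensitive to class
imbalance), V-measure evaluation of clusterings against taxon labels, and
selection of the cluster count that best recovers the labels.  Specimens
labelled ``"unknown"`` never enter a truth set; they are assigned a nearest
taxon and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import balanced_accuracy_score
from sklearn.metrics import homogeneity_completeness_v_measure

__all__ = [
    "LabeledScores",
    "UNKNOWN",
    "knn_balanced_accuracy",
    "v_measure",
    "cluster_scores",
    "select_cluster_count",
]

UNKNOWN = "unknown"


@dataclass(frozen=True)
class LabeledScores:
    """PC scores with taxon labels (``"unknown"`` allowed) and metadata."""

    specimen_ids: list
    scores: np.ndarray           # (n, k) PC coordinates
    labels: list                 # taxon or "unknown"
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.scores, float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("scores must be (n, k>=1)")
        if len(self.labels) != X.shape[0] or len(self.specimen_ids) != X.shape[0]:
            raise ValueError("labels/ids length mismatch")
        object.__setattr__(self, "scores", X)

    @property
    def known_mask(self) -> np.ndarray:
        return np.array([lab != UNKNOWN for lab in self.labels])


def knn_balanced_accuracy(
    data: LabeledScores, k_neighbors: int = 1, n_pcs: int | None = 3
):
    """Leave-one-out KNN over the first ``n_pcs`` score dimensions.

    Labeled specimens are predicted leave-one-out; unknowns get the majority
    label of their ``k_neighbors`` nearest labeled specimens.  Returns
    ``(predictions DataFrame, balanced accuracy)`` where balanced accuracy is
    the mean per-class recall over the labeled specimens.
    """
    X = data.scores if n_pcs is None else data.scores[:, : n_pcs]
    labels = np.asarray(data.labels, dtype=object)
    known = data.known_mask
    y = labels[known]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 labeled classes")
    if k_neighbors > 1 and (counts == 1).any():
        warnings.warn(
            "classes with a single member cannot vote for themselves in "
            "leave-one-out KNN; their recall may be forced low"
        )
    Xk = X[known]
    D = np.linalg.norm(Xk[:, None, :] - Xk[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)

    def vote(dist_row, pool_labels):
        order = np.argsort(dist_row, kind="stable")[:k_neighbors]
        votes = pool_labels[order]
        uniq, cnt = np.unique(votes, return_counts=True)
        best = cnt.max()
        tied = uniq[cnt == best]
        if len(tied) == 1:
            return tied[0]
        for idx in order:  # tie-break: closest neighbour among tied classes
            if pool_labels[idx] in tied:
                return pool_labels[idx]

    pred_known = np.array([vote(D[i], y) for i in range(len(y))], dtype=object)
    bacc = balanced_accuracy_score(y, pred_known)

    rows = list(zip(np.asarray(data.specimen_ids)[known], y, pred_known,
                    [False] * len(y)))
    if (~known).any():
        Xu = X[~known]
        Du = np.linalg.norm(Xu[:, None, :] - Xk[None, :, :], axis=2)
        pred_unknown = [vote(Du[i], y) for i in range(Xu.shape[0])]
        rows += list(zip(np.asarray(data.specimen_ids)[~known],
                         [UNKNOWN] * Xu.shape[0], pred_unknown,
                         [True] * Xu.shape[0]))
    preds = pd.DataFrame(rows, columns=["specimen_id", "true", "predicted",
                                        "is_unknown"])
    return preds, float(bacc)


def v_measure(true_labels, cluster_labels, beta: float = 1.0):
    """Homogeneity, completeness and V-measure of a clustering.

    h = 1 - H(C|K)/H(C), c = 1 - H(K|C)/H(K),
    V = (1 + beta) h c / (beta h + c); the degenerate single-class /
    single-cluster case is perfect by convention (V = 1).
    """
    t = np.asarray(true_labels)
    k = np.asarray(cluster_labels)
    if len(t) != len(k):
        raise ValueError("label vectors must have the same length")
    if len(t) == 0:
        raise ValueError("empty labelings")
    h, c, v = homogeneity_completeness_v_measure(t, k, beta=beta)
    return float(h), float(c), float(v)


def cluster_scores(
    data: LabeledScores | np.ndarray,
    n_clusters: int,
    method: str = "ward",
    seed: int | None = 0,
    n_pcs: int | None = 3,
) -> np.ndarray:
    """Cluster score coordinates; deterministic given the seed.

    ``method``: ``"ward"`` (agglomerative) or ``"kmeans"`` (multi-start).
    """
    X = data.scores if isinstance(data, LabeledScores) else np.asarray(data, float)
    if n_pcs is not None:
        X = X[:, : n_pcs]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > X.shape[0]:
        raise ValueError("more clusters than specimens")
    if method == "ward":
        if n_clusters == 1:
            return np.zeros(X.shape[0], dtype=int)
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
        return model.fit_predict(X)
    if method == "kmeans":
        model = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        return model.fit_predict(X)
    raise ValueError(f"unknown method {method!r}")


def select_cluster_count(
    data: LabeledScores,
    candidates=range(2, 9),
    method: str = "ward",
    seed: int | None = 0,
    n_pcs: int | None = 3,
):
    """Pick the cluster count whose clustering best matches the taxon labels.

    Each candidate count is clustered on all specimens; the V-measure is
    evaluated against the labels of the labeled specimens only.  Ties break
    toward the smaller count.  Returns ``(best_count, report DataFrame)``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate range")
    known = data.known_mask
    truth = np.asarray(data.labels, dtype=object)[known]
    rows = []
    for k in sorted(candidates):
        labels = cluster_scores(data, k, method=method, seed=seed, n_pcs=n_pcs)
        h, c, v = v_measure(truth, labels[known])
        rows.append((k, h, c, v))
    report = pd.DataFrame(rows, columns=["n_clusters", "homogeneity",
                                         "completeness", "v_measure"])
    best = int(report.loc[report["v_measure"].idxmax(), "n_clusters"])
    return best, report
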