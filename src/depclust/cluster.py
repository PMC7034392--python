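"""Zero-anchored max-min k-means severity classification.

The classification constructor works directly on the item-score vectors
(13 features for BDI-13), not on totals. It is fully deterministic:

1. **Max-min (farthest-point) initialization**, anchored at the all-zero
   item vector — the semantically meaningful "no symptoms" point, used
   whether or not any respondent actually scored all zeros. The second
   center is the respondent farthest (Euclidean) from the anchor; each
   further center is the respondent maximizing its minimum distance to
   the centers chosen so far.
2. **Lloyd's k-means** on raw item scores (no standardization; all items
   share one scale): alternate nearest-center assignment and centroid
   recomputation until no center changes, capped at 100 iterations.
3. **Severity ordering**: clusters are mapped to ordered severity levels
   (None < Mild < Moderate < Severe for k=4) by ascending center total
   score, i.e. the sum of the center's coordinates.

Ties everywhere break to the lowest index so identical input always
yields an identical model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataio import ResponseMatrix, total_scores

__all__ = [
    "ClusterModel",
    "ClusterSummary",
    "maxmin_init",
    "kmeans_fit",
    "severity_map",
    "severity_labels",
    "summarize_clusters",
    "DEFAULT_LEVEL_NAMES",
]

DEFAULT_LEVEL_NAMES = ("None", "Mild", "Moderate", "Severe")
MAX_ITER_DEFAULT = 100


def _as_float_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


def maxmin_init(matrix, k: int, anchor: np.ndarray | None = None) -> np.ndarray:
    """Deterministic farthest-point seeding anchored at the zero vector.

    Returns a ``(k, m)`` array of initial centers. ``anchor`` defaults to
    the all-zero item vector. Ties in the farthest-point choice break to
    the lowest row index.
    """
    X = _as_float_matrix(matrix)
    n, m = X.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"need at least k={k} respondents, got {n}")
    anchor = np.zeros(m) if anchor is None else np.asarray(anchor, dtype=float)
    if anchor.shape != (m,):
        raise ValueError("anchor dimension does not match item count")

    centers = [anchor]
    min_dist = np.linalg.norm(X - anchor, axis=1)
    for _ in range(k - 1):
        idx = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        if min_dist[idx] == 0.0:
            raise ValueError(
                f"fewer than {k} distinct points available for max-min seeding"
            )
        centers.append(X[idx].copy())
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[idx], axis=1))
    return np.vstack(centers)


@dataclass
class ClusterModel:
    """A fitted k-means severity model in item space."""

    centers: np.ndarray          # (k, m) in item units
    labels: np.ndarray           # per-respondent cluster index
    severity_order: np.ndarray   # cluster index -> severity level 0..k-1
    n_iterations: int
    converged: bool
    sse: float                   # within-cluster sum of squared distances
    sse_history: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def center_totals(self) -> np.ndarray:
        """Sum of each center's coordinates — the printed "center score"."""
        return self.centers.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centers": self.centers.tolist(),
            "center_totals": self.center_totals.tolist(),
            "severity_order": self.severity_order.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "sse": self.sse,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks ties to the lowest center index
    return np.argmin(cdist(X, centers, "sqeuclidean"), axis=1)


def _sse(X, centers, labels) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def kmeans_fit(
    matrix,
    init: np.ndarray,
    max_iter: int = MAX_ITER_DEFAULT,
    tol: float = 0.0,
) -> ClusterModel:
    """Lloyd's k-means from the given initial centers.

    Assignment ties break to the lowest center index; a cluster left empty
    keeps its previous center (cannot occur with max-min seeding on data
    of this kind, but the rule must be defined). Convergence means no
    center moved by more than ``tol`` (default: exact equality). The
    objective is checked to be non-increasing on every fit.
    """
    X = _as_float_matrix(matrix)
    centers = np.asarray(init, dtype=float).copy()
    k = centers.shape[0]
    if len(np.unique(centers, axis=0)) != k:
        raise ValueError("initial centers must be distinct")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")

    history: list[float] = []
    converged = False
    n_iter = 0
    labels = _assign(X, centers)
    for n_iter in range(1, max_iter + 1):
        labels = _assign(X, centers)
        history.append(_sse(X, centers, labels))
        new_centers = centers.copy()
        for c in range(k):
            members = labels == c
            if members.any():
                new_centers[c] = X[members].mean(axis=0)
        moved = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if moved <= tol:
            converged = True
            break

    labels = _assign(X, centers)
    final_sse = _sse(X, centers, labels)
    history.append(final_sse)
    if any(b > a + 1e-8 for a, b in zip(history, history[1:])):
        raise AssertionError("k-means objective increased between iterations")

    model = ClusterModel(
        centers=centers,
        labels=labels,
        severity_order=np.empty(k, dtype=int),
        n_iterations=n_iter,
        converged=converged,
        sse=final_sse,
        sse_history=history,
    )
    model.severity_order = severity_map(model)
    return model


def severity_map(model: ClusterModel) -> np.ndarray:
    """Permutation mapping cluster index -> severity level.

    Clusters are ranked by ascending center total score; ties break by
    ascending cluster index (stable sort).
    """
    order = np.argsort(model.center_totals, kind="stable")
    severity = np.empty(model.k, dtype=int)
    severity[order] = np.arange(model.k)
    return severity


def severity_labels(model: ClusterModel) -> np.ndarray:
    """Per-respondent severity level (0 = lowest) under the fitted model."""
    return model.severity_order[model.labels]


@dataclass(frozen=True)
class ClusterSummary:
    """Per-severity-level membership counts and observed score ranges.

    Unlike cutoff intervals, the observed total-score ranges of k-means
    severity levels may overlap across levels, because assignment uses the
    full item profile rather than the total.
    """

    level_names: tuple
    counts: np.ndarray
    center_totals: np.ndarray       # ordered by severity level
    score_ranges: list              # per level: (min total, max total) or None

    def to_records(self) -> list[dict]:
        recs = []
        for i, name in enumerate(self.level_names):
            lo_hi = self.score_ranges[i]
            recs.append({
                "level": name,
                "n": int(self.counts[i]),
                "center_total": float(self.center_totals[i]),
                "score_min": None if lo_hi is None else int(lo_hi[0]),
                "score_max": None if lo_hi is None else int(lo_hi[1]),
            })
        return recs


def summarize_clusters(
    model: ClusterModel,
    matrix: ResponseMatrix,
    level_names: tuple = DEFAULT_LEVEL_NAMES,
) -> ClusterSummary:
    """Counts, center totals, and observed total-score range per level."""
    if len(level_names) != model.k:
        level_names = tuple(f"level_{i}" for i in range(model.k))
    totals = total_scores(matrix)
    sev = severity_labels(model)
    order = np.argsort(model.severity_order, kind="stable")  # level -> cluster
    counts = np.bincount(sev, minlength=model.k)
    ranges = []
    for level in range(model.k):
        member_totals = totals[sev == level]
        ranges.append(None if member_totals.size == 0
                      else (int(member_totals.min()), int(member_totals.max())))
    if counts.sum() != matrix.n_respondents:
        raise AssertionError("cluster summary counts do not partition the sample")
    return ClusterSummary(
        level_names=tuple(level_names),
        counts=counts,
        center_totals=model.center_totals[order],
        score_ranges=ranges,
    )
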