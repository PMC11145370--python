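"""Recurring connectivity states via K-means, and their temporal metrics.

Windows from all subjects (both groups pooled) are clustered on their
upper-triangle Fisher-z edge vectors. The number of states is chosen by
an explicit elbow rule — the interior K maximizing the second difference
(discrete curvature) of the within-cluster dispersion curve — and states
are relabeled so that state 1 is the weakest-connected (hypoconnected)
pattern. Per subject, three temporal summaries are computed from the
window-state sequence:

- FR (frequency / fractional occupancy): share of windows in each state;
- MDTD (mean dwell time): mean length of maximal consecutive runs of a
  state, in windows (seconds = windows x step x TR);
- NT (number of transitions): count of adjacent state changes.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .windows import WindowedFC, upper_triangle

__all__ = [
    "StateModel",
    "TemporalMetrics",
    "pool_windows",
    "select_k",
    "fit_states",
    "temporal_metrics",
    "cohort_temporal_metrics",
    "run_lengths",
]

logger = logging.getLogger(__name__)

#: Relative inertia gain below which adding a cluster is considered flat
#: (the "no elbow" fallback threshold).
NO_ELBOW_TOL = 1e-3


@dataclasses.dataclass
class StateModel:
    """Fitted window-state solution.

    ``centroids`` has shape (K, E) in Fisher-z units over the strict
    upper triangle (E = N(N-1)/2). ``assignments`` maps subject id to a
    1-based state sequence in window order. State labels are sorted by
    ascending mean |centroid| so state 1 is the weakest pattern.
    """

    K: int
    centroids: np.ndarray
    assignments: Mapping[str, np.ndarray]
    inertia: float
    inertia_curve: Mapping[int, float] | None = None
    distance: str = "euclidean"
    no_elbow: bool = False


@dataclasses.dataclass
class TemporalMetrics:
    """Per-subject temporal summaries of a window-state sequence."""

    subject_id: str
    FR: np.ndarray  # length K, sums to 1
    MDTD: np.ndarray  # length K, windows; 0 where state never visited
    visited: np.ndarray  # bool, length K
    NT: int
    n_windows: int


def pool_windows(cohort: Sequence[WindowedFC]) -> tuple[np.ndarray, list[str], list[int]]:
    """Stack upper-triangle window vectors of all subjects.

    Returns (X with one row per window, subject ids, windows per subject).
    """
    blocks = [upper_triangle(w.z) for w in cohort]
    X = np.vstack(blocks)
    ids = [w.subject_id for w in cohort]
    counts = [b.shape[0] for b in blocks]
    return X, ids, counts


def _kmeans_inertia(X: np.ndarray, k: int, replicates: int, seed: int) -> float:
    if k == 1:
        mu = X.mean(axis=0)
        return float(((X - mu) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def select_k(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 7),
    replicates: int = 20,
    seed: int = 0,
) -> tuple[int, dict[int, float], bool]:
    """Choose the number of states by the elbow (maximum-curvature) rule.

    Inertia I(k) is computed for k spanning one beyond each end of
    ``k_range`` (including k=1) so that the discrete curvature
    I(k-1) - 2 I(k) + I(k+1) is defined at every candidate; the K with
    maximal curvature wins. If no candidate improves inertia by more
    than ``NO_ELBOW_TOL`` relative gain, the curve is flat: the smallest
    such k is returned with the ``no_elbow`` flag set.

    Returns (K, inertia curve, no_elbow flag).
    """
    k_range = sorted(k_range)
    if k_range[0] < 2 or k_range[-1] > 10:
        raise ValueError("k_range must lie within [2, 10]")
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    if X.shape[0] < k_range[-1] + 1:
        raise ValueError(
            f"{X.shape[0]} pooled windows cannot support k up to {k_range[-1]}"
        )
    ks = list(range(max(1, k_range[0] - 1), k_range[-1] + 2))
    curve = {k: _kmeans_inertia(X, k, replicates, seed + k) for k in ks}
    gains = {
        k: (curve[k - 1] - curve[k]) / curve[k - 1] if curve[k - 1] > 0 else 0.0
        for k in ks[1:]
    }
    flat = [k for k in k_range if gains.get(k, 0.0) < NO_ELBOW_TOL]
    if len(flat) == len(k_range):
        K = flat[0]
        logger.warning("no elbow: inertia curve flat, defaulting to K=%d", K)
        return K, curve, True
    curvature = {
        k: curve[k - 1] - 2.0 * curve[k] + curve[k + 1]
        for k in k_range
        if (k - 1) in curve and (k + 1) in curve
    }
    K = max(curvature, key=lambda k: (curvature[k], -k))
    return K, curve, False


def _cityblock_kmeans(
    X: np.ndarray, K: int, replicates: int, seed: int, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-medians (L1 distance, median centroids), best of replicates."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(replicates):
        idx = rng.choice(X.shape[0], K, replace=False)
        C = X[idx].copy()
        labels = np.zeros(X.shape[0], dtype=int)
        for _ in range(max_iter):
            D = np.abs(X[:, None, :] - C[None, :, :]).sum(axis=2)
            new = D.argmin(axis=1)
            for k in range(K):
                if not np.any(new == k):  # empty cluster: re-seed farthest point
                    new[D.min(axis=1).argmax()] = k
                    logger.info("re-seeded empty cityblock cluster %d", k)
            if np.array_equal(new, labels) and best is not None:
                break
            labels = new
            for k in range(K):
                C[k] = np.median(X[labels == k], axis=0)
            D = np.abs(X[:, None, :] - C[None, :, :]).sum(axis=2)
            if np.array_equal(D.argmin(axis=1), labels):
                break
        D = np.abs(X[:, None, :] - C[None, :, :]).sum(axis=2)
        inertia = float(D[np.arange(len(labels)), labels].sum())
        if best is None or inertia < best[2]:
            best = (labels.copy(), C.copy(), inertia)
    return best


def fit_states(
    cohort: Sequence[WindowedFC],
    K: int,
    distance: str = "euclidean",
    replicates: int = 20,
    seed: int = 0,
) -> StateModel:
    """Cluster pooled windows into K states and split assignments back.

    Default is standard K-means (squared Euclidean, mean centroids);
    ``distance="cityblock"`` uses L1 with median centroids, as common in
    the windowed-connectivity literature. States are relabeled by
    ascending mean |centroid| (state 1 = hypoconnected).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if distance not in ("euclidean", "cityblock"):
        raise ValueError(f"unknown distance {distance!r}")
    X, ids, counts = pool_windows(cohort)
    if distance == "euclidean":
        km = KMeans(n_clusters=K, n_init=replicates, random_state=seed)
        labels = km.fit_predict(X)
        centroids = km.cluster_centers_
        inertia = float(km.inertia_)
    else:
        labels, centroids, inertia = _cityblock_kmeans(X, K, replicates, seed)
    order = np.argsort(np.abs(centroids).mean(axis=1), kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    labels = relabel[labels] + 1  # 1-based, weakest first
    centroids = centroids[order]
    assignments = {}
    start = 0
    for sid, c in zip(ids, counts):
        assignments[sid] = labels[start : start + c]
        start += c
    return StateModel(
        K=K,
        centroids=centroids,
        assignments=assignments,
        inertia=inertia,
        distance=distance,
    )


def run_lengths(seq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of a sequence as (state, length) pairs, in order."""
    seq = np.asarray(seq)
    out = []
    start = 0
    for t in range(1, len(seq) + 1):
        if t == len(seq) or seq[t] != seq[start]:
            out.append((int(seq[start]), t - start))
            start = t
    return out


def temporal_metrics(seq: np.ndarray, K: int, subject_id: str = "") -> TemporalMetrics:
    """FR, MDTD and NT of one 1-based window-state sequence.

    MDTD of a state that never occurs is reported as 0 with its
    ``visited`` flag False; such entries should be excluded from group
    comparisons rather than treated as true zeros.
    """
    seq = np.asarray(seq, dtype=int)
    if seq.size == 0:
        raise ValueError("empty state sequence")
    if seq.min() < 1 or seq.max() > K:
        raise ValueError(f"state labels must lie in [1, {K}]")
    n_w = len(seq)
    FR = np.array([(seq == k).sum() / n_w for k in range(1, K + 1)])
    runs = run_lengths(seq)
    MDTD = np.zeros(K)
    visited = np.zeros(K, dtype=bool)
    for k in range(1, K + 1):
        lens = [ln for s, ln in runs if s == k]
        if lens:
            MDTD[k - 1] = float(np.mean(lens))
            visited[k - 1] = True
    NT = int((seq[1:] != seq[:-1]).sum())
    return TemporalMetrics(
        subject_id=subject_id, FR=FR, MDTD=MDTD, visited=visited, NT=NT, n_windows=n_w
    )


def cohort_temporal_metrics(model: StateModel) -> pd.DataFrame:
    """Tidy per-subject table: one row per (subject, state) plus NT."""
    rows = []
    for sid, seq in model.assignments.items():
        tm = temporal_metrics(seq, model.K, subject_id=sid)
        for k in range(model.K):
            rows.append(
                dict(
                    subject_id=sid,
                    state=k + 1,
                    FR=tm.FR[k],
                    MDTD=tm.MDTD[k],
                    visited=bool(tm.visited[k]),
                    NT=tm.NT,
                    n_windows=tm.n_windows,
                )
            )
    return pd.DataFrame(rows)
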