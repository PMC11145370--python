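"""Dynamic graph topology of windowed connectivity networks.

Each windowed Fisher-z matrix is proportionally thresholded over a ramp
of sparsity values (default 0.05 to 0.40 in steps of 0.01, i.e. 36
thresholds), binarized, and summarized by global metrics — global
efficiency Eg, local efficiency Eloc, characteristic path length
Cp_path, clustering coefficient Ccoef, and small-world indices gamma /
lambda / sigma against degree-preserving rewired nulls — plus nodal
degree, efficiency and betweenness. Metrics are integrated across the
ramp by the trapezoidal AUC, and the across-window sample variance of
each AUC series is the temporal-variability readout.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .windows import WindowedFC

__all__ = [
    "SparsityRamp",
    "threshold_by_sparsity",
    "global_metrics",
    "nodal_metrics",
    "small_world",
    "auc_over_ramp",
    "temporal_variability",
    "subject_dynamic_graph",
    "NullModelError",
]

GLOBAL_METRICS = ("Eg", "Eloc", "Cp_path", "Ccoef")


class NullModelError(RuntimeError):
    """Raised when a degree-preserving null cannot be generated."""


@dataclasses.dataclass(frozen=True)
class SparsityRamp:
    """Proportional-threshold ramp (fractions of the N(N-1)/2 edge slots)."""

    start: float = 0.05
    stop: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.start < self.stop < 1.0):
            raise ValueError("need 0 < start < stop < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _ranked_edges(z: np.ndarray, use_abs: bool = True) -> np.ndarray:
    """Edge list (i, j) sorted by (weight desc, i asc, j asc) — fixed tie order."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = np.abs(z[iu, ju]) if use_abs else z[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return np.column_stack([iu[order], ju[order]])


def threshold_by_sparsity(
    z: np.ndarray, sparsity: float, use_abs: bool = True
) -> np.ndarray:
    """Binary adjacency keeping the round(sparsity * E) strongest edges.

    Edge strength is |z| by default (``use_abs=False`` ranks signed
    values, a positive-only mode). Ties are broken by the fixed total
    order (value desc, i asc, j asc); round is half-away-from-zero.
    """
    if not (0.0 < sparsity < 1.0):
        raise ValueError("sparsity must lie in (0, 1)")
    n = z.shape[0]
    if z.shape != (n, n) or not np.allclose(z, z.T, atol=1e-10):
        raise ValueError("connectivity matrix must be square symmetric")
    E = n * (n - 1) // 2
    m = _round_half_away(sparsity * E)
    edges = _ranked_edges(z, use_abs=use_abs)[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[edges[:, 0], edges[:, 1]] = True
    return adj | adj.T


@njit(cache=True)
def _bfs_distances(a):  # pragma: no cover - exercised via global_metrics
    """All-pairs unweighted shortest paths (queue BFS); inf if unreachable."""
    n = a.shape[0]
    D = np.full((n, n), np.inf)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        D[s, s] = 0.0
        head, tail = 0, 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            for v in range(n):
                if a[u, v] and not np.isfinite(D[s, v]):
                    D[s, v] = D[s, u] + 1.0
                    queue[tail] = v
                    tail += 1
    return D


@njit(cache=True)
def _subgraph_efficiency(a, nodes):  # pragma: no cover
    """Global efficiency of the induced subgraph on ``nodes``."""
    m = nodes.shape[0]
    if m < 2:
        return 0.0
    sub = np.empty((m, m), dtype=a.dtype)
    for i in range(m):
        for j in range(m):
            sub[i, j] = a[nodes[i], nodes[j]]
    d = _bfs_distances(sub)
    total = 0.0
    for i in range(m):
        for j in range(m):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (m * (m - 1))


def _distances(adj: np.ndarray) -> np.ndarray:
    return _bfs_distances(np.ascontiguousarray(adj, dtype=np.uint8))


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    a = np.ascontiguousarray(adj, dtype=np.uint8)
    return float(_subgraph_efficiency(a, np.arange(n)))


def global_metrics(adj: np.ndarray) -> dict:
    """Eg, Eloc, Cp_path, Ccoef of a simple undirected binary graph.

    - Eg: mean inverse shortest-path length over all ordered pairs,
      unreachable pairs contributing 0 (robust to disconnection);
    - Cp_path: mean shortest-path length over *connected* pairs only,
      0 (with ``connected=False``) if no pair is connected;
    - Ccoef: mean local clustering, nodes of degree < 2 contributing 0;
    - Eloc: mean over nodes of the global efficiency of the subgraph
      induced on each node's neighbours.
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("graph metrics need N >= 3")
    deg = adj.sum(axis=1)
    d = _distances(adj)
    finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    Eg = float(inv.sum() / (n * (n - 1)))
    Cp = float(d[finite].mean()) if finite.any() else 0.0
    A = adj.astype(np.int64)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        local = 2.0 * tri / (deg * (deg - 1))
    local[deg < 2] = 0.0
    Ccoef = float(local.mean())
    a = np.ascontiguousarray(adj, dtype=np.uint8)
    eloc_terms = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if len(nb) >= 2:
            eloc_terms[i] = _subgraph_efficiency(a, nb)
    Eloc = float(eloc_terms.mean())
    return dict(
        Eg=Eg, Eloc=Eloc, Cp_path=Cp, Ccoef=Ccoef,
        connected=bool(np.isfinite(d).all()),
    )


def nodal_metrics(adj: np.ndarray) -> pd.DataFrame:
    """Per-node degree, nodal efficiency and betweenness centrality."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    G = nx.from_numpy_array(adj.astype(int))
    btw = nx.betweenness_centrality(G, normalized=True)
    return pd.DataFrame(
        dict(
            node=np.arange(n),
            degree=adj.sum(axis=1).astype(int),
            nodal_efficiency=inv.sum(axis=1) / (n - 1),
            betweenness=[btw[i] for i in range(n)],
        )
    )


def _rewired_null(G: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    H = G.copy()
    n_edges = H.number_of_edges()
    if n_edges < 2:
        raise NullModelError("graph too sparse to rewire (fewer than 2 edges)")
    try:
        nx.double_edge_swap(
            H,
            nswap=5 * n_edges,
            max_tries=100 * n_edges,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    except nx.NetworkXError as exc:  # pragma: no cover - degenerate degree seq
        raise NullModelError(f"degree-preserving rewiring failed: {exc}") from exc
    return H


def small_world(
    adj: np.ndarray, n_null: int = 20, seed: int = 0, rewire: bool = True
) -> dict:
    """Small-world indices against degree-preserving rewired nulls.

    gamma = Ccoef / <Ccoef_null>, lambda = Cp_path / <Cp_null>,
    sigma = gamma / lambda. Nulls preserve every node's degree exactly
    (double edge swaps). ``rewire=False`` uses the graph itself as its
    null (gamma = lambda = sigma = 1), useful for self-consistency
    checks.
    """
    if n_null < 20:
        raise ValueError("need n_null >= 20")
    m = global_metrics(adj)
    rng = np.random.default_rng(seed)
    G = nx.from_numpy_array(np.asarray(adj, dtype=int))
    cc_null, cp_null = [], []
    for _ in range(n_null):
        H = _rewired_null(G, rng) if rewire else G
        mn = global_metrics(nx.to_numpy_array(H, dtype=bool))
        cc_null.append(mn["Ccoef"])
        cp_null.append(mn["Cp_path"])
    cc0, cp0 = float(np.mean(cc_null)), float(np.mean(cp_null))
    gamma = m["Ccoef"] / cc0 if cc0 > 0 else np.nan
    lam = m["Cp_path"] / cp0 if cp0 > 0 else np.nan
    sigma = gamma / lam if lam and np.isfinite(lam) and lam != 0 else np.nan
    return dict(gamma=gamma, **{"lambda": lam}, sigma=sigma)


def auc_over_ramp(values: Sequence[float], ramp: SparsityRamp | np.ndarray) -> float:
    """Trapezoidal integral of a metric over the sparsity ramp."""
    x = ramp.values() if isinstance(ramp, SparsityRamp) else np.asarray(ramp, float)
    y = np.asarray(values, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"{y.shape[0]} values for {x.shape[0]} ramp points")
    if x.size < 2:
        raise ValueError("AUC needs at least 2 ramp points")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing metric value on the ramp")
    return float(np.trapezoid(y, x))


def temporal_variability(series: np.ndarray, ddof: int = 1, use_sd: bool = False) -> float:
    """Across-window sample variance (default) or sd of a metric series."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("temporal variability needs >= 2 windows")
    v = float(series.var(ddof=ddof))
    return float(np.sqrt(v)) if use_sd else v


def subject_dynamic_graph(
    wfc: WindowedFC,
    ramp: SparsityRamp | None = None,
    use_abs: bool = True,
    include_nodal: bool = False,
    small_world_windows: bool = False,
    small_world_mean: bool = True,
    n_null: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-window AUC global metrics and their temporal variances.

    For every window, each global metric is computed at every sparsity on
    the ramp and integrated to an AUC; the across-window variance of each
    AUC series is returned alongside. Small-world indices are computed on
    the subject's time-averaged network by default (per-window nulls are
    expensive; enable ``small_world_windows`` for the full version).

    Returns (per-window tidy frame, summary dict with variances and
    small-world indices).
    """
    ramp = ramp or SparsityRamp()
    svals = ramp.values()
    rows = []
    rng = np.random.default_rng(seed)
    for w in range(wfc.n_windows):
        per_thr = {m: [] for m in GLOBAL_METRICS}
        sw_thr = {m: [] for m in ("gamma", "lambda", "sigma")}
        for s in svals:
            adj = threshold_by_sparsity(wfc.z[w], s, use_abs=use_abs)
            gm = global_metrics(adj)
            for m in GLOBAL_METRICS:
                per_thr[m].append(gm[m])
            if small_world_windows:
                sw = small_world(adj, n_null=n_null,
                                 seed=int(rng.integers(0, 2**31 - 1)))
                for m in sw_thr:
                    sw_thr[m].append(sw[m])
        row = dict(subject_id=wfc.subject_id, window=w)
        for m in GLOBAL_METRICS:
            row[f"{m}_auc"] = auc_over_ramp(per_thr[m], ramp)
        if include_nodal:
            mid = threshold_by_sparsity(wfc.z[w], float(np.median(svals)), use_abs)
            nm = nodal_metrics(mid)
            for _, r in nm.iterrows():
                row[f"degree_n{int(r.node)}"] = r.degree
        if small_world_windows:
            for m in sw_thr:
                vals = np.asarray(sw_thr[m], float)
                row[f"{m}_auc"] = (
                    auc_over_ramp(vals, ramp) if np.all(np.isfinite(vals)) else np.nan
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    summary: dict = dict(subject_id=wfc.subject_id)
    for m in GLOBAL_METRICS:
        summary[f"{m}_variance"] = temporal_variability(df[f"{m}_auc"].to_numpy())
    if not small_world_mean:
        return df, summary
    mean_z = wfc.z.mean(axis=0)
    sw_vals = {m: [] for m in ("gamma", "lambda", "sigma")}
    for s in svals:
        adj = threshold_by_sparsity(mean_z, s, use_abs=use_abs)
        try:
            sw = small_world(adj, n_null=n_null,
                             seed=int(rng.integers(0, 2**31 - 1)))
        except NullModelError:
            sw = dict(gamma=np.nan, sigma=np.nan, **{"lambda": np.nan})
        for m in sw_vals:
            sw_vals[m].append(sw[m])
    for m in ("gamma", "lambda", "sigma"):
        vals = np.asarray(sw_vals[m], float)
        ok = np.isfinite(vals)
        summary[f"{m}_auc_mean_network"] = (
            auc_over_ramp(vals, ramp) if ok.all() else float(np.nanmean(vals))
        )
    return df, summary
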