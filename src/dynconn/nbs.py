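"""Network-based statistic (NBS) with covariate adjustment.

Edge-wise group contrasts are tested with a linear model (group +
covariates) at every edge; edges surviving a primary threshold
(default p < 0.0001) form a suprathreshold graph whose connected
components are the candidate subnetworks. Family-wise error over
components is controlled by permutation (default 5000 iterations): each
permutation rebuilds the null distribution of the *maximum* component
size, and a component is significant when its size exceeds the null at
the component alpha (default 0.005). Covariates are handled under
permutation by the Freedman-Lane residual-shuffling scheme. Both effect
directions (patient > control and control > patient) are tested
separately.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .windows import upper_triangle, vector_to_matrix

__all__ = [
    "NbsComponent",
    "NbsResult",
    "edge_glm_t",
    "extract_components",
    "permutation_test",
    "build_design",
]


@dataclasses.dataclass
class NbsComponent:
    """One suprathreshold connected subnetwork."""

    edges: list  # (i, j) node-index pairs, i < j
    direction: int  # +1: group coefficient positive, -1: negative
    size: int  # number of edges (the component statistic)
    p_fwe: float | None = None

    @property
    def nodes(self) -> list:
        return sorted({n for e in self.edges for n in e})


@dataclasses.dataclass
class NbsResult:
    edge_t: np.ndarray  # N x N
    edge_p: np.ndarray  # N x N
    primary_p: float
    components: list  # NbsComponent, both directions, FWE p attached
    null_max_sizes: dict  # direction -> ndarray of length n_perm
    n_perm: int
    alpha: float

    def significant(self) -> list:
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe < self.alpha]

    def to_frame(self, node_ids: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.components):
            for (i, j) in c.edges:
                rows.append(
                    dict(
                        node_i=node_ids[i] if node_ids else i,
                        node_j=node_ids[j] if node_ids else j,
                        t=self.edge_t[i, j],
                        p=self.edge_p[i, j],
                        component_id=ci,
                        direction=c.direction,
                        component_p_fwe=c.p_fwe,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["node_i", "node_j", "t", "p", "component_id", "direction",
                     "component_p_fwe"],
        )


def build_design(
    group: Sequence, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[np.ndarray, int, list]:
    """Design matrix [intercept, group indicator, covariates...].

    ``group`` may be any two-level labelling; the indicator is 1 for the
    lexicographically *later* level (so with labels {control, patient},
    positive t means patient > control). Returns (X, index of the group
    column, column names); raises on rank deficiency, naming the
    collinear column.
    """
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    g = (group == levels[1]).astype(float)
    cols = [np.ones(len(g)), g]
    names = ["intercept", f"group[{levels[1]}]"]
    if covariates is not None:
        C = pd.DataFrame(covariates)
        for name in C.columns:
            cols.append(C[name].to_numpy(dtype=float))
            names.append(str(name))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the first column linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"design is rank deficient: column {names[j]!r} "
                                 "is collinear with earlier columns")
    return X, 1, names


def _glm_t(Y: np.ndarray, X: np.ndarray, coef: int) -> tuple[np.ndarray, np.ndarray]:
    """t-statistics of one coefficient across many response columns."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} observations cannot support {p} design columns")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef, coef], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[coef] / se
    t[~np.isfinite(t)] = 0.0
    p_val = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p_val


def edge_glm_t(
    edge_data: np.ndarray,
    group: Sequence,
    covariates=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge t and two-sided p of the group effect, covariate-adjusted.

    ``edge_data`` is an (n_subjects, N, N) stack of symmetric
    connectivity matrices. Without covariates the result equals the
    pooled-variance two-sample t-test at every edge.
    """
    stack = np.asarray(edge_data, dtype=float)
    if stack.ndim != 3:
        raise ValueError("edge_data must be (n_subjects, N, N)")
    n_sub, n_nodes, _ = stack.shape
    X, coef, _ = build_design(group, covariates)
    if n_sub <= X.shape[1] + 1:
        raise ValueError("too few subjects for the requested design")
    Y = upper_triangle(stack)
    t, p = _glm_t(Y, X, coef)
    return vector_to_matrix(t, n_nodes), _p_to_matrix(p, n_nodes)


def _p_to_matrix(p: np.ndarray, n: int) -> np.ndarray:
    m = vector_to_matrix(p, n)
    np.fill_diagonal(m, 1.0)
    # vector_to_matrix leaves the diagonal 0; off-diagonal zeros are real
    return m


def extract_components(
    edge_p: np.ndarray,
    primary_p: float,
    direction: int,
    edge_t: np.ndarray | None = None,
) -> list:
    """Connected components of the suprathreshold edge graph.

    Edges enter when p < primary_p and (if ``edge_t`` is given) the sign
    of t matches ``direction``. Components are maximal sets of edges
    connected through shared nodes, sized in edges; an empty list is a
    valid result.
    """
    n = edge_p.shape[0]
    if edge_p.shape != (n, n) or not np.allclose(edge_p, edge_p.T, atol=1e-10):
        raise ValueError("edge_p must be square symmetric")
    mask = edge_p < primary_p
    if edge_t is not None:
        mask &= np.sign(edge_t) == direction
    np.fill_diagonal(mask, False)
    if not mask.any():
        return []
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    iu, ju = np.nonzero(np.triu(mask, k=1))
    comps: dict[int, list] = {}
    for i, j in zip(iu, ju):
        comps.setdefault(labels[i], []).append((int(i), int(j)))
    return [
        NbsComponent(edges=sorted(e), direction=direction, size=len(e))
        for _, e in sorted(comps.items())
    ]


def _exhaustive_indicators(g: np.ndarray) -> np.ndarray:
    """All distinct reassignments of the group indicator (small n)."""
    n = len(g)
    n1 = int(g.sum())
    out = np.zeros((comb(n, n1), n))
    for r, pos in enumerate(itertools.combinations(range(n), n1)):
        out[r, list(pos)] = 1.0
    return out


def permutation_test(
    edge_data: np.ndarray,
    group: Sequence,
    covariates=None,
    primary_p: float = 1e-4,
    n_perm: int = 5000,
    alpha: float = 0.005,
    seed: int = 0,
) -> NbsResult:
    """Full NBS: edge GLM, components, and permutation FWE control.

    The null of the maximum component size is built per direction by
    Freedman-Lane: responses are residualized on the reduced
    (covariate-only) model, residual rows are shuffled, refitted values
    are added back, and the full model is re-estimated. With no
    covariates this reduces exactly to shuffling group labels. If the
    group labelling admits fewer distinct rearrangements than ``n_perm``,
    all of them are enumerated instead (exact test). FWE p-values use
    the add-one convention p = (1 + #{null >= observed}) / (1 + n_perm),
    so p >= 1/(n_perm + 1) always.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stack = np.asarray(edge_data, dtype=float)
    n_sub, n_nodes, _ = stack.shape
    X, coef, _ = build_design(group, covariates)
    Y = upper_triangle(stack)
    t_vec, p_vec = _glm_t(Y, X, coef)
    edge_t = vector_to_matrix(t_vec, n_nodes)
    edge_p = _p_to_matrix(p_vec, n_nodes)

    components = []
    for direction in (+1, -1):
        components.extend(
            extract_components(edge_p, primary_p, direction, edge_t=edge_t)
        )

    # reduced model: everything but the group column
    Z = np.delete(X, coef, axis=1)
    beta_z = np.linalg.pinv(Z) @ Y
    fitted = Z @ beta_z
    resid = Y - fitted

    g = X[:, coef]
    n_distinct = comb(n_sub, int(g.sum()))
    exhaustive = n_distinct <= n_perm
    rng = np.random.default_rng(seed)
    if exhaustive:
        indicators = _exhaustive_indicators(g)
        n_used = indicators.shape[0]
    else:
        n_used = n_perm

    null_max = {+1: np.zeros(n_used), -1: np.zeros(n_used)}
    for r in range(n_used):
        if exhaustive:
            Xp = X.copy()
            Xp[:, coef] = indicators[r]
            tp, pp = _glm_t(Y, Xp, coef)
        else:
            perm = rng.permutation(n_sub)
            Yp = fitted + resid[perm]
            tp, pp = _glm_t(Yp, X, coef)
        mask = pp < primary_p
        for direction in (+1, -1):
            dm = mask & (np.sign(tp) == direction)
            if not dm.any():
                continue
            m = vector_to_matrix(dm.astype(float), n_nodes) > 0
            _, labels = connected_components(csr_matrix(m), directed=False)
            iu, ju = np.nonzero(np.triu(m, k=1))
            sizes = np.bincount(labels[iu])
            null_max[direction][r] = sizes.max() if sizes.size else 0

    for c in components:
        null = null_max[c.direction]
        c.p_fwe = float((1 + (null >= c.size).sum()) / (1 + len(null)))

    return NbsResult(
        edge_t=edge_t,
        edge_p=edge_p,
        primary_p=primary_p,
        components=components,
        null_max_sizes={k: v for k, v in null_max.items()},
        n_perm=n_used,
        alpha=alpha,
    )
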