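"""Sliding-window connectivity and its temporal variability.

Windowed Pearson correlation matrices, Fisher z-transformed, computed
with a rectangular window by default (a Gaussian taper is available for
sensitivity analyses). With the reference acquisition — 240 volumes at
TR = 2 s, first 10 discarded, window 50 TR, step 2 TR — each subject
yields 91 windows.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import RoiTimeSeries

__all__ = [
    "WindowParams",
    "WindowedFC",
    "count_windows",
    "window_connectivity",
    "dfc_variability",
    "seed_to_target_variability",
    "upper_triangle",
    "vector_to_matrix",
]

#: Fisher-z values are capped at atanh of this correlation so that
#: numerically perfect correlations stay finite.
R_CAP = 0.999999
Z_CAP = float(np.arctanh(R_CAP))


@dataclasses.dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry: width and step in TR units, plus taper."""

    width_tr: int = 50
    step_tr: int = 2
    taper: str = "rectangular"  # or "gaussian"
    gaussian_sigma_tr: float | None = None

    def __post_init__(self) -> None:
        if self.width_tr < 3:
            raise ValueError("window width must be >= 3 TR")
        if self.step_tr < 1:
            raise ValueError("window step must be >= 1 TR")
        if self.taper not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.taper == "gaussian" and not (
            self.gaussian_sigma_tr and self.gaussian_sigma_tr > 0
        ):
            raise ValueError("gaussian taper needs positive gaussian_sigma_tr")

    def weights(self) -> np.ndarray:
        if self.taper == "rectangular":
            return np.ones(self.width_tr)
        t = np.arange(self.width_tr) - (self.width_tr - 1) / 2.0
        return np.exp(-0.5 * (t / self.gaussian_sigma_tr) ** 2)


@dataclasses.dataclass
class WindowedFC:
    """Per-subject stack of Fisher-z connectivity matrices.

    ``z`` has shape (N_w, N, N); every slice is symmetric with zero
    diagonal.
    """

    subject_id: str
    z: np.ndarray
    params: WindowParams
    node_ids: Sequence[str] = ()
    tr_seconds: float = 2.0

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.z.shape[1]


def count_windows(T: int, width: int, step: int) -> int:
    """Number of sliding windows: floor((T - width) / step) + 1."""
    if width > T:
        raise ValueError(f"window width {width} exceeds T={T}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return (T - width) // step + 1


def _weighted_correlation(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of columns of x."""
    wn = w / w.sum()
    mu = wn @ x
    xc = x - mu
    cov = (xc * wn[:, None]).T @ xc
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd, sd)
    r[~np.isfinite(r)] = 0.0
    const = np.ptp(x, axis=0) == 0  # constant columns: correlation undefined -> 0
    r[const, :] = 0.0
    r[:, const] = 0.0
    return np.clip(r, -1.0, 1.0)


def window_connectivity(ts: RoiTimeSeries, params: WindowParams) -> WindowedFC:
    """Windowed Fisher-z connectivity stack for one subject.

    Window w covers rows [w*step, w*step + width). Correlations of
    constant-in-window columns are set to 0 with a warning; |z| is capped
    at atanh(0.999999).
    """
    T = ts.n_timepoints
    n_w = count_windows(T, params.width_tr, params.step_tr)
    w = params.weights()
    z = np.empty((n_w, ts.n_nodes, ts.n_nodes))
    warned = False
    for i in range(n_w):
        seg = ts.data[i * params.step_tr : i * params.step_tr + params.width_tr]
        if not warned and np.any(seg.std(axis=0) == 0):
            warnings.warn(
                f"{ts.subject_id}: constant column inside a window; "
                "affected correlations set to 0",
                stacklevel=2,
            )
            warned = True
        r = _weighted_correlation(seg, w)
        np.clip(r, -R_CAP, R_CAP, out=r)
        zi = np.arctanh(r)
        np.fill_diagonal(zi, 0.0)
        z[i] = (zi + zi.T) / 2.0  # enforce exact symmetry
    return WindowedFC(
        subject_id=ts.subject_id,
        z=z,
        params=params,
        node_ids=ts.node_ids,
        tr_seconds=ts.tr_seconds,
    )


def dfc_variability(wfc: WindowedFC, ddof: int = 1) -> np.ndarray:
    """Per-edge standard deviation of Fisher-z connectivity across windows.

    The (i, j) entry is the sample (n-1) standard deviation of z_w(i, j)
    over windows; symmetric, zero diagonal.
    """
    if wfc.n_windows < 2:
        raise ValueError("dfc_variability needs at least 2 windows")
    sd = wfc.z.std(axis=0, ddof=ddof)
    np.fill_diagonal(sd, 0.0)
    return sd


def seed_to_target_variability(
    wfc: WindowedFC, seed_nodes: Sequence[str], target_nodes: Sequence[str]
) -> np.ndarray:
    """Seed-to-parcel dFC variability: rows = seeds, cols = targets.

    Parcel-level analogue of seed-based voxelwise variability maps: the
    across-window sd of the Fisher-z connectivity from each seed node
    (e.g. a cerebellar ROI) to each target node (e.g. cerebral parcels).
    """
    sd = dfc_variability(wfc)
    idx = {n: i for i, n in enumerate(wfc.node_ids)}
    si = [idx[n] for n in seed_nodes]
    ti = [idx[n] for n in target_nodes]
    return sd[np.ix_(si, ti)]


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix (row-major)."""
    iu = np.triu_indices(mat.shape[-1], k=1)
    return mat[..., iu[0], iu[1]]


def vector_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle`: symmetric matrix, zero diagonal."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    return m + m.T


def save_windowed_fc(wfc: WindowedFC, path) -> None:
    """Persist as compressed npz with a JSON sidecar of parameters."""
    path = Path(path)
    np.savez_compressed(path, z=wfc.z)
    sidecar = dict(
        subject_id=wfc.subject_id,
        node_ids=list(wfc.node_ids),
        tr_seconds=wfc.tr_seconds,
        params=dataclasses.asdict(wfc.params),
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_windowed_fc(path) -> WindowedFC:
    path = Path(path)
    z = np.load(path.with_suffix(".npz"))["z"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return WindowedFC(
        subject_id=meta["subject_id"],
        z=z,
        params=WindowParams(**meta["params"]),
        node_ids=meta["node_ids"],
        tr_seconds=meta["tr_seconds"],
    )
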