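"""Reading, validation and serialization of parcellated BOLD inputs.

The pipeline operates on ROI-level (parcellated) time series: one T x N
matrix per subject, where rows are volumes acquired every ``tr_seconds``
and columns are atlas nodes. Voxel-level preprocessing (realignment,
normalization, nuisance regression, filtering) happens upstream and is
out of scope here; an optional helper extracts sphere-averaged series
from a preprocessed 4D NIfTI for real-data use.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "AtlasSpec",
    "MotionDecision",
    "ValidationError",
    "load_timeseries",
    "write_timeseries",
    "load_atlas",
    "write_atlas",
    "load_subjects",
    "screen_motion",
    "extract_sphere_timeseries",
]

#: Closed vocabulary of network labels. The first eight are the cerebellar
#: networks of the parcellation; the remainder are standard cerebral labels
#: used by the whole-brain mode.
CEREBELLAR_NETWORKS = (
    "DMN",
    "FPN",
    "CON",
    "DAN",
    "SN",
    "SMN-dorsal",
    "SMN-lateral",
    "VN",
)
CEREBRAL_NETWORKS = (
    "DMN",
    "FPN",
    "CON",
    "DAN",
    "SN",
    "SMN-dorsal",
    "SMN-lateral",
    "VN",
    "LN",
    "AUD",
    "MTL",
    "RTN",
    "unassigned",
)
KNOWN_NETWORKS = tuple(sorted(set(CEREBELLAR_NETWORKS) | set(CEREBRAL_NETWORKS)))


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


@dataclasses.dataclass
class RoiTimeSeries:
    """One subject's parcellated time series.

    Parameters
    ----------
    subject_id : str
        Unique subject label.
    data : ndarray, shape (T, N)
        BOLD signal, arbitrary units; T counted after any discard step.
    tr_seconds : float
        Repetition time in seconds.
    node_ids : sequence of str
        Atlas node labels, one per column.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    node_ids: Sequence[str]
    constant_nodes: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: time series must be 2-D, got shape {self.data.shape}"
            )
        if self.tr_seconds <= 0:
            raise ValidationError(f"{self.subject_id}: tr_seconds must be positive")
        if len(self.node_ids) != self.data.shape[1]:
            raise ValidationError(
                f"{self.subject_id}: {len(self.node_ids)} node ids for "
                f"{self.data.shape[1]} columns"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted({n for n in self.node_ids if list(self.node_ids).count(n) > 1})
            raise ValidationError(f"{self.subject_id}: duplicated node ids {dupes}")
        if not np.all(np.isfinite(self.data)):
            t, n = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"{self.subject_id}: non-finite value at row {t}, column "
                f"{self.node_ids[n]!r}"
            )
        # Constant columns are legal but flagged: their windowed correlations
        # are undefined and will be zeroed downstream.
        sd = self.data.std(axis=0)
        self.constant_nodes = tuple(
            str(self.node_ids[j]) for j in np.flatnonzero(sd == 0)
        )
        self.node_ids = tuple(str(n) for n in self.node_ids)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def reorder(self, node_order: Sequence[str]) -> "RoiTimeSeries":
        """Return a copy with columns permuted to ``node_order`` (lossless)."""
        missing = [n for n in node_order if n not in self.node_ids]
        if missing:
            raise ValidationError(f"{self.subject_id}: nodes not in series: {missing}")
        if sorted(node_order) != sorted(self.node_ids):
            raise ValidationError(
                f"{self.subject_id}: node_order is not a permutation of the series nodes"
            )
        idx = [self.node_ids.index(n) for n in node_order]
        return RoiTimeSeries(
            subject_id=self.subject_id,
            data=self.data[:, idx],
            tr_seconds=self.tr_seconds,
            node_ids=[self.node_ids[i] for i in idx],
        )


@dataclasses.dataclass
class AtlasSpec:
    """Node table of a spherical-ROI atlas: id, MNI centre, network, radius."""

    table: pd.DataFrame  # columns: node_id, x, y, z, network, radius_mm

    REQUIRED = ("node_id", "x", "y", "z", "network", "radius_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"atlas missing columns {missing}")
        ids = self.table["node_id"].astype(str)
        if ids.duplicated().any():
            raise ValidationError(
                f"atlas has duplicated node ids: {sorted(ids[ids.duplicated()])}"
            )
        bad = sorted(set(self.table["network"]) - set(KNOWN_NETWORKS))
        if bad:
            raise ValidationError(
                f"atlas networks {bad} not in declared vocabulary {KNOWN_NETWORKS}"
            )
        if (self.table["radius_mm"] <= 0).any():
            raise ValidationError("atlas radius_mm must be positive")
        self.table = self.table.assign(node_id=ids).reset_index(drop=True)

    @property
    def node_ids(self) -> tuple:
        return tuple(self.table["node_id"])

    @property
    def networks(self) -> tuple:
        return tuple(self.table["network"])

    def __len__(self) -> int:
        return len(self.table)


@dataclasses.dataclass(frozen=True)
class MotionDecision:
    keep: bool
    reason: str


def load_timeseries(
    path,
    tr_seconds: float,
    discard_initial: int = 0,
    subject_id: str | None = None,
    atlas: AtlasSpec | None = None,
) -> RoiTimeSeries:
    """Load a TSV/CSV time-series file (header row of node ids).

    The first ``discard_initial`` volumes are dropped before T is recorded,
    mirroring the usual discard of pre-steady-state volumes. If ``atlas``
    is given, columns are reordered to atlas order.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path.name}: non-numeric cell at row {row}, column {col!r}"
            )
    if df.isna().any().any():
        col = df.columns[int(np.argmax(df.isna().any().values))]
        raise ValidationError(f"{path.name}: missing value in column {col!r}")
    if discard_initial < 0:
        raise ValidationError("discard_initial must be >= 0")
    if len(df) <= discard_initial:
        raise ValidationError(
            f"{path.name}: {len(df)} rows <= discard_initial={discard_initial}"
        )
    data = df.iloc[discard_initial:].to_numpy(dtype=float)
    ts = RoiTimeSeries(
        subject_id=subject_id or path.stem,
        data=data,
        tr_seconds=tr_seconds,
        node_ids=list(df.columns),
    )
    if atlas is not None:
        ts = ts.reorder(atlas.node_ids)
    return ts


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    """Write a series as TSV with full float precision (exact round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ts.node_ids) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.17g")


def load_atlas(path) -> AtlasSpec:
    return AtlasSpec(pd.read_csv(path, sep="\t"))


def write_atlas(atlas: AtlasSpec, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def load_subjects(path) -> pd.DataFrame:
    """Load the subjects table (group label, demographics, clinical scores)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValidationError("subjects table needs 'subject_id' and 'group' columns")
    return df


def screen_motion(
    max_translation_mm: float,
    max_rotation_deg: float,
    translation_limit_mm: float = 1.5,
    rotation_limit_deg: float = 1.5,
) -> MotionDecision:
    """Head-motion inclusion rule: exclude iff motion strictly exceeds a limit.

    The boundary is inclusive (exactly 1.5 mm is kept): the criterion is
    "more than" the limit, read literally.
    """
    if translation_limit_mm <= 0 or rotation_limit_deg <= 0:
        raise ValueError("motion limits must be positive")
    if max_translation_mm is None or max_rotation_deg is None or not (
        np.isfinite(max_translation_mm) and np.isfinite(max_rotation_deg)
    ):
        raise ValidationError("missing motion summary")
    if max_translation_mm > translation_limit_mm:
        return MotionDecision(
            False, f"translation {max_translation_mm} mm > {translation_limit_mm} mm"
        )
    if max_rotation_deg > rotation_limit_deg:
        return MotionDecision(
            False, f"rotation {max_rotation_deg} deg > {rotation_limit_deg} deg"
        )
    return MotionDecision(True, "within limits")


def extract_sphere_timeseries(
    nifti_path,
    atlas: AtlasSpec,
    tr_seconds: float,
    subject_id: str = "subject",
    brain_mask_path=None,
) -> RoiTimeSeries:
    """Average a 4D NIfTI within spheres around each atlas MNI coordinate.

    Optional real-data entry point; requires nibabel. Sphere membership is
    nearest-voxel: a voxel belongs to the sphere if its world-space centre
    lies within ``radius_mm`` of the node coordinate. If a brain mask is
    given, out-of-mask voxels are excluded; otherwise the full sphere is
    used (whether published extractions mask is not standardized).
    """
    import nibabel as nib  # optional dependency

    img = nib.load(str(nifti_path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValidationError(f"expected 4D image, got shape {vol.shape}")
    affine = img.affine
    mask = None
    if brain_mask_path is not None:
        mask = np.asarray(nib.load(str(brain_mask_path)).dataobj) > 0
    ijk = np.indices(vol.shape[:3]).reshape(3, -1)
    world = affine[:3, :3] @ ijk + affine[:3, 3:4]  # 3 x V
    series = np.empty((vol.shape[3], len(atlas)))
    flat = vol.reshape(-1, vol.shape[3])
    for j, row in atlas.table.iterrows():
        d2 = ((world - np.array([[row.x], [row.y], [row.z]])) ** 2).sum(axis=0)
        sel = d2 <= row.radius_mm ** 2
        if mask is not None:
            sel &= mask.reshape(-1)
        if not sel.any():
            raise ValidationError(f"node {row.node_id}: empty sphere")
        series[:, j] = flat[sel].mean(axis=0)
    return RoiTimeSeries(
        subject_id=subject_id,
        data=series,
        tr_seconds=tr_seconds,
        node_ids=list(atlas.node_ids),
    )
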