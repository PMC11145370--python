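"""Synthetic two-group cohorts with state-switching connectivity.

The generator emulates resting-state cohorts in which windowed
connectivity alternates between a small number of recurring patterns:
each subject's T x N series is drawn from a hidden Markov chain over K
connectivity "states", with observation x_t ~ N(mu, Sigma_{z_t}) plus
isotropic noise. The default world is the two-state, two-group setting
of sleep-apnea connectomics studies: a hypoconnected baseline state and
a hyperconnected integrated state over a 27-node cerebellar parcellation
grouped into 8 functional networks, with patients dwelling longer in the
hyperconnected state. A matched clinical table (apnea severity,
cognition, mood, sleep scores) is drawn with controlled Spearman
coupling to each subject's true hyper-state occupancy via a Gaussian
copula, so every downstream estimator has known ground truth.

No hemodynamic forward model or scanner physics is attempted; the output
is already-parcellated signal.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AtlasSpec, RoiTimeSeries, write_atlas, write_timeseries

__all__ = [
    "GroundTruth",
    "default_atlas",
    "default_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "DEFAULT_CLINICAL_EFFECTS",
    "CLINICAL_MARGINALS",
]

# Cerebellar networks and node counts summing to 27.
_CEREBELLAR_BLOCKS = (
    ("DMN", 5),
    ("FPN", 4),
    ("CON", 3),
    ("DAN", 3),
    ("SN", 3),
    ("SMN-dorsal", 3),
    ("SMN-lateral", 3),
    ("VN", 3),
)

# Clinical marginals per group as (mean, sd, low, high): published-scale
# group summaries for patients (OSA) and controls (HC). REM and sleep
# efficiency are stored as percentages in [0, 100].
CLINICAL_MARGINALS: dict[str, dict[str, tuple]] = {
    "age": {"patient": (37.88, 9.08, 18, 60), "control": (41.25, 10.47, 18, 60)},
    "education": {"patient": (12.07, 3.73, 0, 22), "control": (11.53, 3.17, 0, 22)},
    "bmi": {"patient": (26.90, 3.65, 15, 45), "control": (20.86, 1.63, 15, 45)},
    "head_motion": {"patient": (0.13, 0.06, 0.0, 1.5), "control": (0.12, 0.06, 0.0, 1.5)},
    "AHI": {"patient": (49.42, 18.11, 15, 120), "control": (2.20, 1.18, 0, 5)},
    "MoCA": {"patient": (24.35, 2.89, 0, 30), "control": (28.00, 1.46, 0, 30)},
    "HAMD": {"patient": (8.47, 6.21, 0, 52), "control": (4.03, 2.77, 0, 52)},
    "HAMA": {"patient": (8.98, 4.76, 0, 56), "control": (5.77, 2.76, 0, 56)},
    "PSQI": {"patient": (7.88, 3.38, 0, 21), "control": (3.63, 1.65, 0, 21)},
    "ESS": {"patient": (10.53, 4.36, 0, 24), "control": (1.52, 1.42, 0, 24)},
    "REM_pct": {"patient": (13.57, 11.01, 0, 100), "control": (18.31, 5.70, 0, 100)},
    "SE_pct": {"patient": (86.0, 17.0, 0, 100), "control": (92.0, 4.0, 0, 100)},
}

#: Default Spearman coupling between clinical scores and true
#: hyper-state occupancy. Signs follow the reported correlation
#: directions (worse cognition / mood / sleep with more time in the
#: hyperconnected state); magnitudes are moderate since no effect sizes
#: are published for these couplings.
DEFAULT_CLINICAL_EFFECTS: dict[str, float] = {
    "MoCA": -0.3,
    "HAMD": 0.3,
    "PSQI": 0.2,
    "ESS": 0.2,
    "REM_pct": -0.3,
}


def default_atlas(whole_brain: bool = False, seed: int = 0) -> AtlasSpec:
    """Synthetic spherical-ROI atlas: 27 cerebellar nodes in 8 networks.

    Coordinates are plausible cerebellar MNI positions generated
    deterministically; they stand in for a real parcellation table and
    carry no anatomical claim. ``whole_brain=True`` appends 273 cerebral
    nodes for the seed-to-parcel variability analysis.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for network, count in _CEREBELLAR_BLOCKS:
        for _ in range(count):
            i += 1
            rows.append(
                dict(
                    node_id=f"CB{i:02d}",
                    x=round(float(rng.uniform(-45, 45)), 1),
                    y=round(float(rng.uniform(-90, -40)), 1),
                    z=round(float(rng.uniform(-60, -15)), 1),
                    network=network,
                    radius_mm=4.0,
                )
            )
    if whole_brain:
        cerebral = (
            ("DMN", 45), ("FPN", 35), ("CON", 30), ("DAN", 25), ("SN", 20),
            ("SMN-dorsal", 30), ("SMN-lateral", 20), ("VN", 30), ("LN", 15),
            ("AUD", 10), ("MTL", 8), ("RTN", 5),
        )
        j = 0
        for network, count in cerebral:
            for _ in range(count):
                j += 1
                rows.append(
                    dict(
                        node_id=f"CX{j:03d}",
                        x=round(float(rng.uniform(-65, 65)), 1),
                        y=round(float(rng.uniform(-100, 70)), 1),
                        z=round(float(rng.uniform(-30, 75)), 1),
                        network=network,
                        radius_mm=4.0,
                    )
                )
    return AtlasSpec(pd.DataFrame(rows))


def _block_correlation(
    networks: Sequence[str], r_within: float, r_between: float
) -> np.ndarray:
    """Unit-diagonal correlation matrix with network-block structure."""
    networks = np.asarray(networks)
    same = networks[:, None] == networks[None, :]
    C = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def _nearest_pd_correlation(C: np.ndarray) -> np.ndarray:
    """Ridge-repair to positive definiteness, then renormalize diagonal."""
    w = np.linalg.eigvalsh(C)
    if w.min() <= 1e-10:
        C = C + (1e-6 - w.min()) * np.eye(len(C))
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


@dataclasses.dataclass
class GroundTruth:
    """Generating model: per-state covariances and per-group Markov chains.

    ``state_covariances`` are on the correlation scale (unit diagonal);
    state order is weakest-connected first, matching the downstream
    convention that state 1 is the hypoconnected pattern.
    """

    n_states: int
    state_covariances: list  # K matrices, N x N, positive definite
    transition_matrix_per_group: Mapping[str, np.ndarray]  # K x K row-stochastic
    mean_vector: np.ndarray
    observation_noise_sd: float
    seed: int
    atlas: AtlasSpec | None = None

    def __post_init__(self) -> None:
        self.state_covariances = [
            np.asarray(S, dtype=float) for S in self.state_covariances
        ]
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        if self.n_states != len(self.state_covariances):
            raise ValueError("n_states does not match number of covariances")
        n = len(self.mean_vector)
        for k, S in enumerate(self.state_covariances):
            if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-12):
                raise ValueError(f"state {k}: covariance not symmetric {n}x{n}")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"state {k}: covariance not positive definite")
        self.transition_matrix_per_group = {
            g: np.asarray(P, dtype=float)
            for g, P in self.transition_matrix_per_group.items()
        }
        for g, P in self.transition_matrix_per_group.items():
            if P.shape != (self.n_states, self.n_states):
                raise ValueError(f"group {g}: transition matrix wrong shape")
            if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"group {g}: rows must be stochastic (sum to 1)")
        if self.observation_noise_sd <= 0:
            raise ValueError("observation_noise_sd must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.mean_vector)

    def expected_dwell(self, group: str) -> np.ndarray:
        """Closed-form mean dwell time 1 / (1 - P[k, k]) per state."""
        P = self.transition_matrix_per_group[group]
        return 1.0 / (1.0 - np.diag(P))

    def stationary_distribution(self, group: str) -> np.ndarray:
        P = self.transition_matrix_per_group[group]
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        return pi / pi.sum()

    def to_json(self) -> str:
        payload = dict(
            n_states=self.n_states,
            state_covariances=[S.tolist() for S in self.state_covariances],
            transition_matrix_per_group={
                g: P.tolist() for g, P in self.transition_matrix_per_group.items()
            },
            mean_vector=self.mean_vector.tolist(),
            observation_noise_sd=self.observation_noise_sd,
            seed=self.seed,
        )
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str, atlas: AtlasSpec | None = None) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            n_states=d["n_states"],
            state_covariances=[np.array(S) for S in d["state_covariances"]],
            transition_matrix_per_group={
                g: np.array(P) for g, P in d["transition_matrix_per_group"].items()
            },
            mean_vector=np.array(d["mean_vector"]),
            observation_noise_sd=d["observation_noise_sd"],
            seed=d["seed"],
            atlas=atlas,
        )


def default_ground_truth(
    whole_brain: bool = False,
    seed: int = 0,
    connectivity_scale: tuple[float, float] = (0.55, 1.6),
    r_within: float = 0.35,
    r_between: float = 0.10,
    observation_noise_sd: float = 0.25,
) -> GroundTruth:
    """Two-state, two-group default world.

    Both states share the network-block base correlation structure; a
    global strength multiplier makes state 1 hypoconnected and state 2
    hyperconnected. Controls favour the baseline state; patients switch
    into, and persist in, the hyperconnected state more (longer state-2
    dwell, higher state-2 frequency).
    """
    atlas = default_atlas(whole_brain=whole_brain, seed=seed)
    base = _block_correlation(atlas.networks, r_within, r_between)
    covs = []
    off = base - np.eye(len(base))
    for scale in connectivity_scale:
        covs.append(_nearest_pd_correlation(np.eye(len(base)) + scale * off))
    transition = {
        # expected dwell: control 20 / ~6.7 TR, patient 10 / 10 TR
        "control": np.array([[0.95, 0.05], [0.15, 0.85]]),
        "patient": np.array([[0.90, 0.10], [0.10, 0.90]]),
    }
    return GroundTruth(
        n_states=2,
        state_covariances=covs,
        transition_matrix_per_group=transition,
        mean_vector=np.zeros(len(base)),
        observation_noise_sd=observation_noise_sd,
        seed=seed,
        atlas=atlas,
    )


def _simulate_chain(P: np.ndarray, T: int, rng: np.random.Generator,
                    initial: np.ndarray | None = None) -> np.ndarray:
    K = P.shape[0]
    if initial is None:
        # start from the stationary distribution so occupancy is unbiased
        w, v = np.linalg.eig(P.T)
        initial = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        initial = np.abs(initial) / np.abs(initial).sum()
    cum = np.cumsum(P, axis=1)
    z = np.empty(T, dtype=np.int64)
    z[0] = rng.choice(K, p=initial)
    u = rng.random(T - 1)
    for t in range(1, T):
        z[t] = np.searchsorted(cum[z[t - 1]], u[t - 1], side="right")
    return z


def simulate_subject(
    gt: GroundTruth,
    group: str,
    T: int = 230,
    seed: int = 0,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
    initial_state: int | None = None,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Draw one subject's series and its latent state path.

    x_t = mu + L_{z_t} e_t + sigma_noise eta_t with e, eta iid standard
    normal and L_k the Cholesky factor of state k's covariance. Identical
    seed gives identical output.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if group not in gt.transition_matrix_per_group:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    P = gt.transition_matrix_per_group[group]
    initial = None
    if initial_state is not None:
        initial = np.zeros(gt.n_states)
        initial[initial_state] = 1.0
    z = _simulate_chain(P, T, rng, initial)
    chols = [np.linalg.cholesky(S) for S in gt.state_covariances]
    e = rng.standard_normal((T, gt.n_nodes))
    x = np.empty((T, gt.n_nodes))
    for k in range(gt.n_states):
        sel = z == k
        if sel.any():
            x[sel] = e[sel] @ chols[k].T
    x += gt.observation_noise_sd * rng.standard_normal((T, gt.n_nodes))
    x += gt.mean_vector
    node_ids = gt.atlas.node_ids if gt.atlas is not None else [
        f"node{j:03d}" for j in range(gt.n_nodes)
    ]
    ts = RoiTimeSeries(
        subject_id=subject_id or f"{group}_s{seed}",
        data=x,
        tr_seconds=tr_seconds,
        node_ids=list(node_ids),
    )
    return ts, z


def _truncnorm_ppf(q: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def _mixture_ppf(q: np.ndarray, specs: Sequence[tuple], weights: Sequence[float],
                 n_grid: int = 2048) -> np.ndarray:
    """Quantile function of a mixture of truncated normals (grid-inverted)."""
    lo = min(s[2] for s in specs)
    hi = max(s[3] for s in specs)
    grid = np.linspace(lo, hi, n_grid)
    cdf = np.zeros(n_grid)
    for (mean, sd, a, b), w in zip(specs, weights):
        ta, tb = (a - mean) / sd, (b - mean) / sd
        cdf += w * stats.truncnorm.cdf(grid, ta, tb, loc=mean, scale=sd)
    cdf[0], cdf[-1] = 0.0, 1.0
    return np.interp(q, cdf, grid)


def simulate_cohort(
    gt: GroundTruth,
    n_per_group: int = 60,
    T: int = 230,
    clinical_model: Mapping[str, float] | None = None,
    seed: int = 0,
    tr_seconds: float = 2.0,
) -> tuple[list[RoiTimeSeries], pd.DataFrame, list[np.ndarray]]:
    """Simulate a full two-group cohort plus its clinical table.

    ``clinical_model`` maps score name -> target Spearman rho between the
    score and the subject's true occupancy of the last (hyperconnected)
    state, pooled over the cohort. Coupling uses a Gaussian copula: the
    occupancy ranks are converted to normal scores u, a latent
    v = r u + sqrt(1-r^2) eps is drawn with r = 2 sin(pi rho / 6) (the
    Pearson latent correlation that yields Spearman rho), and v is pushed
    through a marginal transform. Coupled scores use the *pooled*
    two-group mixture marginal — a common monotone map, so the pooled
    sample Spearman hits the target up to sampling noise, and group mean
    differences in coupled scores emerge through the groups' occupancy
    difference (in the published directions when signs align). Scores
    without a stated coupling use their group-specific truncated-normal
    marginals, which reproduces the published group contrasts (e.g. the
    large apnea-severity gap) independently of the dynamics.

    Returns (series list, subjects table, latent state paths).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    effects = dict(DEFAULT_CLINICAL_EFFECTS if clinical_model is None else clinical_model)
    for name, rho in effects.items():
        if abs(rho) >= 1:
            raise ValueError(f"clinical effect rho for {name!r} must satisfy |rho| < 1")
        if name not in CLINICAL_MARGINALS:
            raise ValueError(f"unknown clinical score {name!r}")
    rng = np.random.default_rng(seed)
    series: list[RoiTimeSeries] = []
    paths: list[np.ndarray] = []
    records: list[dict] = []
    groups = ["patient"] * n_per_group + ["control"] * n_per_group
    for i, group in enumerate(groups):
        sid = f"{'osa' if group == 'patient' else 'hc'}{i % n_per_group + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ts, z = simulate_subject(gt, group, T=T, seed=sub_seed, subject_id=sid,
                                 tr_seconds=tr_seconds)
        series.append(ts)
        paths.append(z)
        records.append(dict(subject_id=sid, group=group))
    occ = np.array([(z == gt.n_states - 1).mean() for z in paths])
    df = pd.DataFrame(records)
    df["true_occupancy_hyper"] = occ
    # normal scores of occupancy ranks (mid-rank convention, ties averaged)
    u = stats.norm.ppf((stats.rankdata(occ) - 0.5) / len(occ))
    for name, spec in CLINICAL_MARGINALS.items():
        rho = effects.get(name, 0.0)
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        v = r * u + np.sqrt(1.0 - r * r) * rng.standard_normal(len(occ))
        q = stats.norm.cdf(v)
        if rho != 0.0:
            vals = _mixture_ppf(q, [spec["patient"], spec["control"]], [0.5, 0.5])
        else:
            vals = np.empty(len(occ))
            for g in ("patient", "control"):
                sel = (df["group"] == g).to_numpy()
                mean, sd, lo, hi = spec[g]
                vals[sel] = _truncnorm_ppf(q[sel], mean, sd, lo, hi)
        digits = 3 if name == "head_motion" else 2
        df[name] = np.round(vals, digits)
    int_scores = ("education", "MoCA", "HAMD", "HAMA", "PSQI", "ESS")
    for name in int_scores:
        df[name] = np.round(df[name]).astype(int)
    return series, df, paths


def write_cohort(
    out_dir,
    series: list[RoiTimeSeries],
    subjects: pd.DataFrame,
    gt: GroundTruth,
    paths: list[np.ndarray] | None = None,
) -> None:
    """Persist a cohort: per-subject TSV, subjects CSV, atlas TSV, truth JSON."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in series:
        write_timeseries(ts, out / "timeseries" / f"{ts.subject_id}.tsv")
    subjects.to_csv(out / "subjects.csv", index=False)
    if gt.atlas is not None:
        write_atlas(gt.atlas, out / "atlas.tsv")
    (out / "ground_truth.json").write_text(gt.to_json())
    if paths is not None:
        state_df = pd.DataFrame(
            {ts.subject_id: z for ts, z in zip(series, paths)}
        )
        state_df.to_csv(out / "latent_states.csv", index=False)
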