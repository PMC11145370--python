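"""End-to-end pipeline: simulate -> dfc -> states -> graph -> hmm -> nbs -> stats.

A single YAML/ dict config drives every stage; one global seed fans out
to per-stage seeds through a declared derivation (CRC-32 of the stage
name XOR the global seed, mod 2^31 - 1), so stages are reproducible
independently. Each stage writes its artifacts plus a provenance
manifest (stage, config hash, seed, package version) into the run
directory, and is skipped on re-run if its outputs already exist —
deleting a stage's outputs and re-running regenerates them identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graph as graphmod
from . import hmm as hmmmod
from . import nbs as nbsmod
from . import stats as statsmod
from .io import load_atlas, load_timeseries
from .states import cohort_temporal_metrics, fit_states, select_k, pool_windows
from .synthetic import GroundTruth, default_ground_truth, simulate_cohort, write_cohort
from .windows import (
    WindowParams,
    dfc_variability,
    load_windowed_fc,
    save_windowed_fc,
    window_connectivity,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dfc", "states", "graph", "hmm", "nbs", "stats", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: crc32(stage) XOR global seed, below 2^31."""
    return (zlib.crc32(stage.encode("utf-8")) ^ int(global_seed)) % (2**31 - 1)


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    n_per_group: int = 20
    T: int = 230
    tr_seconds: float = 2.0
    window_width_tr: int = 50
    window_step_tr: int = 2
    taper: str = "rectangular"
    gaussian_sigma_tr: float | None = None
    k_range: tuple = (2, 6)
    kmeans_replicates: int = 20
    distance: str = "euclidean"
    sparsity_start: float = 0.05
    sparsity_stop: float = 0.40
    sparsity_step: float = 0.01
    graph_n_null: int = 20
    graph_use_abs: bool = True
    graph_small_world: bool = True
    hmm_n_init: int = 5
    hmm_max_iter: int = 200
    hmm_tol: float = 1e-4
    nbs_primary_p: float = 1e-4
    nbs_n_perm: int = 5000
    nbs_alpha: float = 0.005
    stats_covariates: tuple = ("age", "education", "bmi", "head_motion")
    stats_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - valid)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        WindowParams(self.window_width_tr, self.window_step_tr, self.taper,
                     self.gaussian_sigma_tr)
        graphmod.SparsityRamp(self.sparsity_start, self.sparsity_stop,
                              self.sparsity_step)
        lo, hi = self.k_range
        if not (2 <= lo <= hi <= 10):
            raise ValueError("k_range must satisfy 2 <= lo <= hi <= 10")
        if self.n_per_group < 2 or self.T < self.window_width_tr:
            raise ValueError("n_per_group >= 2 and T >= window width required")

    @property
    def window_params(self) -> WindowParams:
        return WindowParams(self.window_width_tr, self.window_step_tr,
                            self.taper, self.gaussian_sigma_tr)

    @property
    def ramp(self) -> graphmod.SparsityRamp:
        return graphmod.SparsityRamp(self.sparsity_start, self.sparsity_stop,
                                     self.sparsity_step)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(run_dir: Path, stage: str, cfg: RunConfig) -> None:
    from . import __version__

    (run_dir / f"{stage}.manifest.json").write_text(
        json.dumps(
            dict(
                stage=stage,
                seed=stage_seed(cfg.seed, stage),
                config_hash=cfg.config_hash(),
                version=__version__,
            ),
            indent=1,
        )
    )


def _load_cohort_series(run_dir: Path, cfg: RunConfig):
    atlas = load_atlas(run_dir / "data" / "atlas.tsv")
    subjects = pd.read_csv(run_dir / "data" / "subjects.csv")
    series = [
        load_timeseries(
            run_dir / "data" / "timeseries" / f"{sid}.tsv",
            tr_seconds=cfg.tr_seconds,
            atlas=atlas,
        )
        for sid in subjects["subject_id"]
    ]
    return atlas, subjects, series


def _stage_simulate(run_dir: Path, cfg: RunConfig) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    gt = default_ground_truth(seed=seed)
    series, subjects, paths = simulate_cohort(
        gt, n_per_group=cfg.n_per_group, T=cfg.T, seed=seed,
        tr_seconds=cfg.tr_seconds,
    )
    write_cohort(run_dir / "data", series, subjects, gt, paths)


def _stage_dfc(run_dir: Path, cfg: RunConfig) -> None:
    _, subjects, series = _load_cohort_series(run_dir, cfg)
    out = run_dir / "dfc"
    out.mkdir(exist_ok=True)
    var_rows = []
    for ts in series:
        wfc = window_connectivity(ts, cfg.window_params)
        save_windowed_fc(wfc, out / ts.subject_id)
        sd = dfc_variability(wfc)
        var_rows.append(
            dict(subject_id=ts.subject_id,
                 mean_edge_variability=float(sd[np.triu_indices_from(sd, 1)].mean()))
        )
        np.savetxt(out / f"{ts.subject_id}.variability.tsv", sd, delimiter="\t")
    pd.DataFrame(var_rows).to_csv(out / "variability_summary.csv", index=False)


def _load_wfc(run_dir: Path, subjects: pd.DataFrame):
    return [load_windowed_fc(run_dir / "dfc" / sid) for sid in subjects["subject_id"]]


def _stage_states(run_dir: Path, cfg: RunConfig) -> None:
    _, subjects, _ = _load_cohort_series(run_dir, cfg)
    cohort = _load_wfc(run_dir, subjects)
    seed = stage_seed(cfg.seed, "states")
    X, _, _ = pool_windows(cohort)
    lo, hi = cfg.k_range
    K, curve, no_elbow = select_k(X, range(lo, hi + 1),
                                  replicates=cfg.kmeans_replicates, seed=seed)
    model = fit_states(cohort, K, distance=cfg.distance,
                       replicates=cfg.kmeans_replicates, seed=seed)
    out = run_dir / "states"
    out.mkdir(exist_ok=True)
    cohort_temporal_metrics(model).to_csv(out / "temporal_metrics.csv", index=False)
    np.savetxt(out / "centroids.tsv", model.centroids, delimiter="\t")
    pd.DataFrame(
        {sid: pd.Series(seq) for sid, seq in model.assignments.items()}
    ).to_csv(out / "assignments.csv", index=False)
    (out / "model.json").write_text(
        json.dumps(
            dict(K=K, inertia=model.inertia, distance=model.distance,
                 no_elbow=no_elbow,
                 inertia_curve={str(k): v for k, v in curve.items()}),
            indent=1,
        )
    )


def _stage_graph(run_dir: Path, cfg: RunConfig) -> None:
    _, subjects, _ = _load_cohort_series(run_dir, cfg)
    cohort = _load_wfc(run_dir, subjects)
    seed = stage_seed(cfg.seed, "graph")
    out = run_dir / "graph"
    out.mkdir(exist_ok=True)
    frames, summaries = [], []
    for i, wfc in enumerate(cohort):
        df, summary = graphmod.subject_dynamic_graph(
            wfc, ramp=cfg.ramp, use_abs=cfg.graph_use_abs,
            small_world_mean=cfg.graph_small_world,
            n_null=cfg.graph_n_null, seed=seed + i,
        )
        frames.append(df)
        summaries.append(summary)
    pd.concat(frames).to_csv(out / "window_auc.csv", index=False)
    pd.DataFrame(summaries).to_csv(out / "metric_variance.csv", index=False)


def _stage_hmm(run_dir: Path, cfg: RunConfig) -> None:
    _, subjects, series = _load_cohort_series(run_dir, cfg)
    model_info = json.loads((run_dir / "states" / "model.json").read_text())
    seed = stage_seed(cfg.seed, "hmm")
    fit = hmmmod.fit_hmm(series, K=model_info["K"], n_init=cfg.hmm_n_init,
                         seed=seed, max_iter=cfg.hmm_max_iter, tol=cfg.hmm_tol)
    out = run_dir / "hmm"
    out.mkdir(exist_ok=True)
    hmmmod.cohort_hmm_metrics(fit, tr_seconds=cfg.tr_seconds).to_csv(
        out / "hmm_metrics.csv", index=False
    )
    np.savez_compressed(out / "fit.npz", means=fit.means,
                        covariances=fit.covariances, transition=fit.transition)
    (out / "fit.json").write_text(
        json.dumps(dict(K=fit.K, log_likelihood=fit.log_likelihood,
                        transition=fit.transition.tolist()), indent=1)
    )
    pd.DataFrame({sid: pd.Series(p) for sid, p in fit.paths.items()}).to_csv(
        out / "paths.csv", index=False
    )


def _state_mean_matrices(run_dir: Path, subjects: pd.DataFrame, state: int):
    """Per-subject mean windowed z-matrix over windows assigned to a state."""
    assignments = pd.read_csv(run_dir / "states" / "assignments.csv")
    mats, keep = [], []
    for i, sid in enumerate(subjects["subject_id"]):
        wfc = load_windowed_fc(run_dir / "dfc" / sid)
        seq = assignments[sid].to_numpy()
        sel = seq == state
        if sel.sum() == 0:
            continue
        mats.append(wfc.z[sel].mean(axis=0))
        keep.append(i)
    return np.array(mats), subjects.iloc[keep]


def _stage_nbs(run_dir: Path, cfg: RunConfig) -> None:
    _, subjects, _ = _load_cohort_series(run_dir, cfg)
    model_info = json.loads((run_dir / "states" / "model.json").read_text())
    seed = stage_seed(cfg.seed, "nbs")
    out = run_dir / "nbs"
    out.mkdir(exist_ok=True)
    atlas = load_atlas(run_dir / "data" / "atlas.tsv")
    all_frames = []
    for state in range(1, model_info["K"] + 1):
        mats, sub = _state_mean_matrices(run_dir, subjects, state)
        if len(sub["group"].unique()) < 2 or len(sub) < len(cfg.stats_covariates) + 4:
            logger.warning("state %d: too few subjects for NBS, skipped", state)
            continue
        res = nbsmod.permutation_test(
            mats, sub["group"], covariates=sub[list(cfg.stats_covariates)],
            primary_p=cfg.nbs_primary_p, n_perm=cfg.nbs_n_perm,
            alpha=cfg.nbs_alpha, seed=seed + state,
        )
        df = res.to_frame(node_ids=list(atlas.node_ids))
        df["state"] = state
        all_frames.append(df)
        (out / f"state{state}.json").write_text(
            json.dumps(
                dict(
                    state=state,
                    n_perm=res.n_perm,
                    components=[
                        dict(size=c.size, direction=c.direction, p_fwe=c.p_fwe)
                        for c in res.components
                    ],
                ),
                indent=1,
            )
        )
    if all_frames:
        pd.concat(all_frames).to_csv(out / "edges.tsv", sep="\t", index=False)
    else:
        (out / "edges.tsv").write_text("")


def _stage_stats(run_dir: Path, cfg: RunConfig) -> None:
    subjects = pd.read_csv(run_dir / "data" / "subjects.csv")
    out = run_dir / "stats"
    out.mkdir(exist_ok=True)
    cov = list(cfg.stats_covariates)
    tables = []

    tm = pd.read_csv(run_dir / "states" / "temporal_metrics.csv")
    wide = tm.pivot_table(index="subject_id", columns="state",
                          values=["FR", "MDTD"])
    wide.columns = [f"{a}_state{b}" for a, b in wide.columns]
    wide["NT"] = tm.groupby("subject_id")["NT"].first()
    merged = wide.reset_index().merge(subjects, on="subject_id")
    measures = [c for c in wide.columns]
    tables.append(("temporal", statsmod.compare_measures(merged, measures,
                                                         covariate_cols=cov)))

    hm = pd.read_csv(run_dir / "hmm" / "hmm_metrics.csv")
    hwide = hm.pivot_table(index="subject_id", columns="state",
                           values=["FO", "MDTH"])
    hwide.columns = [f"{a}_state{b}" for a, b in hwide.columns]
    hwide["SR"] = hm.groupby("subject_id")["SR"].first()
    hmerged = hwide.reset_index().merge(subjects, on="subject_id")
    tables.append(("hmm", statsmod.compare_measures(
        hmerged, list(hwide.columns), covariate_cols=cov)))

    gv = pd.read_csv(run_dir / "graph" / "metric_variance.csv")
    gmerged = gv.merge(subjects, on="subject_id")
    gmeasures = [c for c in gv.columns if c.endswith("_variance")]
    tables.append(("graph", statsmod.compare_measures(
        gmerged, gmeasures, covariate_cols=cov)))

    for name, df in tables:
        df.to_csv(out / f"group_{name}.csv", index=False)

    scores = [s for s in ("AHI", "MoCA", "HAMD", "HAMA", "PSQI", "ESS",
                          "REM_pct", "SE_pct") if s in subjects.columns]
    corr_rows = []
    patients = merged[merged["group"] == "patient"]
    for m in measures:
        for s in scores:
            sub = patients.dropna(subset=[m, s])
            try:
                r = statsmod.partial_spearman(
                    sub[m], sub[s], covariates=sub[cov], measure=m, score=s
                )
            except ValueError as exc:
                logger.warning("correlation %s ~ %s skipped: %s", m, s, exc)
                continue
            corr_rows.append(dataclasses.asdict(r))
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    manifest = dict(
        seed=cfg.seed,
        config_hash=cfg.config_hash(),
        alpha=cfg.stats_alpha,
        fdr_families={name: list(df["measure"]) for name, df in tables},
    )
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def _stage_report(run_dir: Path, cfg: RunConfig) -> None:
    lines = ["# Pipeline run report", ""]
    model_path = run_dir / "states" / "model.json"
    if model_path.exists():
        info = json.loads(model_path.read_text())
        lines += [f"- Selected K = {info['K']} (no_elbow={info['no_elbow']})"]
    hmm_path = run_dir / "hmm" / "fit.json"
    if hmm_path.exists():
        info = json.loads(hmm_path.read_text())
        lines += [f"- HMM log-likelihood = {info['log_likelihood']:.1f}"]
    for name in ("temporal", "hmm", "graph"):
        p = run_dir / "stats" / f"group_{name}.csv"
        if p.exists():
            df = pd.read_csv(p)
            sig = df[df["p_fdr"] < cfg.stats_alpha]["measure"].tolist()
            lines += [f"- {name}: {len(df)} measures tested, FDR-significant: "
                      f"{sig or 'none'}"]
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "dfc": _stage_dfc,
    "states": _stage_states,
    "graph": _stage_graph,
    "hmm": _stage_hmm,
    "nbs": _stage_nbs,
    "stats": _stage_stats,
    "report": _stage_report,
}

_STAGE_MARKER = {
    "simulate": "data/subjects.csv",
    "dfc": "dfc/variability_summary.csv",
    "states": "states/model.json",
    "graph": "graph/metric_variance.csv",
    "hmm": "hmm/fit.json",
    "nbs": "nbs/edges.tsv",
    "stats": "stats/run_manifest.json",
    "report": "report.md",
}


def run_pipeline(
    config: RunConfig | dict | str | Path,
    run_dir,
    stages=None,
    force: bool = False,
) -> Path:
    """Run (or resume) the pipeline into ``run_dir``.

    Stages with existing marker outputs are skipped unless ``force``;
    a stage failure raises with the stage name, leaving earlier outputs
    in place.
    """
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = RunConfig.from_dict(config)
    else:
        cfg = config
        cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    )
    for stage in stages or STAGES:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        if not force and (run_dir / _STAGE_MARKER[stage]).exists():
            logger.info("stage %s: outputs present, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            _STAGE_FN[stage](run_dir, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _manifest(run_dir, stage, cfg)
    return run_dir
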