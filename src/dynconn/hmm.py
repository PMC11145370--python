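"""Gaussian hidden Markov model view of connectivity dynamics.

An HMM with full-covariance Gaussian observation model is fit to the
z-scored parcellated series of all subjects jointly (per-sequence
fitting: no transitions across subject boundaries), as an independent
validation of the sliding-window states. The state count is fixed in
advance — normally to the K selected by the window clustering — and a
likelihood scan over K is available for audit. Temporal summaries per
subject mirror the windowed metrics:

- FO (fractional occupancy): share of timepoints decoded to each state;
- MDTH (mean dwell time): mean run length of a state, in timepoints;
- SR (switching rate): state changes per unit sequence length,
  (number of switches) / (T - 1).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import linear_sum_assignment

from .io import RoiTimeSeries
from .states import StateModel, run_lengths
from .windows import upper_triangle

__all__ = [
    "HmmFit",
    "fit_hmm",
    "hmm_temporal_metrics",
    "cohort_hmm_metrics",
    "match_states",
    "scan_states",
]

logger = logging.getLogger(__name__)

#: Mean matching correlation below which an HMM/K-means state pairing is
#: reported with a warning (the two solutions likely describe different
#: structure).
MATCH_SCORE_WARN = 0.3


@dataclasses.dataclass
class HmmFit:
    """Best-of-restarts EM solution with per-subject decoded paths."""

    K: int
    means: np.ndarray  # K x N
    covariances: np.ndarray  # K x N x N
    transition: np.ndarray  # K x K row-stochastic
    paths: Mapping[str, np.ndarray]  # 0-based decoded state per timepoint
    log_likelihood: float
    ll_trace: np.ndarray  # EM log-likelihood history of the winning restart


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def fit_hmm(
    cohort: Sequence[RoiTimeSeries],
    K: int,
    n_init: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    decode: str = "posterior",
) -> HmmFit:
    """Fit a full-covariance Gaussian HMM to z-scored cohort series.

    Subjects are concatenated as separate sequences (the chain never
    crosses a subject boundary). The best of ``n_init`` EM restarts by
    final log-likelihood wins; a degenerate covariance triggers a
    ridge-regularized retry. Decoding is per-timepoint posterior argmax
    by default (``decode="viterbi"`` for the joint most-likely path).
    EM monotonicity of the winning restart is asserted.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if decode not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decode mode {decode!r}")
    X = np.vstack([_zscore(ts.data) for ts in cohort])
    lengths = [ts.n_timepoints for ts in cohort]
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_init):
        init_seed = int(rng.integers(0, 2**31 - 1))
        for min_covar in (1e-3, 1e-1):
            model = GaussianHMM(
                n_components=K,
                covariance_type="full",
                n_iter=max_iter,
                tol=tol,
                min_covar=min_covar,
                random_state=init_seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model.fit(X, lengths)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    logger.warning(
                        "EM restart %d degenerate (min_covar=%g): %s; retrying "
                        "with stronger ridge", attempt, min_covar, exc,
                    )
                    continue
            ll = model.monitor_.history[-1]
            if best is None or ll > best[1]:
                best = (model, ll)
            break
    if best is None:
        raise RuntimeError("all EM restarts failed")
    model, ll = best
    hist = np.asarray(model.monitor_.history, dtype=float)
    if np.any(np.diff(hist) < -1e-6):
        raise RuntimeError("EM log-likelihood decreased — numerical failure")
    paths = {}
    start = 0
    for ts in cohort:
        seg = X[start : start + ts.n_timepoints]
        if decode == "posterior":
            post = model.predict_proba(seg)
            paths[ts.subject_id] = post.argmax(axis=1)
        else:
            paths[ts.subject_id] = model.predict(seg)
        start += ts.n_timepoints
    return HmmFit(
        K=K,
        means=model.means_.copy(),
        covariances=model.covars_.copy(),
        transition=model.transmat_.copy(),
        paths=paths,
        log_likelihood=float(ll),
        ll_trace=hist,
    )


def scan_states(
    cohort: Sequence[RoiTimeSeries],
    k_values: Sequence[int],
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Audit scan: final log-likelihood (and BIC) across candidate K."""
    n_obs = sum(ts.n_timepoints for ts in cohort)
    rows = []
    for k in k_values:
        fit = fit_hmm(cohort, k, seed=seed, **kwargs)
        n = fit.means.shape[1]
        n_params = k * n + k * n * (n + 1) / 2 + k * (k - 1) + (k - 1)
        rows.append(
            dict(
                K=k,
                log_likelihood=fit.log_likelihood,
                bic=-2 * fit.log_likelihood + n_params * np.log(n_obs),
            )
        )
    return pd.DataFrame(rows)


def hmm_temporal_metrics(path: np.ndarray, K: int | None = None,
                         tr_seconds: float | None = None) -> dict:
    """FO, MDTH and SR of one decoded (0-based) state path."""
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("empty state path")
    if path.size == 1:
        raise ValueError("switching rate undefined for a single timepoint")
    K = K if K is not None else int(path.max()) + 1
    T = len(path)
    FO = np.array([(path == k).sum() / T for k in range(K)])
    MDTH = np.zeros(K)
    for k in range(K):
        lens = [ln for s, ln in run_lengths(path) if s == k]
        if lens:
            MDTH[k] = float(np.mean(lens))
    SR = float((path[1:] != path[:-1]).sum() / (T - 1))
    out = dict(FO=FO, MDTH=MDTH, SR=SR)
    if tr_seconds is not None:
        out["MDTH_seconds"] = MDTH * tr_seconds
    return out


def cohort_hmm_metrics(fit: HmmFit, tr_seconds: float = 2.0) -> pd.DataFrame:
    """Tidy per-subject table of FO, MDTH (timepoints and s) and SR."""
    rows = []
    for sid, path in fit.paths.items():
        m = hmm_temporal_metrics(path, K=fit.K, tr_seconds=tr_seconds)
        for k in range(fit.K):
            rows.append(
                dict(
                    subject_id=sid,
                    state=k + 1,
                    FO=m["FO"][k],
                    MDTH=m["MDTH"][k],
                    MDTH_seconds=m["MDTH_seconds"][k],
                    SR=m["SR"],
                )
            )
    return pd.DataFrame(rows)


def _cov_to_fisher_edges(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    r = np.clip(r, -0.999999, 0.999999)
    return upper_triangle(np.arctanh(r))


def match_states(fit: HmmFit, model: StateModel) -> tuple[np.ndarray, np.ndarray]:
    """Match HMM states to window-clustering states by connectivity pattern.

    Each HMM state covariance is converted to a Fisher-z edge vector and
    correlated with each K-means centroid; the optimal bipartite
    assignment (maximizing total correlation) is returned as ``perm``
    with ``perm[h]`` the 0-based K-means state matched to HMM state h,
    plus the full score matrix. A mean matched score below
    ``MATCH_SCORE_WARN`` triggers a warning.
    """
    if fit.K != model.K:
        raise ValueError(f"state-count mismatch: HMM K={fit.K}, clustering K={model.K}")
    H = np.array([_cov_to_fisher_edges(c) for c in fit.covariances])
    C = np.asarray(model.centroids)
    scores = np.empty((fit.K, model.K))
    for i in range(fit.K):
        for j in range(model.K):
            scores[i, j] = np.corrcoef(H[i], C[j])[0, 1]
    rows, cols = linear_sum_assignment(-scores)
    perm = np.empty(fit.K, dtype=int)
    perm[rows] = cols
    matched = scores[rows, cols]
    if matched.mean() < MATCH_SCORE_WARN:
        warnings.warn(
            f"HMM/K-means state matching is weak (mean score "
            f"{matched.mean():.2f} < {MATCH_SCORE_WARN}); the two solutions "
            "may describe different structure",
            stacklevel=2,
        )
    return perm, scores
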