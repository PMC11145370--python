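# dynconn

Dynamic functional connectivity (dFC) analysis for parcellated
resting-state BOLD time series, built around the cerebellar-connectome
workflow used in sleep-apnea neuroimaging: recurring connectivity
states from sliding windows, dynamic graph topology of a 27-node
cerebellar network, hidden-Markov validation of state dynamics,
network-based statistics, and covariate-adjusted group and correlation
statistics. A synthetic cohort generator with known ground truth stands
in for patient scans, so every estimator in the pipeline can be
validated end to end without any imaging data.

**Who it is for.** Researchers analysing ROI-level fMRI time series who
want a tested, scriptable implementation of the sliding-window state
pipeline (instead of GUI toolboxes), and methodologists who want a
ground-truth test bed for dFC estimators.

## The method in brief

For each subject with series `X ∈ R^{T×N}` (TR = 2 s, default T = 230,
N = 27 ROIs), windowed connectivity is computed in sliding windows of
width `w = 50` TR and step `s = 2` TR, giving
`N_w = ⌊(T − w)/s⌋ + 1 = 91` windows; each window yields a Fisher-z
matrix `z = atanh(r)` of Pearson correlations. Key quantities:

- **States.** Upper-triangle window vectors of all subjects are pooled
  and clustered by K-means; K is chosen by the elbow rule (maximum
  second difference of the inertia curve I(k)). Per subject the state
  sequence yields FR (fraction of windows per state), MDTD (mean dwell
  time, windows) and NT (number of transitions).
- **Dynamic topology.** Each windowed matrix is proportionally
  thresholded over sparsities 0.05–0.40 (step 0.01), binarized, and
  summarized by global efficiency `Eg = ⟨1/d_ij⟩`, characteristic path
  length `Cp` (connected pairs), clustering `Ccoef`, local efficiency
  `Eloc`, and small-world indices γ, λ, σ = γ/λ against
  degree-preserving rewired nulls; metrics are integrated over the ramp
  (trapezoidal AUC) and their across-window variance is the
  temporal-variability readout.
- **HMM validation.** A full-covariance Gaussian HMM fit to z-scored
  series gives decoded state paths and FO / MDTH / SR, matched to the
  K-means states by connectivity-pattern correlation.
- **NBS.** Edge-wise group contrasts (linear model with age, education,
  BMI, head-motion covariates; primary threshold p = 0.0001) define
  suprathreshold components whose size is tested against a
  Freedman-Lane permutation null (5000 iterations, component
  α = 0.005).
- **Statistics.** Normality screening by skewness/kurtosis in [−2, 2],
  covariate-adjusted t or Mann-Whitney fallback, Benjamini-Hochberg
  FDR, and covariate-partialled Spearman correlations with clinical
  scores.

## Worked example

```python
import dynconn

gt = dynconn.default_ground_truth(seed=11)          # 2 states, 27 nodes
series, subjects, paths = dynconn.simulate_cohort(gt, n_per_group=20, T=230, seed=11)

wfc = [dynconn.window_connectivity(ts, dynconn.WindowParams()) for ts in series]
print(wfc[0].z.shape)

from dynconn.states import pool_windows, select_k, fit_states, temporal_metrics
X, ids, counts = pool_windows(wfc)
K, curve, flat = select_k(X, range(2, 7), replicates=10, seed=0)
print(K)

model = fit_states(wfc, K, replicates=10, seed=0)
tm = temporal_metrics(model.assignments[ids[0]], K)
print(tm.FR.round(3), tm.MDTD.round(2), tm.NT)
```

prints

```
(91, 27, 27)
2
[0.78 0.22] [35.5 20. ] 2
```

i.e. 91 windows of 27×27 Fisher-z connectivity per subject, the elbow
criterion recovers the two generating states, and the first subject (a
patient) spends 78% of windows in the hypoconnected state with mean
dwell times of 35.5 / 20 windows and 2 state transitions. The full pipeline —
simulate → dfc → states → graph → hmm → nbs → stats → report — runs
from one config:

```bash
dynconn run --out runs/demo            # or: python -m dynconn.cli ...
```

## Acceptance script

`scripts/acceptance.py` regenerates the state-count selection
experiment from scratch: twenty independent two-state synthetic
cohorts (20 + 20 subjects, T = 230) are simulated, windowed
connectivity is clustered, and the modal K selected by the elbow
criterion across cohorts is written as JSON.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/dynconn/synthetic.py` — state-switching covariance generator + clinical copula
- `src/dynconn/io.py` — series/atlas/subjects I/O, motion screening, NIfTI sphere extraction
- `src/dynconn/windows.py` — sliding-window Fisher-z stacks, dFC variability
- `src/dynconn/states.py` — K selection, K-means states, FR/MDTD/NT
- `src/dynconn/graph.py` — sparsity thresholding, graph metrics, AUC, small-world nulls
- `src/dynconn/hmm.py` — Gaussian HMM fit, FO/MDTH/SR, state matching
- `src/dynconn/nbs.py` — edge GLM, component extraction, permutation FWE
- `src/dynconn/stats.py` — group tests, FDR, partial Spearman
- `src/dynconn/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
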