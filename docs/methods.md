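# Methods notes

This note records the models, conventions and numerical choices behind
`dynconn`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Synthetic cohort model

Each subject's parcellated series follows a hidden-Markov switching
covariance model: a latent chain `z_t ∈ {1..K}` with group-specific
row-stochastic transition matrix `P_g`, and observations

    x_t = μ + L_{z_t} e_t + σ η_t,   e_t, η_t ~ N(0, I) iid,

with `L_k` the Cholesky factor of state k's correlation-scale
covariance and `σ` (default 0.25) isotropic observation noise. The
chain starts from its stationary distribution so occupancy is unbiased
at any T. Expected dwell time of state k is `1/(1 − P[k,k])`, the
quantity used throughout for calibration checks.

**Default world.** Two states over 27 cerebellar nodes grouped into 8
functional networks (DMN, FPN, CON, DAN, SN, SMN-dorsal, SMN-lateral,
VN). Both states share a network-block base correlation matrix
(within-network r = 0.35, between-network r = 0.10); a global strength
multiplier (0.55 vs 1.6) makes state 1 hypoconnected and state 2
hyperconnected, mirroring the baseline/integrated dichotomy reported in
patient cohorts without inventing per-edge values. Transition defaults:
controls `diag(0.95, 0.85)` (dwell 20 / ~6.7 TR), patients
`diag(0.90, 0.90)` (dwell 10 / 10 TR) — patients spend more time in,
and dwell longer in, the hyperconnected state, matching the published
direction of group differences. Published effect sizes for these
dynamics do not exist, so the magnitudes are exposed as parameters and
the defaults are moderate. Atlas coordinates are plausible synthetic
cerebellar MNI positions; they carry no anatomical claim.

**Clinical coupling.** Score–dynamics coupling uses a Gaussian copula
against each subject's true hyper-state occupancy: occupancy ranks →
normal scores `u`; latent `v = r·u + √(1−r²)·ε` with
`r = 2 sin(πρ/6)` so the latent Pearson r yields Spearman ρ; `v` is
pushed through a marginal quantile transform. Coupled scores use the
pooled two-group mixture marginal — a single monotone map, so the
pooled sample Spearman equals the target up to sampling noise, and
group differences in coupled scores arise through the groups' occupancy
difference (in the published directions, since the signs align).
Uncoupled scores use group-specific truncated-normal marginals with
published group means/SDs, which reproduces the large demographic
contrasts (e.g. apnea severity) independently of the dynamics. Integer
scales are rounded, which slightly attenuates realized correlations via
ties.

**What a green test does not establish.** The generator emulates
state-switching second-order structure only: no hemodynamic response,
scanner drift, motion artefacts, spatial autocorrelation, or voxel
data. Estimator performance on this world bounds nothing about
real-data effect sizes; it verifies correctness and calibration of the
machinery.

## Windowed connectivity

Rectangular window of 50 TR, step 2 TR (91 windows at T = 230). The
window is rectangular by default because the reference sliding-window
implementation states no taper; a Gaussian taper (weighted-correlation
formula) is available for sensitivity analyses alongside the 30-TR
window variants. Fisher z is capped at `atanh(0.999999)` to keep
numerically perfect correlations finite. Correlations of
constant-in-window columns are undefined and set to 0 with a warning.
Edge-level dFC variability is the across-window sample (n−1) standard
deviation of z. Seed-based variability maps are computed
seed-to-parcel (27 cerebellar seeds × cerebral parcels) rather than
voxelwise; voxel-level cluster correction is out of scope and the
parcel statistic preserves the quantity of interest.

Note that windowed state detectability depends on the dwell/width
ratio: when mean dwell (10 TR default) is far below the window width
(50 TR), windows average over states and the switching contribution to
edge variability is largely suppressed. Tests that probe state-driven
effects therefore use sticky-chain variants (dwell ≈ 100 TR).

## State clustering

Windows of *all* subjects (both groups) are pooled and clustered
jointly, so centroids are common to the cohort; metrics are then per
subject. Default distance is squared Euclidean with mean centroids
(standard K-means, best of ≥10 restarts); city-block distance with
median centroids is available, following the windowed-connectivity
literature. States are relabeled by ascending mean |centroid| so state
1 is always the hypoconnected pattern.

"Elbow method" is made falsifiable as: K = argmax over interior k of
the second difference `I(k−1) − 2I(k) + I(k+1)` of the inertia curve
(ties broken toward smaller k), with the curve computed one k beyond
each end of the candidate range. If no candidate improves inertia by
more than 1e-3 relative gain the curve is flat: the smallest such k is
returned with a `no_elbow` flag. In practice finite-sample K-means on
unclustered Gaussian data still yields relative gains above 1e-3, so
the flag fires only for genuinely degenerate data; on such data the
curvature rule returns its generic answer K = 2.

MDTD of a never-visited state is reported as 0 with `visited=False`
and should be excluded from group tests (group means over dwell times
need a convention for absent states; exclusion avoids biasing means
toward zero). MDTD is in windows; seconds = windows × step × TR.

## Dynamic graph topology

Proportional thresholding keeps the `round(s·E)` largest-|z| edges
(E = N(N−1)/2), binary and undirected, with round half-away-from-zero
and a fixed total tie order (value desc, i asc, j asc) for
bit-reproducibility. Negative edges compete by absolute value by
default (configurable positive-only mode): the choice is not
documented in GRETNA-style analyses, so it is explicit and switchable.

Metric definitions: Eg counts unreachable pairs as zero contribution
(robust to disconnection); Cp is averaged over connected pairs only,
since the sparsest thresholds can disconnect a 27-node graph, and
would otherwise be infinite; Ccoef averages local clustering with
degree-<2 nodes contributing 0; Eloc averages the neighbourhood
subgraph efficiency. Shortest paths use a numba-compiled BFS kernel
(exactness is enforced against brute-force Floyd-Warshall enumeration
in the tests). Small-world γ, λ use means over ≥20 degree-preserving
rewired nulls (double edge swaps, 5·E swaps); σ = γ/λ.

AUC over the sparsity ramp (0.05–0.40, step 0.01; 36 points) is the
trapezoidal integral in sparsity units. Temporal variability is the
across-window sample *variance* of each AUC series (SD available);
variance is the published scale for these quantities (reported ×10⁻⁴).
Per-window small-world AUC with full null ensembles costs
36 thresholds × 20 nulls × 91 windows per subject and is prohibitive
on one CPU; the pipeline default computes γ/λ/σ on each subject's
time-averaged network over the full ramp, with the per-window version
behind `small_world_windows=True`.

## HMM validation

Full-covariance Gaussian observation model on per-subject z-scored
series, fit by EM over all subjects as separate sequences (no
transition across subject boundaries), best of `n_init` restarts by
final log-likelihood; a degenerate covariance triggers a
ridge-regularized retry. EM monotonicity is asserted on every fit. The
state count is fixed to the K from window clustering (a likelihood/BIC
scan is provided for audit, not selection). Decoding is per-timepoint
posterior argmax — FO/MDTH are occupancy quantities, so marginal
decoding is the matching estimator; Viterbi joint decoding is an
option. The HMM input is the raw parcellated series (standard for
Gaussian-mode HMM connectivity analyses), not windowed matrices. HMM
states are matched to K-means states by maximal bipartite correlation
between state-covariance Fisher-z edge patterns and centroids; a mean
matched correlation below 0.3 warns that the solutions disagree.

## Network-based statistic

Edge-wise t of the group coefficient in an OLS model with intercept
and covariates (equal to the pooled two-sample t when covariates are
absent). Components are maximal node-connected sets of suprathreshold
edges, sized in edges (extent statistic; intensity is a possible
extension, extent matches how subnetworks are reported). The
permutation scheme is Freedman-Lane: residuals from the covariate-only
model are row-shuffled, refitted values added back, and the full model
re-estimated; with no covariates this reduces exactly to label
shuffling. Both contrast directions are tested separately, each
against its own max-component-size null. FWE p uses the add-one
convention `(1 + #{null ≥ obs})/(1 + n_perm)`. When the group labels
admit fewer distinct rearrangements than `n_perm`, all are enumerated
(exact test). Defaults: primary p = 0.0001, 5000 permutations,
component α = 0.005.

The pipeline applies NBS as the group contrast within each state
(subjects' state-mean z-matrices), the reading consistent with
red/blue per-state group differences; the module itself takes explicit
data and design, so other contrasts are one call away.

## Group statistics

Normality screening declares a measure normal iff sample skewness and
excess kurtosis both lie in [−2, 2]. Normal measures: t on the group
coefficient of an OLS model with covariates (age, education, BMI, head
motion by default); non-normal: Mann-Whitney on covariate-residualized
values (no covariate-aware rank test is standard, so residualize-then-
rank is used). Both the adjusted and the plain covariate-free p are
reported, since published tables are ambiguous about which was used.
FDR is Benjamini-Hochberg per measure family (temporal, HMM, graph —
one `compare_measures` call each; the scope is recorded in the run
manifest). Partial Spearman ranks x, y *and* covariates, residualizes
the x/y ranks on the covariate ranks, and correlates the residuals,
with a t-approximation p on n − 2 − n_cov df; this composition is
invariant to monotone transforms of every variable.

## Orchestration and reproducibility

One global seed fans out per stage as `crc32(stage_name) XOR seed`
(mod 2³¹−1), so stages are independently reproducible. Every stage
writes a provenance manifest (stage, derived seed, config hash,
version); re-running skips stages whose outputs exist, and regenerated
outputs are byte-identical (full-precision text serialization,
round-trip float parsing).

## Known limitations

- No voxel-level analysis, GRF cluster correction, meta-state/temporal
  ICA, MAR observation models, variational model selection, weighted
  graph variants, modularity/rich-club metrics, paired NBS designs, or
  mixed-effects models.
- The elbow rule, like all inertia heuristics, is only reliable when
  states are well separated relative to window sampling noise.
- Small-world indices on very sparse thresholds can fail when the
  degree sequence admits no rewiring; such windows are reported as
  missing rather than silently dropped.
- Motion screening operates on summary statistics; computing framewise
  displacement from realignment parameters is upstream preprocessing
  and out of scope.
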