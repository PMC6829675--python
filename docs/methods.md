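# Methods

This note documents what `connfuse` computes, the assumptions behind each
stage, the parameters that matter, and the numerical and design choices
made where the procedure left room. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Two groups of subjects (patients, coded +1, and healthy controls, coded
−1) are compared on two whole-brain networks built over the 90 cerebral
regions of the AAL parcellation. The *structural covariance network* is a
group-level object: one Pearson correlation per region pair, computed
across the subjects of a group from their regional gray-matter volumes.
The *functional connectivity network* is subject-level: the Fisher-z
transformed Pearson correlation between two regions' resting-state time
courses. Both modalities share one edge index — the lower triangle of the
90 × 90 matrix in row-major order, pairs (2,1), (3,1), (3,2), …, (90,89) —
giving 4,005 features per modality.

## Time-series quality control (`ts_qc`)

Fixed order: **discard → nuisance regression → scrubbing → band-pass**.

- *Discard*: the first 10 of 250 volumes are dropped (signal
  equilibration), leaving 240.
- *Nuisance regression*: each ROI series is replaced by its OLS residual
  against an intercept, the 6 rigid-body motion parameters, their backward
  first differences (first row zero), and the WM/CSF signals. Collinear
  columns are dropped with a warning; residuals are orthogonal to every
  retained regressor.
- *Framewise displacement*: Power convention, the sum of absolute backward
  differences of the six parameters with rotations converted to arc length
  on a 50 mm sphere (radius configurable; the convention's standard value).
- *Scrubbing*: a volume is censored when the FD of the transition leading
  into it exceeds 0.5 mm (only the later frame of a high-FD pair is
  flagged) or its global mean intensity — the mean over the 90 ROI
  signals, z-scored over time, since no voxel data exist at this stage —
  deviates by more than 2 SD. Censored volumes are deleted, never
  interpolated, and the mask is applied once (FD is not recomputed after
  deletion). A subject is excluded when strictly more than 20% of retained
  volumes are censored (48 of 240: 48 flagged is kept, 49 excluded).
- *Band-pass*: second-order zero-phase Butterworth, 0.01–0.08 Hz at
  TR = 2 s, applied to the censored series treated as contiguous. The
  order/family is a standard resting-state choice; only the band itself is
  prescribed by the procedure.

## Network construction (`connectome`)

Functional correlations are clipped to ±(1 − 1e−7) before `atanh` so
perfectly collinear signals stay finite; zero-variance regions yield zero
edges with a warning. Covariate correction (age, sex, education, plus an
intercept) is OLS residualization applied per region (volumes) or per edge
(functional features); by default it is fitted on all subjects before
cross-validation, matching the original analysis — a leakage-safe variant
that refits within training folds is available by calling the correction
inside a fold loop.

The structural permutation test reassigns the covariate-corrected volume
rows to two groups of the original sizes; the statistic is
`r_A − r_B` per edge and the two-tailed p-value uses the add-one
Monte-Carlo estimator `p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (B + 1)`, which
never returns zero. Default `B` = 10,000; tests and the acceptance script
use 1,000.

## Feature filtering (`fusion_select.filter_features`)

`ΔM_S = |M_S^patients − M_S^controls|` is ranked descending; functional
edges are ranked ascending by pooled-variance two-sample-t p-value. The
cutoff `c` is the number of `ΔM_S` entries at or above the vector's mean
(when every entry equals the mean, `c = 4005` and filtering degenerates to
the full set). The selected set `L` is the intersection of the two top-`c`
lists, ordered by edge position; ties in either ranking break by edge
position ascending, for determinism. An empty intersection raises an
error. All filtering statistics are computed on training subjects only.

## Subject-level structural features

The structural network is a group statistic, so no subject-level
structural vector exists a priori. We use jackknife pseudo-values:
`m_i = n_g · r_g − (n_g − 1) · r_g^(−i)`, where `r_g^(−i)` is the
leave-one-out group correlation, computed within the subject's own group
(minimum group size 5). Pseudo-values are parameter-free, reduce to `r_g`
when subjects are exchangeable, and isolate influential subjects
otherwise. Columns of `M` are affinely rescaled to the matching functional
column's mean and SD before distances are taken, so the inter-modality
distance compares shapes, not units.

## Fusion objective

`min_W ||XW − y||² + λ1·Ω_k(W) + λ2·Σ_j d_j W_j²`, with
`d_j = Σ_i (x_ij − m_ij)²`.

- The k-support norm `Ω_k` is the standard definition
  `Ω_k(w)² = Σ_{i=1}^{k−r−1} (|w|↓_i)² + (Σ_{i=k−r}^{d} |w|↓_i)²/(r+1)`,
  with the unique split index `r` satisfying
  `|w|↓_{k−r−1} > (1/(r+1)) Σ_{i=k−r}^d |w|↓_i ≥ |w|↓_{k−r}` (sentinel
  `|w|↓_0 = +∞`). When exact ties make several `r` norm-equivalent the
  smallest is returned. The penalty enters at the first power; a
  squared-norm variant is available (`penalty="ksupport_squared"`).
- The literal subject-level distance `Σ_i ||x_i − m_i||²` does not involve
  `W` and is vacuous as a penalty; the feature-weighted ridge above
  realizes its evident intent — edges on which the modalities disagree are
  shrunk harder. The literal reading is kept as an audit mode
  (`intermodality="constant"`), which adds the constant to the reported
  objective and nothing to the gradient.
- `k` is exposed as a hyperparameter; the default is 10% of `|L|`. For
  recovery experiments where the generative support is known (the
  acceptance runs plant 4 edges), `k` is set to that support size — the
  natural choice for a recovery study, and markedly better than 0.1·|L|
  when `|L|` runs to hundreds of features, because the downstream RBF
  classifier degrades when dozens of noise features accompany a handful of
  informative ones.

### Proximal operator

`prox_{θΩ_k}(v) = v − P(v)` by Moreau decomposition, where `P` projects
onto the dual-norm ball `{u : Σ of the k largest u_i² ≤ θ²}`. The
projection's KKT system partitions the sorted magnitudes into a scaled
block `v_i/(1+2μ)`, a tie block clamped at a common level `t`, and an
untouched tail. The solver enumerates all candidate partitions `(l, m)`
vectorized, brackets `t` inside `(p_m, p_{m−1}]` ∩ `(0, A/q]` (the upper
bound enforces `μ ≥ 0`), prunes candidates by two bracket evaluations,
bisects 38 steps on the survivors, validates the KKT ordering conditions
with a relative tolerance of 1e−9, and picks the valid candidate nearest
to `v`. Successive calls inside an optimization loop re-validate the
previous partition first (a scalar operation) before falling back to the
full sweep. Closed-form anchors: k = 1 reduces to soft thresholding, k = d
to Euclidean shrinkage; the test suite also checks the operator against an
independent trust-region solver of the smooth QCQP reformulation of the
projection (auxiliary CVaR variables for the top-k constraint).

### Optimizer

Monotone accelerated proximal gradient (FISTA with a monotonicity guard):
a step that would increase the objective is rejected and the momentum
restarts from the current iterate; the objective trace is therefore
non-increasing by construction. Step size 1/L with
`L = 2(σ_max(X)² + λ2 max_j d_j)`; `σ_max(X)` is computed once per design
and cached. Convergence when the relative objective change falls below
`tol` (default 1e−8, 10,000 iterations max; the cross-validation loop uses
1e−6 and 2,000 by default, which the fixed-point test shows is ample at
these problem sizes).

## Nested cross-validation and consensus (`cv_consensus`)

Stratified 10-fold CV repeated over rounds (default 100; scaled-down runs
use 10), per-round fold shuffles seeded `seed + round`. Everything
data-driven — structural networks, filtering, jackknife features, design,
fusion fit — is recomputed inside each training fold, and again inside
each inner fold during model selection; an instrumentation test verifies
that corrupting held-out rows never changes training-fold artifacts.
`(λ1, λ2)` are chosen per training fold by inner stratified CV accuracy
over the mesh grid `G = 1:20:100 = {1, 21, 41, 61, 81}` for both axes
(ties prefer smaller λ1, then smaller λ2); inner folds default to 5.
Features with non-zero fusion coefficients feed an RBF SVM (C = 10,
`gamma="scale"`), z-scored by training-fold statistics — an RBF kernel is
scale-sensitive and the procedure is otherwise silent on scaling. A fold
whose fit is all-zero predicts the training-majority class with zero
decision scores and contributes nothing to the consensus accumulator
(alternatives — disqualifying such λ pairs during selection, or backing
off λ1 — were evaluated and degraded both accuracy and consensus purity by
forcing dense fits).

Per-round metrics pool each round's held-out predictions; the reported
aggregate is the mean of per-round values, not a pooled total. Sensitivity
takes patients as the positive class. AUC is the rank statistic of the
decision scores with ties averaged.

Consensus: `|W|` summed over every fold of every round; the top 1% of
edges (exactly 40 of 4,005, boundary ties by edge position) are the
consensus connections, and the top 10% of regions (exactly 9 of 90, ties
by region index) ranked by summed incident consensus weight are the
consensus nodes. If fewer edges than the quota have non-zero scores the
set is padded by the same ranking rule, with a warning.

## Univariate arm (`group_stats`)

Student (pooled-variance) two-sample t-tests — the unqualified reading of
"two-sample t-test"; Welch is available by flag — with Benjamini–Hochberg
step-up adjustment across the 4,005-edge family (each modality corrected
separately). The four-edge summation score is the plain sum of the
corrected Fisher-z values. One-way ANOVA is available from raw scores and
from printed (mean, SD, n) summaries — the two agree to numerical
precision by construction — with Tukey–Kramer pairwise p-values from the
studentized-range distribution using unequal-n Kramer standard errors.
Partial correlation correlates OLS residuals on the covariates, two-tailed
p from the t transform with `df = n − n_cov − 2`.

## Synthetic cohort generator (`cohort_sim`)

The generator emulates the *statistical structure the analysis assumes*,
not raw images. Defaults reproduce the study conditions: 83 patients
(episodes: 35 depressive, 19 manic, 29 remission) vs 94 controls, 90
regions, 250 volumes at TR 2 s; the four planted ACC–medial-prefrontal
edges at group Fisher-z means (−0.10, −0.09, −0.09, −0.10) vs (+0.09,
+0.08, +0.07, +0.08) with SDs 0.235–0.275 (the 0.07 entry corrects an
apparent misprint, which also makes the control-group four-edge sum equal
the reported 0.32); patient demographics older and less educated than
controls (25.63 ± 5.59 vs 23.3 ± 4.6 years; 13 ± 2.9 vs 14 ± 2.1 years);
mean FD 0.15 vs 0.13 mm. Episode shifts of the planted-edge sum
(depressive −0.17, manic +0.426, remission −0.08 relative to the patient
mean) reproduce the reported episode-level score means and are divided
equally across the four edges — a modelling convenience, since no
edge-level episode decomposition is reported.

**Time series.** Only second-order structure matters downstream, so each
subject's series is T i.i.d. Gaussian frames from a correlation matrix
assembled from a common background level (default 0.1) plus per-subject
planted-edge correlations `tanh(z)`, `z` drawn per subject around the
group mean. Three calibration details:

- the between-subject latent SD is deflated by the finite-T sampling
  variance, `latent_sd = sqrt(sd_z² − 1/(T−3))`, so the *measured* z has
  the configured SD;
- WM/CSF-like AR(1) nuisance signals leak into every region with random
  weights (SD 0.1 by default), which dilutes measured correlations; the
  latent correlation is built from each subject's realized leak weights
  (scaled by the analytic expected AR(1) sample variance over T frames) so
  the emitted series realizes the target exactly at the population level;
- the assembled matrix is projected to the nearest positive-definite
  correlation matrix by eigenvalue clipping; a warning fires if the
  projection moves any planted entry by more than 0.05 — planted patterns
  must be jointly feasible (in particular, a clique of strong
  cross-correlations requires its within-pairs elevated too, which is why
  the default structural module plants all pairs among the four
  anterior-midline regions).

Residual calibration error of the planted group difference, measured at
n = 500/500 in the test suite, is below 0.01 on the Fisher-z scale.

**Volumes.** Per group, i.i.d. draws from a correlation structure with a
background level (0.1) and the planted structural module; by default the
module shows *no* group difference, matching the null structural findings.
`couple_structural=True` plants a matched group difference (cross pairs
0.15 vs 0.65, sibling pairs 0.55 in both groups) for fusion recovery
experiments. Covariate slopes shift volumes (all regions) and planted-edge
z (additively) per unit of age/sex/education, creating genuine
confounding since the group demographics differ.

**Motion.** Gaussian random-walk drift scaled so mean FD matches the group
target, plus optional persistent step jumps (probability and magnitude
configurable) so that exactly the post-spike frame crosses the FD
threshold; an optional global-intensity offset at spike frames exercises
the intensity criterion.

**Clinical scores.** HAMD/YMRS are drawn uniformly inside the ranges that
define each episode (depressive: HAMD ≥ 17, YMRS < 12; manic: YMRS ≥ 12,
HAMD < 17; remission: both below), HAMA and illness duration from the
reported moments; scores carry no true association with connectivity by
default (matching the reported null correlations), with
`clinical_association` available for power experiments.

**What the generator does not emulate**: spatial structure within regions,
scanner/site effects, autocorrelated hemodynamics (frames are white in
time; the band-pass therefore removes noise power but no signal),
non-Gaussian volume distributions, or realistic spatial covariance beyond
the planted module. Passing tests therefore demonstrate that the
*pipeline* behaves correctly under the assumed statistical structure, not
that the original biological findings replicate.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at reduced scale chosen to keep the suite
fast while leaving the tested property identifiable: recovery experiments
use 40/40-subject cohorts with the planted effect doubled (Δz = 0.4),
10-round 10-fold nested CV with 3 inner folds and the λ grid restricted to
{1, 21, 41} per axis (a pilot range scan showed λ1 ≥ 61 always empties the
model at this problem scale); calibration checks pool thousands of null
edges across many small cohorts; the permutation test runs B = 1,000. The
full-scale defaults (100 rounds, 5-fold inner selection over the full
grid, B = 10,000) remain the package defaults.

## Known limitations

- The filtering rule's reliability is bounded by the structural-network
  estimate: at 40 subjects per group the inter-subject correlation has an
  SE near 0.16, so a planted structural difference of 0.5 occasionally
  fails to rank inside the top-`c` list on an unlucky draw, which removes
  the edge from `L` for that fold. This is a property of the procedure,
  not of the implementation.
- Covariate correction fitted on the full sample (the default, for
  fidelity) leaks a small amount of information across folds; when groups
  are demographically confounded it also absorbs genuine group signal and
  injects covariate noise into within-group feature variance.
- The inter-modality ridge uses a fixed, data-derived `d_j`; it is not
  re-estimated inside the optimization.
- `anova_from_summary` on printed (rounded) summaries inherits the
  rounding of its inputs; reconstructed F statistics can differ from
  printed ones by a few percent.
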