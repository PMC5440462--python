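# Methods

This note documents the models, defaults and numerical choices behind
`fncpipe`, and what the synthetic validation does and does not establish.

## Generative model of the synthetic cohort

Each subject's 4D signal is

    y(v, t) = Σ_k a_k s_k m_k(v) c_k(t) + n_wm(v, t) + n_csf(v, t)
              + b (t − T/2) + ε(v, t),   ε ~ N(0, σ²)

- **Spatial maps** `m_k`: mixtures of isotropic Gaussian blobs,
  peak-normalized to 1. The default layout places the twelve networks'
  blobs (two each) on a 3×3×3 interior lattice so that all 66 pairwise
  spatial correlations stay ≤ 0.3 — spatial ICA's independence assumption
  holds by construction. Default blob FWHM is 10 mm, capped on small
  grids so suprathreshold extent (map > 0.1) clears the nuisance slabs.
- **Time courses** `c_k`: latent Gaussian factors drawn with the
  lag-aligned correlation matrix implied by the coupling table (checked
  positive semi-definite; infeasible tables are rejected with the
  offending eigenvalue). Lags are realized by integer-sample shifts of
  the shared factors — the per-network shifts are solved on the coupling
  graph, so inconsistent lag cycles are rejected — with the wrapped
  margin discarded and rows re-standardized. Planted lags must therefore
  be multiples of TR. For every coupling, corr(c_i(t), c_j(t + lag)) = ρ
  exactly in population; the empirical mean over 200 draws at T = 250 is
  within 0.02 of ρ (tested).
- **Group effects** act (i) on the Fisher-z scale of selected couplings
  (additive shifts, then back-transformed), so planted deltas are
  commensurate with the z-scale mean differences that group FNC
  statistics report, and (ii) as per-network amplitude multipliers.
- **Nuisance**: WM and CSF are fixed corner slabs (low-x/low-y and
  high-x/high-y columns), disjoint from all suprathreshold network
  voxels (asserted at assembly). Each carries an AR(1) (φ = 0.9) series
  at unit amplitude inside its slab and a 0.15 leak elsewhere, so the
  nuisance regression has something real to remove. Drift slopes are
  N(0, 0.005)/volume; motion traces are bounded random walks
  (step sd 0.04, bound 1.2), with an optional fraction of subjects given
  a > 2 mm excursion to exercise exclusion.

Study-design constants follow the emulated acquisition: TR 2 s, 255
volumes per run, 3 mm isotropic voxels, groups HC/MS/AS of 21/20/21
(62 subjects). The default analysis grid is 24×24×18 (a desk-scale
stand-in for a brain volume; acquisition constants are kept exact while
the voxel count is reduced for tractability). The default noise is
σ = 1.0 against unit-peak, unit-variance network signal — per-voxel
SNR ≈ 1 at blob peaks before smoothing, a deliberately conservative
regime in which 8-mm smoothing is what makes recovery work, as in real
data. The default planted group effect is the visual–salience (VN–SN)
coupling lowered by 0.31 (AS) and 0.43 (MS) on the z scale — magnitudes
taken from the range reported for this edge in the motivating
three-group study — plus amplitude scales (SMN ×1.2 and LFPN ×1.15 in
MS, SN ×0.85 in AS) mirroring its qualitative sensorimotor/frontal and
salience findings.

What the generator does *not* emulate: physiological (cardiac or
respiratory) noise, scanner artifacts and spatial autocorrelation of
noise, inter-subject anatomical variability (all subjects share one
grid and one set of maps), hemodynamic convolution, and age or sex
confounds. Passing tests therefore show the estimators are correct and
well-calibrated under the stated statistical structure, not that the
pipeline is robust to registration error or structured physiological
artifacts.

## Preprocessing

Fixed order: discard → motion screen → smooth → nuisance regression
(order is asserted by a regression test, since smoothing and regression
do not commute). "Exceeding 2 mm and/or 2°" is read strictly: a maximum
of exactly 2.0 is retained; thresholds are configurable. Screening
consumes provided motion-parameter tables; realignment itself is out of
scope for shared-grid data. Smoothing uses σ = FWHM/(2√(2 ln 2))/voxel
in voxel units with a half-sample-symmetric (reflect) boundary, which
conserves each frame's total mass exactly on small grids — chosen over
zero-padding, whose attenuation at the boundary is material at desk
scale. The nuisance design is [WM mean, CSF mean, linear ramp,
intercept] on the post-discard time axis; residuals are orthogonal to
the design to machine precision per voxel.

## Group ICA

Concatenation centers each subject's block per voxel. Model order
comes from the MDL criterion on covariance eigenvalues
(λ_{k+1..p}, p = min dimension, n = rows-as-samples):

    MDL(k) = −(p−k) n ln(gm_k / am_k) + ½ k (2p − k + 1) ln n,

minimized over k. A single concatenated PCA (rather than a two-stage
subject-then-group reduction) retains the top-k spatial eigenvectors;
whitened rows have identity covariance and the back-projection
reproduces the rank-k approximation exactly. Randomized SVD is used
above ~1500×1500 (seeded), exact SVD otherwise.

Infomax maximizes entropy through the logistic nonlinearity with
natural-gradient block updates, `W += lr (B·I + (1 − 2g(u)) uᵀ) W`.
Defaults: lr = 0.01/ln k, block ≈ 8√(m/3), tol 1e-6 on the per-pass
weight change, max 512 passes. Divergence (non-finite or exploding
weights) anneals the rate ×0.9 and restarts; oscillation (successive
pass updates turning by > 60°) anneals ×0.98 so the stochastic passes
settle. Components are canonicalized — unit-variance maps, sign fixed
by positive skewness, order fixed by explained variance — making the
decomposition deterministic given a seed. Gaussian sources terminate
cleanly but are not identifiable (ICA's standard caveat); the planted
blob maps are strongly super-Gaussian, which is why the logistic
nonlinearity suffices.

Dual regression: stage 1 regresses each volume on all group maps
jointly (plus intercept) → subject time courses; stage 2 z-scores the
time courses and regresses each voxel's series on them jointly →
subject maps. Stage-2 designs are z-scored (the common dual-regression
convention); whether the original workflow variance-normalized them is
not documented, so this choice is flagged here. Collinear group maps
(condition number > 1e8) are rejected.

## Network selection

Anatomical selection by experts is replaced by the only automatable
reading: optimal one-to-one assignment (linear sum assignment)
maximizing total |spatial correlation| against a template atlas —
planted ground-truth maps for simulated cohorts, any user-supplied
NIfTI template set for real data. Scores below 0.2 are flagged
unmatched (the threshold rejects noise components; configurable). A
greedy-vs-optimal audit warns when the assignment is ambiguous.
Matching is invariant to component sign and affine rescaling; ties
break toward the lower component index.

## Voxelwise statistics

RSN masks: voxelwise one-sample t over all subjects' dual-regression
maps, two-sided p with Bonferroni over in-brain voxels, mask = corrected
p < 0.05 *and* t > 0 (a network-presence mask; negative-loading voxels
are not part of the network). Zero-variance voxels get p = 1. Bonferroni
is used rather than random-field theory: exact and conservative, and
appropriate for synthetic grids with no smoothness model. The
three-group comparison is a voxelwise one-way ANOVA (the single-factor
reading of a full-factorial design with no covariates) plus pairwise
Welch t contrasts — unequal group variances are not assumed, a
deliberate divergence from pooled-variance defaults — each BH-FDR
corrected within the mask. The mask t-test pools all subjects; a
per-group-then-union variant would be a config change, not a different
algorithm.

## FNC statistic

Time courses are mask-averaged over each RSN's suprathreshold mask by
default (`timecourse_source: dualreg` switches to stage-1 regressors).
With TR = 2 s, the ±5 s lag range is not an integer number of samples,
so both series are linearly resampled to a 1-s grid (11 lags, −5..+5);
a TR-grid mode (lags −4..+4 s in steps of 2) exists for sensitivity
analysis. r(ℓ) is the Pearson correlation over the truncated overlap
window (no zero padding); the selected lag maximizes |r| with ties
broken toward smaller |ℓ|, then negative ℓ; the **signed** r at that lag
is reported — "absolute maximal" determines the lag choice only, which
is what lets negative (anticorrelated) connections appear in the
within-group diagrams. z = atanh(r) after clipping |r| to 1 − 1e-7.
Selection over lags inflates |r| under independence (max of ~11
correlated estimates); the package's null calibration is therefore run
through the same selection procedure, never against a lag-0 null. The
signed statistic remains mean-zero under independence, so the
within-group one-sample t stays calibrated (tested).

## Group inference

Within group: per-edge one-sample t on z, BH-FDR across the group's 66
edges, significant edges carrying the sign of the mean. Across groups:
per-edge one-way ANOVA with BH-FDR across the 66 ANOVA p-values;
Tukey–Kramer post hoc p-values (q = |Δ|/√(MSE/2·(1/nᵢ+1/nⱼ)),
studentized range with (3, n−3)) are reported without further
multiplicity adjustment beyond their built-in familywise control —
matching how such tables are conventionally reported. MSE is pooled
across all three groups. Mean differences are reported in the fixed
orders AS−HC, MS−HC, AS−MS, which satisfy
(AS−HC) − (MS−HC) = (AS−MS) identically. BH-FDR is computed in-package
by the exact step-up definition (q_(i) = min_{j≥i} p_(j)·m/j) so it can
be tested for *exact* agreement with a brute-force oracle; the
studentized-range distribution comes from scipy and is tested against a
numerical-integration oracle to 1e-4. Edges with numerically zero total
variation get F = 0, p = 1, post hoc p = 1 by convention.

## Problem sizes used in validation

The test suite and acceptance script choose sizes that keep a full run
on one CPU comfortable while preserving every design constant that
matters statistically: the full-scale recovery run uses the complete
design (62 subjects, 24×24×18, T = 255, k = 12); repeated-cohort checks
(planted-effect detection, 20 cohorts; type-I error, 50 cohorts) use a
16×16×12 grid and/or operate at the time-course level where the imaging
stages are irrelevant to the quantity being calibrated. Detection and
calibration results at these sizes transfer to larger grids because the
edge statistics depend on T, group sizes and planted effect sizes, not
on voxel count.

## Known limitations

- The simulator's shared-map, shared-grid design means template
  matching is easier than on real data; match scores near 0.92 here say
  nothing about anatomical-template matching quality on scanner data.
- MDL order selection assumes i.i.d. samples; no smoothness-corrected
  effective-sample variant is provided, so on heavily smoothed real
  data it will over-estimate the order.
- Amplitude-type group effects change extraction SNR and therefore leak
  into measured FNC on low-voxel grids (visible as secondary significant
  edges in the worked example); this is a property of the statistic, not
  a bug, but it means planted coupling deltas are recovered attenuated.
- No dynamic (windowed) FNC, partial correlations, cluster-extent or
  permutation inference, or covariate adjustment.
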