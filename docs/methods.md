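# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices behind them, and what the synthetic-data tests do and
do not establish about behavior on real cohort data.

## Network extraction

A grey-matter probability volume is tiled into cubes of `cube_edge = 3`
voxels per side starting at voxel (0,0,0); trailing slabs smaller than a
full cube are discarded, so tiling is deterministic and every node carries
exactly 27 intensities. A cube becomes a node when at least `min_gm_voxels
= 1` of its voxels exceeds `gm_inclusion_threshold = 0.1` grey-matter
probability; neither inclusion constant is canonical, so both are exposed
in `AnalysisConfig` rather than hard-coded. Node order is lexicographic by
cube origin.

Edge weights are Pearson correlations between cube intensity vectors. A
`rotation_mode` variant reports the maximum correlation over the 48
axis-aligned rotations/reflections of the second cube, which makes the
similarity orientation-invariant; it is off by default because plain
pairwise correlation is the primary definition, and the rotation variant is
kept for compatibility with toolchains that use it. Zero-variance cubes
yield flagged undefined correlations (NaN) that can never form edges; the
nodes are retained so the node count is unaffected.

The binarization threshold is subject-specific: the voxel values inside
included cubes are randomly permuted across those same positions (one
permuted volume per subject), the permuted volume is re-parcellated, and
the threshold is the (1 − alpha) upper quantile of the null correlations,
with `alpha = 0.05`. Up to `n_null_pairs = 10^6` null pairs are used; at
cube counts where more pairs exist, subsampling changes the quantile by
far less than its Monte-Carlo spread. Edges are strict exceedances
(r > threshold), one-sided and positive: the null construction is an
upper-tail exceedance rule, so negative correlations never form edges.

## Graph statistics

Local clustering is Watts–Strogatz: C_i = 2t_i / (k_i(k_i−1)), zero for
degree < 2. Characteristic path length is the mean shortest-path distance
over unordered pairs **within the largest connected component** — binarized
covariance networks are occasionally fragmented, and restricting to the
giant component avoids infinite distances; the component fraction is always
reported so the convention is auditable. Distances come from per-source
unweighted BFS on a sparse adjacency, keeping ~10³–10⁴-node networks cheap.

Random references are degree-preserving: 10 × n_edges attempted double-edge
swaps, rejecting self-loops and multi-edges. Degree sequences strongly
constrain both C and L, which makes this a sharper null than density-matched
Erdős–Rényi graphs. The small-world coefficient uses means over `n_random
= 5` references: gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda.
References whose path length is undefined are excluded with a warning.

**A caveat that matters for interpretation:** networks thresholded from
correlation matrices of spatially unstructured (i.i.d.) volumes are *not*
Erdős–Rényi graphs. Each node's standardized intensity vector is a point on
a 26-sphere and edges are spherical-cap neighborhoods, so two cubes that
both correlate with a third are themselves closer than chance. This
geometric transitivity gives even pure-noise volumes substantial clustering
and sigma well above 1 (≈ 3 at these cube counts and densities). Sigma
therefore separates *more* structure from *less* along a continuum; it is
not calibrated to equal 1 in the absence of spatial structure. Graph-level
nulls behave as expected: an Erdős–Rényi graph measured against its own
degree-preserving references gives sigma ≈ 1.

## Association models

Eight analytes (pTau, tTau, SNAP-25, Ng, NfL, VILIP-1, YKL-40, sTREM2) are
natural-log transformed before modelling; the Aβ42/40 ratio is analyzed
untransformed. The log base is immaterial because every predictor and the
outcome are subsequently Z-scored — always on the entire cohort (all
available values per column), so subgroup models inherit the cohort scaling
and slopes are comparable across predictors. Models are ordinary least
squares with complete cases per model; Wald (normal-approximation) 95% CIs
are used throughout, appropriate at the intended n ≥ 100 and easy to swap
for exact-t intervals. Rank-deficient designs are rejected with the
offending columns named.

Carrier staging: stage 1 iff pTau/Aβ42 < 0.019 (the boundary value is
classed abnormal because the normal range is defined strictly below the
cutoff); otherwise CDR 0 / 0.5 / ≥ 1 give stages 2/3/4. Missing ratios
leave the subject unassigned.

Per-group slopes are linear contrasts of the interaction model's
coefficients (non-carrier: the predictor main effect; carrier: plus the
interaction), with CIs from the fitted covariance. On balanced designs
these equal group-stratified refits exactly; in general they condition on
the pooled covariate estimates, and both routes are available.

Stage-interaction models (carriers only) test the joint predictor-by-stage
interaction with a Wald F test; stages with fewer than 3 subjects are
excluded with a warning. When the joint test is significant at 0.05, all
pairwise stage-slope contrasts are adjusted by the studentized-range (Tukey
HSD) procedure using the residual df of the single fitted model — with two
stages this reduces exactly to the unadjusted t test.

## Trajectory model

Restricted cubic splines use Harrell's truncated-power normalization with 3
knots at the 0.1/0.5/0.9 quantiles of the pooled EYO sample, giving two
basis columns (eyo_1 = identity, eyo_2 = restricted cubic term scaled by
(t₃−t₁)²); the represented function is linear beyond the boundary knots.

The observation model is Gaussian with a family random intercept. Rather
than sampling the per-family intercepts, they are marginalized analytically:
each family block has compound-symmetric covariance σ²I + τ²J with
closed-form inverse and determinant, so the sampled vector is just the
fixed effects plus (log σ, log τ). Priors are Cauchy(0, 2.5) on
standardized coefficients, Cauchy(0, 10) on the intercept, and half-Cauchy
(0, 2.5) on both scales — weakly-informative defaults of the applied
Bayesian regression literature, chosen because the analysis tradition this
model comes from specifies Cauchy priors without scales.

Sampling uses an affine ensemble MCMC with differential-evolution moves
(80% DE, 20% DE-snooker), which on this correlated spline posterior mixes
substantially better than stretch moves. `McmcSettings(chains, iterations,
thinning)` maps chains to ensemble walkers (widened to at least 2·(ndim+1)
when needed; the realized count is recorded), discards the first half of
iterations as warmup, and stores chains × (iterations − warmup)/thinning
draws. The production default is 8 chains × 10 000 iterations thinned by
10; tests and the acceptance script use 32 walkers × 6 000 iterations
thinned by 10, which passes the convergence diagnostic and changes
divergence estimates by less than the grid step. A split-chain potential
scale reduction factor is computed per parameter from the walker chains
(conservative, since walkers are not independent chains) and a warning is
emitted above 1.01.

Before fitting, biomarkers are Z-scored to young non-carriers (< 40 years),
so the carrier-minus-non-carrier difference reads in units of the normal
young reference spread. The difference curve at grid point g is the
posterior of β_mutation + β_eyo1:mut·b₁(g) + β_eyo2:mut·b₂(g), with
equal-tailed bands at 95/99/99.5% (nested by construction). The divergence
point at a level is the earliest grid EYO from which the band excludes zero
*and keeps excluding it through the end of the grid* — a single "point of
divergence" implies a persistent departure, and the sustained rule keeps
transient exclusions from producing spuriously early calls; first-pointwise
exclusion is available behind a flag. The default grid is −25 to +10 years
in 0.5-year steps, spanning the plausible EYO range at a step finer than
any claimed precision. Sustained exclusion plus nested bands guarantee that
stricter levels never diverge earlier.

## Synthetic data

`simulate_volume` plants cube-community covariance: each cube of the
parcellation grid belongs to one community; all cubes of a community share
a latent 27-vector with SD `community_signal × noise_sd` on top of i.i.d.
voxel noise, so the expected within-community cube correlation is
c²/(c²+1) with c = `community_signal` (between-community ≈ 0). Values are
clipped to [0, 1]; at the default `noise_sd = 0.05` and baseline 0.5,
clipping is negligible. `simulate_null_volume` draws i.i.d. uniform voxels.

`simulate_cohort` emulates a cross-sectional ADAD cohort: 216 carriers and
136 non-carrier family relatives in 40 families by default. Each family
draws a mean onset age uniform on 40–55; each subject draws an EYO uniform
on −30 to +10 and visit age = onset + EYO, so the EYO identity holds by
construction. Analytes are log-normal with NC means and SDs moment-matched
to realistic assay values, family intercepts shared by siblings
(`family_sd = 0.3` vs `residual_sd = 0.95` on the standardized log scale),
and an optional shared latent factor across analytes (default off — the
joint correlation structure among analytes is not pinned down, so no value
is claimed). Carrier means depart from NC means as a piecewise-linear hinge
on the standardized log scale: flat before the analyte's divergence EYO,
linear after, reaching `mc_effect` standardized units at EYO 0 (for
analytes diverging at EYO ≥ −1, where that anchor is degenerate, at
divergence + 10 years). The hinge is the simplest departure whose onset is
itself a recoverable parameter. Default divergence EYOs stagger amyloid and
tau markers earliest, synaptic and neuronal-injury markers next, axonal and
inflammatory markers around the small-world divergence (−6), and microglial
and Aβ40 changes after it. CDR is assigned from EYO in carriers (0 below
−3, 0.5 to +3, then 1/2/3 at +3/+7/+11); non-carriers stay CDR 0.
Missingness is completely at random per analyte, defaulting to the
panel-availability pattern (about half missing for NfL and sTREM2, 7% for
the research-assay analytes, none for the core markers). Ratios are
computed after missingness so a ratio is present exactly when both
components are.

What the generators do **not** emulate: anatomy (no cortical geometry,
folding or atlas structure), spatial autocorrelation beyond the planted
communities, longitudinal visits, informative missingness, assay batch
effects, or a claimed inter-analyte correlation structure. Passing
recovery tests therefore establishes that the estimators recover what they
are pointed at under the stated model, not that real acquisition artifacts
are handled.

## Problem sizes used in tests

Simulation-based checks run at desk scale by choice: 30³-voxel volumes
(1000 cube nodes), 20 null volumes for threshold calibration, 200–300
replicates for OLS coverage and error rates, and 8–18 replicated trajectory
fits at n = 350 subjects in 40 families with 32 walkers × 6 000 iterations.
These sizes put Monte-Carlo error comfortably inside the asserted bands
while keeping the full suite in minutes.

## Known limitations

* Sigma is not calibrated against correlation-geometry clustering (see the
  caveat above); comparisons should be within-method, between subjects.
* Wald CIs slightly undercover at small n; observed coverage at n = 350 is
  ~93%.
* The ensemble sampler's split-R̂ is conservative; values up to ~1.015 on
  the trajectory posterior reflect walker correlation, not failure to
  explore.
* Divergence points inherit the grid resolution (0.5 years) and, as
  cross-sectional estimates, read as group-level ordering information, not
  individual predictions.
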