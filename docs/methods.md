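# Methods

`rehofc` implements a resting-state fMRI analysis chain that links
executive function (EF) and episodic memory (EM) through seed-based
functional connectivity (FC): regional-homogeneity (ReHo) seed
discovery, seed-to-whole-brain correlation networks, covariate-adjusted
group inference with a voxelwise gray-matter correction, Monte-Carlo
cluster-extent thresholds, behavior-connectivity regression with
conjunction, and a three-step mediation model. Every stage can be
exercised against a synthetic cohort with planted, recoverable ground
truth. This note records the models, the defaults and why they are what
they are, the numerical choices, and what the synthetic verification
does and does not establish.

## Preprocessing

Order is fixed: discard the first `n_discard` volumes (default 10, for
T1 equilibration at TR = 2 s) → per-voxel linear detrend → temporal
band-pass 0.01–0.08 Hz → nuisance regression (six motion parameters,
plus WM, CSF and optionally the global mean signal). Motion scrubbing is
applied only on the connectivity branch; ReHo uses the continuous,
motion-regressed series, because deleting volumes would break the rank
structure of neighboring time courses.

**Band-pass.** An ideal (rectangular) frequency-domain filter: the
demeaned series is zero-padded to a fast FFT length, bins strictly
outside [low, high] are zeroed, and the series is inverse-transformed
and truncated. The filter's transfer gain is exactly 0 in the stopband
and 1 in the passband; tests measure the response of a sinusoidal probe
as the amplitude remaining *at the probe frequency* (the projection of
the output onto the probe). A 240-sample record of a 0.005 Hz sinusoid
also leaks a few percent of broadband energy through truncation
side-lobes; that is a property of the finite record, not of the filter,
and the projection measurement separates the two.

**Framewise displacement (dRMS).** Rotations (degrees) are converted to
arc length on a 50 mm sphere; element *i* is the RMS over the six
backward-differenced parameters between volumes *i* and *i+1* (i.e.
`sqrt(mean(d^2))`, so a single-axis 0.3 mm step gives 0.1225 mm). A
transition above 0.5 mm is attributed to the later volume; that volume,
one back and two forward are deleted. Subjects whose cumulative
translation exceeds 2.0 mm or rotation 2.0° on any axis are flagged for
exclusion. A QA report compares per-subject mean dRMS between groups
with a two-sample t-test.

**Global-signal regression (GSR).** Fully implemented and on by default
at the operation level, but the pipeline config defaults it *off* for
synthetic studies. On the 24×28×24 grid the planted networks are ~8% of
the ~7,000-voxel brain, so the global mean carries an appreciable copy
of the mediator-coupled network signal; regressing it out injects a
sign-inverted, behavior-correlated component into every voxel and can
flip the sign of the measured EF→FC path. In real acquisitions networks
are a much smaller fraction of the in-mask volume and this leakage is
second-order; `global_signal: true` restores the conventional setting.

## ReHo

For each in-mask voxel, Kendall's coefficient of concordance W is
computed over the voxel and its nearest neighbors (27 by default; 19 and
7 available) across time:

    W = 12 * sum_t (R_t − k(n+1)/2)^2 / (k^2 (n^3 − n)),

with within-series ranks over time and R_t the across-series rank sum.
W ∈ [0, 1]; under independence E[W] = 1/k. No tie correction is applied
— BOLD intensities are continuous, so exact ties have probability ~0;
constant series receive first-occurrence ranks with a logged warning. At
mask edges the neighborhood is intersected with the mask and k is the
actual neighbor count (minimum 2). Maps are divided by the whole-brain
mean (in-mask mean exactly 1 afterwards) and then smoothed with an 8 mm
FWHM Gaussian (σ = FWHM/(2√(2 ln 2)) ≈ 1.13 voxels at 3 mm); smoothing
uses normalized convolution inside the mask so edge voxels are not
diluted by outside zeros.

Mean normalization has a known side effect that shows up clearly in
synthetic data: a genuine group difference confined to the seeds shifts
the whole-brain mean of one group, which induces small opposite-sign
"differences" at every other high-ReHo region. Seed selection therefore
names suprathreshold clusters by the atlas label at their peak, and the
pipeline carries forward only the two canonical seed regions (the
frontal DLPFC-like and retrosplenial RSC-like seeds) — the counterpart
of selecting two of several candidate regions on neuroscientific
grounds. Discovered clusters are used as ROIs directly; a fixed-radius
sphere at the peak is available as an alternative.

## Seed-based connectivity

The connectivity branch smooths the preprocessed data (8 mm FWHM),
scrubs flagged volumes, extracts the seed ROI's mean time course,
correlates it with every in-mask voxel, and applies Fisher's
z = arctanh(r). Zero-variance voxels get r = 0 with a flag; |r| ≥ 1 is
clamped to 1 − 1e−7 with a warning. Degrees of freedom downstream use
the retained (post-scrub) volume count. Group comparisons are restricted
to voxels with significantly *positive* group-mean connectivity — the
standard guard against interpreting the spurious negative couplings that
global-mean correction can create.

For the positive-connectivity mask the pipeline corrects the one-sample
t maps by cluster extent (voxel p < 0.01, Monte-Carlo extent threshold,
positive t, union over the two groups). A Bonferroni variant
(`one_sample_map`) exists and is the operation-level default; at
desk-scale n it requires |t| ≳ 7 and would exclude targets whose
between-subject spread is dominated by genuine mediator variance, so
the pipeline uses the extent-corrected form.

## Group and behavior statistics

All voxelwise inference is OLS. The group model per voxel is

    FC_v ~ 1 + group + age + gender + education + GM_v,

where GM_v is that subject's smoothed half-logit gray-matter value *at
voxel v* (logit(a) = 0.5 ln(a/(1−a)), probabilities clamped to
[1e−6, 1−1e−6], then 8 mm smoothing) — the gray-matter covariate enters
voxel-wise, so anatomical atrophy cannot masquerade as connectivity
change. The batched per-voxel solver is checked against a per-voxel
statsmodels loop to 1e−10. Behavior maps regress FC on one composite
score at a time with the same covariates. Cluster formation is two-sided
at the voxel threshold, components per sign, 26-connectivity by default
(6/18 available), extent filter applied as `extent >= min_extent_voxels`
(74 voxels = 1,998 mm³ and 389 voxels = 10,503 mm³ at 3 mm are the
conventional fixed values). Tables report extent, peak world-mm
coordinate, atlas label at the peak, and peak t. Conjunction is the
voxelwise intersection of two significant sets, tabulated by connected
component. Partial correlation of extracted strengths with a score
residualizes both on the covariates and uses df = n − k − 2.

**Extent thresholds.** The fixed mm³ values above were derived by the
original AlphaSim procedure for a particular mask and smoothness and do
not transfer to other geometries. The pipeline therefore estimates its
extent thresholds per run with the `clustersim` module on the actual
analysis mask (default), or uses the fixed voxel counts
(`extent_source: fixed`). The Monte-Carlo procedure: fill the mask with
white noise, smooth at the nominal FWHM, restandardize within the mask
(so the realized voxelwise exceedance equals the nominal voxel p),
threshold two-sided, record the largest per-sign cluster; the threshold
is ceil of the (1−alpha) quantile of max extents plus one voxel (strict
">"). 5,000 iterations reproduce the threshold to within one voxel
across independent streams on the default mask.

## Composite scores

EM = mean of z-scored AVLT_DR, CFT_DR, LMT_DR; EF = mean of z-scored
TMT_A, TMT_B, SCWT_C. z-scores are taken against the pooled mean and
*sample* SD (n−1) of the whole cohort — pooling across both groups is
what lets group differences survive into the composites. EF members are
completion times, so larger EF = slower = worse, and no sign flip is
applied; when ability correlates across domains the EM–EF association is
therefore negative. Missing raw scores propagate to missing composites
with a log message.

## Mediation

Three OLS regressions, each with an intercept (the textbook equations
omit intercepts, but without them estimates are biased for non-centered
scores):

    (1) EM = c  EF + e1
    (2) FC = a  EF + e2
    (3) EM = c' EF + b FC + e3

Without covariates c = c' + a·b holds exactly (asserted to 1e−10).
Classification: *none* unless c, a and b are all significant (OLS
t-tests, two-sided alpha = 0.05); then *full* if c' is insignificant,
*partial* if |c'| < |c|. The mediated fraction (a·b)/c is reported only
when c is significant (it is unstable near c = 0). A Sobel z for a·b is
reported as supplementary information; the classification itself uses
only the per-path t-tests. A covariate-adjusted variant appends
age/gender/education to all three regressions (the identity then no
longer holds and the result is flagged). The mediator is the mean
Fisher-z connectivity over the conjunction cluster's voxels.

## Synthetic cohorts

The generator produces everything downstream of spatial normalization:
4D BOLD at 3 mm on a 24×28×24 grid (an ellipsoidal brain of ~7,000
voxels with deep WM and ventricular CSF compartments), GM probability
maps, six-parameter motion traces, and a phenotype table. Defaults are
the study conditions: TR 2 s, 240 volumes, cohort 79 patients / 119
controls, ages 54–80, education 6–20 years.

**Signals.** Each region carries a band-limited (0.01–0.08 Hz) unit-
variance latent; target regions mix their seed's latent with weight
r = tanh(z) for a planted per-subject coupling z, so seed-target
correlation equals the planted value by construction. Voxel noise
(SD 0.6 relative to the regional signal) is half white, half spatially
smoothed (σ 1.2 voxels), emulating BOLD's intrinsic spatial
autocorrelation; regional and global amplitudes get multiplicative
per-subject jitter (log-SD 0.2). Both realism terms matter: without
them, between-subject variance of image-level confounds is nearly zero
and arbitrarily small systematic effects become massively significant at
n = 198. A weak global fluctuation (amplitude 0.2) is shared by all
brain voxels.

**ReHo hotspots.** The patient-vs-control contrast in local homogeneity
is planted by scaling the *local noise* inside the seed regions
(multipliers 0.6 in patients, 2.2 in controls). This leaves the regional
signal amplitude — and therefore seed-based connectivity and the global
mean — group-invariant while moving within-region concordance along the
steep part of the noise→W curve. (Two rejected designs: a shared-signal
gain contrast saturates W; an amplitude contrast warps FC brain-wide.)

**Couplings.** Frontal-network targets (MCC-like, caudate-like,
ACG/SMA-like) couple at z = 0.4 in patients vs 0.1 in controls
(Δz = 0.3, raised in patients); the retrosplenial network's PCC/PCu-like
target is reversed (0.1 vs 0.4, lowered in patients); the two
IPL-like targets couple equally (0.3). Region extents (~100–350 voxels)
are on the scale of typically reported clusters. Per-subject coupling
noise SD is 0.1, except the mediator (below).

**Phenotypes and mediation truth.** EF composites are drawn per group
(patients 0.44 ± 0.95, controls −0.27 ± 0.52 on the composite-z scale).
The mediator is the planted seed→MCC coupling,
M = z_group + a(EF − EF_group) + e2 with a = 0.3 and σ2 = 0.3, so the
planted group Δz stays exactly 0.3 while within-group variation follows
the mediation model. EM = intercept_group + c'·EF + b·M + e3 with
c' = −0.2 and b = −0.5, giving total effect c = c' + ab = −0.35 and
mediated fraction (a·b)/c = 0.4286. Group intercepts and residual SDs
are solved analytically so group EM composites come out at
−0.74 ± 0.71 / 0.50 ± 0.51. Raw test scores are affine embeddings of the
composite targets plus member noise whose variance is solved so that
pooled member variance ≈ 1; pooled z-scoring downstream then returns the
calibrated group means. Because pooled z-scores depend on group
proportions, the calibration reproduces those numbers at the 79/119
proportions specifically.

Two knowingly simplified points, with their consequences:

* The three tests per domain are parallel forms with reliability ~0.64
  (forced by the calibrated composite SDs, whose pooled variance is well
  below 1). Fitting mediation on the *measured* composites therefore
  inflates the apparent mediated fraction (~0.52 instead of 0.43) by the
  classic error-in-regressor mechanism — an attenuation the original
  design would share. Recovery of the generative 0.429 is checked on the
  generative-scale scores; the pipeline also reports the
  measured-composite fit.
* Connectivity measured through the imaging chain is attenuated ~10%
  relative to planted couplings (region-mean extraction after smoothing
  dilutes edge voxels; the shared global fluctuation inflates
  denominators). The planted Δz = 0.3 is typically recovered as
  0.26–0.34 at 30/group, with its 95% CI covering 0.3.

**Motion.** A per-parameter random walk (step SD 0.01) plus, for ~30% of
subjects, one persistent spike of 0.8–1.4 mm applied to all three
translation axes (framewise dRMS spike/√2, so every cohort spike trips
the 0.5 mm rule while staying inside the 2.0 mm exclusion bound). A
single spike at volume v flags exactly {v−1, v, v+1, v+2}.

**GM maps.** Smooth probability fields strictly inside (0, 1): GM ~0.75,
WM ~0.25, CSF ~0.10 plus smoothed noise; optional patient atrophy
subtracts a constant in designated regions before smoothing, detectable
by a two-sample t-test at 0.1 loss and 40/group.

**Determinism.** All randomness flows from one integer seed;
per-subject streams are derived deterministically, BOLD volumes are
regenerated on demand (so full-size cohorts never hold all images in
memory), and two runs of the full pipeline with the same seed write
byte-identical summary JSON.

## What the synthetic verification shows — and does not

Passing tests establish that each operation implements its stated
formula (oracle equivalence, null calibration, closed-form cases), that
the chain recovers planted effects of realistic size at realistic n, and
that the whole pipeline is deterministic and honest about thresholds.
They do not establish performance on real BOLD data: the generator has
no anatomy, no slice-timing or realignment residuals, no physiological
(cardiac/respiratory) structure, no scanner drift beyond a linear trend,
and stationary Gaussian noise. Two desk-scale distortions deserve
emphasis because they were large enough to change default choices: the
planted networks occupy a far larger fraction of the brain than real
networks do (which is why pipeline GSR defaults off), and the brain-mean
ReHo normalization couples any real seed difference to every other
region (which is why seed selection is restricted to the two canonical
regions).

## Default problem sizes

Unit and property tests run on toy volumes (≤ 12³) and small cohorts;
the end-to-end recovery checks use 30/group at 200 volumes and the
cohort-calibration checks use 79/119 phenotype-only cohorts; the
mediated-fraction check averages 200 cohorts of 79 patients; the
Monte-Carlo threshold reproducibility check uses two 5,000-iteration
runs. The full-pipeline demonstration (`run_all` with defaults) is
79/119 at 200 volumes and takes a few minutes on one core.
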