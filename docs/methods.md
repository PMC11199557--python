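# Methods

## The parcellation model

Each striatal voxel carries two nonnegative tractographic scores — its
streamline score to a striosome-favoring and to a matrix-favoring composite
target set.  The connectivity bias of a voxel is the per-target fraction of
the summed score; where the total score is zero the bias is undefined and
the voxel can never be labeled, but it remains in the striatal mask and so
still enters the MCS and iSD denominators (both indices are defined over the
whole mask).  A voxel is labeled striosome- or matrix-like when its bias to
that target is **at least** the threshold (inclusive comparison; default
0.87, strict variant 0.95).  Because the two fractions sum to one and the
threshold exceeds 0.5, the labels are disjoint by construction.  The
comparison convention matters only on the measure-zero boundary where the
bias equals the threshold exactly; the inclusive reading was chosen because
it is the natural reading of a predominance *of at least* the cutoff.

Volumes are labeled-voxel counts × voxel volume (2 mm isotropic → 8 mm³),
reported per hemisphere and in total.  Compartment volumes are adjusted to
the control-group mean total striatal mask volume (TSMV):

    vol_adj = vol_raw − β (TSMV_raw − TSMV_mean)

with β the OLS slope of raw volume on TSMV *in controls only*, fitted
separately for every adjusted measure (bilateral totals and per-hemisphere
volumes each get their own β).  Two consequences are used as exact test
oracles: the control mean of adjusted volumes equals the control mean of raw
volumes, and adjusted volumes regressed on TSMV in controls have slope zero.
Per-hemisphere volumes are adjusted against the subject's *total* TSMV (not
the hemispheric one), mirroring how the side analyses reference the total
mask volume; MCS and iSD are never adjusted.  Bilateral MCS and iSD are the
means of the two hemispheric values, each computed with its own hemisphere's
voxel count as denominator.

## The tracker

The tracker is a deliberately simplified classification-targets
probabilistic tractography engine for synthetic orientation fields: seeds at
voxel centres, fixed 0.5 mm steps, at most 2000 steps, 5000 samples per seed
voxel, a curvature threshold of 0.2 interpreted as the minimum cosine of the
turning angle between successive steps, and first-hit semantics — a sample
is credited to the first target it enters and stops there.  Orientation
lookup is nearest-voxel (no trilinear interpolation), which keeps tiny
phantoms exactly analysable.  Tracts are treated as undirected: at each step
the sign of the sampled fibre direction is chosen to minimise the turning
angle, so stored orientation signs matter only for the first step.
Direction noise, when enabled, is a von Mises–Fisher perturbation around the
sampled fibre axis ("angular dispersion" = the vMF concentration).  With
distance correction on, a sample contributes its path length in mm instead
of a unit count; the exact weighting used by reference implementations is
not restated anywhere authoritative, so length-in-mm is adopted as the
approximation and scores should be compared only within one convention.
A midline exclusion mask terminates (and discards) samples that would cross
hemispheres, keeping connections ipsilateral.

## The synthetic cohort generator

The generator emulates what the real study measures, not how the brain
produces it.  Per subject it draws demographics (age, sex, MoCA, TIV, TSMV
per group), putaminal SBR per hemisphere (PD and iRBD only; a lognormal side
asymmetry multiplier calibrated to a ~13.8% mean relative side difference;
three iRBD subjects lack SBR, giving the pooled n = 125), item-level
MDS-UPDRS III scores, and a voxel geometry: one contiguous ellipsoid-like
blob per hemisphere holding exactly the subject's TSMV, with striosome
islands (3 mm radius balls) placed with a rostro-ventro-medial spatial
preference until the configured striosome fraction (default 0.156) is met
exactly — the island count is therefore emergent, not configured.

Scores follow a three-layer mixture per voxel:

1. **bias layer** — latent striosome-ward bias (0.95 in islands, 0.05 in
   matrix) with logit-normal voxel jitter (σ = 0.8) producing the
   near-threshold scatter that the 0.87 labeling acts on; hemispheric SBR
   deficit (reference 2.8 minus the hemisphere's SBR) shifts the bias toward
   matrix;
2. **reach layer** — Bernoulli zero-inflation per channel (own-target reach
   ~0.52 for matrix voxels, ~0.93 for striosome voxels; cross-target reach
   conditional on own reach, plus a 5% "leak" of voxels connected only to
   the opposite target).  This is what puts iSD near 50% instead of 100%;
3. **magnitude layer** — Poisson scores (matrix voxels ~9830 mean total,
   striosome ~1850 at the default 5000-samples budget; distance-corrected
   scores exceed raw counts, hence the >5000 means), scaled by per-subject
   lognormal channel effects (σ = 0.36) and per-subject/hemisphere reach
   jitters (SD 0.06 / 0.04).

Disease effects enter in four places: hemispheric SBR deficit raises matrix
reach (+0.019/unit) and matrix magnitude (+10%/unit); the *within-subject*
relative deficit lowers striosome reach and magnitude on the worse side and
raises matrix reach there (creating paired side differences without
inducing between-subject striosome–SBR correlations, which the reference
data do not show); and lateralized motor item rates couple to the
contralateral hemisphere's relative deficit (coupling 2.0).  Setting every
effect slope to zero (`CohortConfig.null()`) yields a null generator used
for type-I-error calibration.

**Calibration.**  No per-compartment SBR-effect magnitudes are published, so
the defaults were solved analytically from the mixture moments to reproduce
the reference cohort's printed summary statistics — control striosome-like
fraction ≈ 15.4%, matrix iSD ≈ 50.7%, matrix MCS ≈ 4.5·10³, adjusted
matrix-like volumes ≈ 5.8 (control) and 6.3 cm³ (PD), SBR–matrix-MCS partial
correlation ≈ −0.27 — and then refined once by simulation.  These are
calibration targets, not measurements: hitting them shows internal
consistency of the pipeline, not anything about real brains.  One
compromise: the within-group SBR SD is set to 0.8 (slightly wider than the
side-table dispersions imply) so that the partial correlation and the
between-group volume gap can be carried by a single slope.

**What the generator does not emulate:** anatomically realistic striatal
shape, nucleus accumbens / caudate-tail exclusions, registration error, CSF
contamination, scanner/site effects, spatially correlated score noise, or
any cortical geometry — the tracker phantoms use abstract target slabs.
Passing tests therefore validate the estimators and the inference chain,
not the biological claims.

**Determinism.**  One RNG stream per subject, seeded by
`(config.seed, subject_index)`, so identical configs are bit-identical and
adding subjects never perturbs earlier ones.  With all four dispersions at
zero the generator switches to exact-expectation mode (every mask voxel
scores `samples_per_voxel` split by its latent bias), which the
parameter-recovery tests exploit.

## Statistics

ANCOVA is fitted by OLS on an explicit design matrix (intercept, k−1 group
dummies, covariates); the group effect is the Type-III model-comparison F,
partial η² = SS_group/(SS_group+SS_error), and the LSD post-hoc contrasts
are unadjusted t-tests on covariate-adjusted mean differences using the
full-model pooled error.  Sex enters as a single 0/1 covariate.  Partial
correlation uses the residual method, with p from
t = r·√((n−k−2)/(1−r²)); a variable perfectly explained by the covariates
returns r = 0 by convention, while a constant input raises an error.  Paired
side comparisons use the paired Student's t with Cohen's d =
mean(diff)/SD(diff).  Age matching is greedy 1:1 with randomized case order
and a 5-year tolerance.  Item 9 appears in both the bradykinesia and axial
subscore listings; it is kept in both by default (as printed) with a
`drop_overlap` switch.  The supra-threshold matrix:striosome count ratio is
reported as the raw labeled-voxel count ratio; whether it should instead be
normalized to compartment priors is ambiguous, and the raw ratio is the
documented choice.

## Problem sizes in the test suite

Unit tests run on 4–14-subject cohorts and ≤20-row statistical fixtures with
closed-form oracles.  The calibration-recovery tests use 20 full-size
cohorts (45/56/72) and check seed-averaged quantities; the type-I-error
check uses 1000 null datasets of n = 60; parameter recovery tracks ~1800
seed voxels at 8 samples each with zero dispersion.  These sizes keep the
whole suite under a minute while leaving the seed-averaged acceptance
quantities with standard errors well inside their tolerances.

## Known limitations

- The tracker is a phantom engine; it does not fit orientation fields from
  diffusion data and its fields are nearest-voxel constant, so streamline
  geometry is piecewise straight.
- The generator's voxels are conditionally independent given subject- and
  hemisphere-level effects; real tractographic scores are spatially
  autocorrelated, so mask-level variances are better matched than voxel-level
  spatial statistics.
- TIV is a pass-through covariate with a generic adult distribution; it is
  used only as an ANCOVA covariate for mask-volume comparisons.
- Disease duration is generated for table parity but drives nothing.
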