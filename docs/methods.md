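# Methods

This note documents the modelling assumptions, parameter choices and known
limitations of the `inflammetry` package: the synthetic cohort generator,
the connectivity and source-decomposition stages, the two regression levels,
and the numerical conventions that hold them together.

## The synthetic cohort

The generator emulates the data-generating structure a TSPO-PET +
resting-state fMRI case-control study assumes, at the scale such studies
run: 28 patients on the AD/MCI+ spectrum and 14 healthy controls.

**PET maps.** Five spatially compact sources (isotropic 3-D Gaussian blobs,
unit peak, SD ≈ grid/10 voxels) are placed at random centers at least four
blob-SDs apart on a 20×20×20 grid (8,000 voxels; large enough for stable
ICA, small enough for a laptop), giving pairwise spatial correlations below
0.05. Subject maps are `loadings @ sources` plus i.i.d. Gaussian voxel noise
(SD 0.1 in binding units; sources have unit peak). Loadings are zero-mean
normal with SD 0.75 per component; patients receive a fixed shift of
`group_effect` (default 1.0) on the *target* component, so the planted group
difference in mean loading equals the requested effect exactly. The
within-group SD is a calibration choice — real studies do not publish it —
set so the joint selection rule (group test AND patient-stratum atrophy
test) recovers the target component in ≈95% of replicates rather than
sitting at the edge of detectability; the group shift itself is never
touched. A smooth ellipsoidal gray-matter probability template (≈0.75 inside,
0.05 outside, per-subject jitter SD 0.02) supplies the masking stage; blob
centers fall inside the >0.3 region.

**Connectivity.** Thirteen nodes (5 default-mode, 4 frontoparietal,
4 subcortical) share a baseline correlation matrix: 0.5 within networks,
0.2 between DMN and FPN, +0.15 DMN–hippocampus, −0.1 DMN–putamen, 0.05
elsewhere (verified positive definite). Subject *i*'s latent correlation on
connection *j* is `base(j) + coupling · w(j) · centered_loading(i)` with
planted weights w = +0.2 on the ten DMN–hippocampus connections and −0.2 on
the ten within-DMN connections (hyper-connectivity between DMN and medial
temporal structures, within-DMN breakdown — the directional pattern the
analysis is designed to detect), clipped to ±0.95 with a Higham
nearest-correlation repair (logged) if clipping breaks positive
definiteness. Time points (263 volumes at TR 2.43 s) are drawn i.i.d. from
the subject's multivariate normal: no temporal autocorrelation or
hemodynamics, because only the cross-sectional connectivity estimates feed
the analysis. Consequences: synthetic connectivity estimates are somewhat
more precise than real BOLD at the same series length, and nuisance
regression has nothing real to remove — the cleaning stage is therefore
exercised by its own spectral unit tests, not by the pipeline recovery
suite.

**Cognition and covariates.** A latent factor
`g = −1.2·patient + slope·centered_score·patient + ε` (group gap 1.2 in
latent units; slope default −0.5; latent noise SD 0.15) generates three
observed tests as `g` plus test-specific noise (SD 0.45), mapped affinely to
MMSE-, ACE-R- and RAVLT-like scales. The two noise SDs are calibrated
jointly so that (a) the first principal component of the z-scored tests
explains ~0.80 of their variance (mean 0.800 over seeds 1–20; individual
seeds scatter ±0.05 with n = 42) and (b) the second-level interaction test
has ~0.88 power at the default slope. Total gray matter is planted with
correlation −0.65 to the (standardized) target loading within patients and
is independent of loading in controls; this value keeps the patient-stratum
atrophy test at ~97% power while limiting the collinearity that total GM —
itself a second-level covariate — induces with the interaction regressor.
Age, sex, education and motion approximate the published cohort profile and
carry no signal.

All randomness derives from one master seed through named substreams
(`sources`, `loadings`, `map_noise`, `gm_maps`, `timeseries`, `cognition`,
`covariates`), so regenerating any one modality is reproducible in
isolation.

## Connectivity stage

Node series are cleaned by a single least-squares projection per node onto a
design holding: intercept; linear trend; a 24-parameter motion expansion
(6 realignment parameters, first differences, squares of those 12); WM and
CSF mean signals (voxels with tissue probability > 0.7) with differences and
squares; and a DCT-II basis restricted to frequencies *outside*
0.0078–0.1 Hz (k/(2·T·TR) below the low cut or above the high cut), so
filtering and nuisance regression happen simultaneously and residuals are
orthogonal to every retained column. Rank-deficient designs are reduced by
pivoted QR with dropped columns logged; constant columns (e.g. zero motion
input) are dropped up front. With the full random-nuisance design at
T = 263 roughly 30% of any fixed in-band signal is absorbed by the ~34
random regressors — an unavoidable property of projection, worth knowing
when interpreting the passband contract, which is exact only for the
DCT-only design.

Head motion is summarized as the root-mean-square over volume pairs of the
Euclidean norm of parameter increments, rotations converted to arc length on
a 50 mm sphere (a stated convention; other radii rescale the rotational
contribution). Connectivity is the Pearson correlation of cleaned series,
stored as the upper triangle in lexicographic pair order. Univariate group
statistics Fisher-z-transform correlations before two-sample t-tests with
Benjamini–Hochberg correction; the first-level regression consumes raw
correlations, keeping "Pearson correlation" as the stated connectivity
measure (a documented choice — the two conventions differ negligibly at
|r| < 0.6).

## Source-based inflammetry

The group mask keeps voxels whose *group-mean* GM probability exceeds 0.3
(strict; reconciling the two phrasings "probability of 0.3 across all
individuals" and "larger than 0.3" in the usual way for group templates).
Model order minimizes the Wax–Kailath MDL cost computed from the
eigenspectrum of the subject-level covariance across masked voxels,
candidates 1..n_subjects−1; numerically-zero tail eigenvalues are floored at
a relative 1e−12 so noiseless low-rank stacks behave. The decomposition is
PCA whitening to the chosen order followed by fixed-point ICA (deflation,
logcosh contrast, tolerance 1e−6), deterministic given the seed with three
documented fallback seeds retried on non-convergence. Sources are
standardized to unit variance over masked voxels and sign-fixed to positive
skewness — hot spots load positively, so a higher loading means higher
binding in the source's peaks — with scale and sign folded into the
loadings, leaving the reconstruction invariant; components are ordered by
explained variance.

Component selection requires (1) a robust group difference in loadings —
Huber IRLS (c = 1.345, MAD scale, H1 covariance, matching the standard
RLM conventions) with a two-sided permutation p from label shuffles of the
robust t — and (2) a significant *negative* robust association between
loadings and total gray matter specifically in the patient stratum. Zero or
multiple qualifying components raise distinct, descriptive errors rather
than guessing. The group test is intentionally covariate-free at this
stage. Outliers are screened by the iterative two-sided Grubbs test
(t-quantile critical values); note the classic masking caveat: two extreme
points on opposite sides can shelter each other, which the brute-force
deletion oracle in the tests shares by construction.

## First level

Connections are z-scored; the regularized covariance is the analytic
Ledoit–Wolf convex combination `(1−ρ)S + ρμI` (or a fixed ρ). Weights solve
`Σ w = cov(X, y)`; brain scores are the fitted linear combination; structure
coefficients are plain Pearson correlations of each connection with the
brain scores (verified identical to direct computation). One property of the
analytic intensity worth knowing: when the true covariance is close to the
spherical target μI (e.g. i.i.d. predictors), the optimal ρ approaches 1 —
shrinkage is then strong yet harmless, since target and truth coincide.

Cross-validation re-partitions subjects into 5 folds per repetition (1,000
repetitions by default), learns standardization and shrinkage on training
folds only, and reports the median Pearson R between pooled out-of-fold
predictions and observed loadings. Because predictions are linear in the
response for fixed connectivity, each (repeat, fold) yields one prediction
operator reused across all label permutations; the model-level permutation
p compares the observed median R with the identically-computed statistic
under label shuffles (one-sided), and per-connection structure-coefficient
permutation p-values are FDR-corrected. This exactness-by-symmetry is what
the 200-replicate null calibration in the acceptance suite checks.

Brain scores entering the second level come from the full-sample fit; CV
serves only to validate the fit. Grubbs screening is applied to the selected
loadings before the fit (flagged subjects excluded, logged). Covariates of
no interest default to the second level, where the source text attaches
them; `covariate_placement` can move the residualization to the first level
or both (the first-level option also removes the GM-correlated share of the
loading variance, which in the synthetic design is signal — a trade-off the
configuration makes explicit rather than hiding).

## Second level

The cognitive composite is the first principal component of the z-scored
tests (scales are incommensurate), sign-fixed so all three loadings are
nonnegative: higher composite, better cognition. The interaction model
regresses the composite on centered brain scores, group (patients = 1),
their product, and age, sex (F = 1), motion RMS and total GM, by Huber IRLS
(OLS available). p-values use the t distribution with residual degrees of
freedom rather than the asymptotic normal reference — at n = 42 with 8
parameters this keeps the null rejection rate near nominal (0.070 measured
over 200 replicates) where the normal reference is slightly liberal.
Centering the brain scores before forming the product decorrelates main
effect and interaction; without covariates the interaction coefficient
equals the difference of within-group slopes exactly (verified
numerically). Post hoc within-group Pearson correlations mirror the
second-level result descriptively. The amyloid rule classifies a subject
positive iff mean cortical SUVR strictly exceeds 1.5. Cohort summaries
compute pooled-variance two-sample t-tests from raw rows or directly from
printed means/SDs/ns — the latter is how the package reproduces a published
ACE-R group comparison (t = 5.5) without any raw data.

## Problem sizes and determinism

The Monte-Carlo suites use the study-scale design throughout (42 subjects,
8,000 voxels, 78 connections): 50 replicates for recovery rates, 200 for
null calibration, with permutation counts inside replicate loops reduced to
500–2,000 (p-value resolution well below the 0.05 decision threshold);
reported single-run analyses use the full 10,000/5,000-permutation,
1,000-repetition defaults. Every stage seeds its own generator from the
master seed via stable hashing; identical configuration and seed reproduce
identical output files digest-for-digest, which the determinism test
asserts end to end (uncompressed NIfTI avoids gzip timestamp
nondeterminism).

## Limitations

- The generator models neither PET kinetics, scanner noise, temporal
  autocorrelation, hemodynamic response, nor motion beyond a scalar
  covariate; passing recovery tests demonstrate the *statistical chain* is
  correct and calibrated, not that it would survive arbitrary real-data
  artifacts.
- Planted effect sizes (coupling, GM association, noise SDs) are
  calibration choices that make recovery feasible at n = 42; they are not
  estimates of any published cohort's unpublished moments.
- Spatial ICA assumes linear mixing of spatially independent sources;
  Gaussian blobs satisfy it by construction, so source recovery rates say
  nothing about ICA's behavior under model violation.
- The selection rule returns exactly one component by design and refuses
  otherwise; analyses of cohorts with genuinely multiple group-differing
  inflammation patterns need the ambiguity error handled upstream.
- Robust-regression permutation tests shuffle raw labels, which assumes
  exchangeability under the null; covariate-dependent heteroscedasticity
  would require a residual-permutation scheme not implemented here.
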