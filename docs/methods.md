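# Methods

## Overview

`hipshape` implements a statistical shape analysis of 2D right-proximal-femur
outlines and its downstream fracture-risk models. The pipeline is the
model-building half of classical active shape modelling (ASM): ordered
landmark outlines are superimposed by generalized Procrustes analysis (GPA),
the aligned coordinates are decomposed by PCA into orthonormal "modes of
variation", each subject is scored on each mode in SD units, and the scores
enter adjusted logistic regression models whose discrimination is summarized
by in-sample AUROC. Because the radiographic cohort this analysis style was
developed on is not publicly available, the package ships a synthetic-cohort
generator with fully known ("planted") structure; every claim the test suite
and acceptance script make is a property or parameter-recovery statement on
that generator, not a reproduction of clinical results.

## Shape model

**Data contract.** An outline is k = 60 ordered (x, y) landmarks in mm,
traced from the lesser trochanter up the inferior femoral neck, around the
femoral head, back along the superior neck, over the greater trochanter and
down the lateral shaft to the point opposite the start. Coordinates follow
the mathematical convention (y up); image-origin files can be flipped on
import. Pixel-space files are converted with a pixel-spacing scalar
(25.4/dpi mm; 0.169 mm at 150 dpi). Outlines whose trochanters were not
fully visualized carry an `acceptable = False` flag and are dropped by the
cohort filter before alignment.

**GPA.** Each shape is centred and scaled to unit centroid size, rotated
onto the evolving mean by the proper (det +1) Kabsch rotation — reflections
are forbidden because all outlines are right hips — and the mean is
recomputed and renormalized until its RMS change falls below `tol = 1e-8`
(`max_iter = 100`; non-convergence warns and flags rather than failing).
Similarity alignment (scale removed) is used: the analysis is of *relative*
shape, and absolute size survives separately in the stored centroid sizes
and in the geometry module, which only ever operates on raw mm landmarks.
Tangent-space projection at the mean is applied by default before PCA
(toggleable), and the arbitrary global rotation of a GPA solution is fixed
by rotating the converged configuration onto the first input shape, making
output reproducible while leaving all rotation-invariant quantities
unchanged.

**PCA point-distribution model.** The covariance of the aligned coordinate
vectors (divisor n − 1) is eigen-decomposed; modes are sorted by descending
eigenvalue with a deterministic sign convention (each mode's
largest-magnitude coefficient is made positive) and stable handling of tied
eigenvalues. The default retains m = 10 modes; an alternative retention
rule keeps the smallest m reaching a variance target (e.g. 0.95). A
subject's raw coefficient on mode j is b_j = φ_jᵀ(x − x̄) and its SD-unit
score is s_j = b_j / √λ_j, so training-cohort score columns have mean 0 and
SD 1 exactly. Reconstruction is x̄ + Σ s_j √λ_j φ_j; mode galleries render
reconstructions at ±2 SD of one mode.

A fitted PCA basis is identified only up to mode permutation and sign.
Wherever estimated modes must be compared with planted ones (recovery
tests, the acceptance script, the worked analysis), the match is resolved
by greedy best-|correlation| assignment between estimated and true score
columns; this uses the truth ledger solely to *name* modes, never to alter
estimates.

## Geometric measures

The comparator predictors are computed directly from the 60 landmarks with
documented operational definitions (the original measurement protocol is
not reproducible from landmarks alone, so these are the package's own
constructions):

* **head diameter** — twice the radius of an algebraic (Kåsa) least-squares
  circle fitted to the articular-surface landmarks; the RMS radial residual
  is reported as a fit-quality diagnostic;
* **neck axis** — the line through the head-circle centre and the midpoint
  of the intertrochanteric line (greater- to lesser-trochanter landmarks);
* **neck width** — the minimal separation of the superior and inferior neck
  border chains along cuts perpendicular to the neck axis (dense-grid
  minimization over interpolated chain offsets);
* **neck length** — the distance from the head-circle centre along the neck
  axis to its intersection with the intertrochanteric line.

Which landmark indices form the head, neck-border and trochanter regions is
configuration (`GeometryConfig`), defaulted to the synthetic template's
point semantics. All measures are rigid-invariant and scale with the
outline (degree-1 homogeneous), verified by property tests.

## Risk models

Logistic fracture models are maximum-likelihood fits (Newton/IRLS via
statsmodels). "Adjusted for age and BMI" means the adjustment covariates
enter the model whose fitted probabilities feed the ROC — the only reading
under which single-predictor models have distinct AUROCs per adjustment
set. AUROC is the Mann–Whitney probability that a random case outranks a
random control (ties ½); its 95% CI uses the DeLong structural-components
variance with a seeded stratified bootstrap (2000 reps) as fallback when
that variance degenerates. Pseudo-R² is McFadden's 1 − ℓ_model/ℓ_null.
AUROCs are in-sample (no cross-validation), matching the analysis style
this package reimplements. Perfect separation raises an explicit error
advising the optional ridge fit (λ = 1e-4); penalization is never applied
silently, because it would distort odds ratios. The orchestration pipeline
is the one caller that opts into the ridge fallback (and marks affected
cells), so that very small demonstration runs — where the 13-parameter
mode model cannot have a finite MLE — still complete.

Site-specific analyses compare femoral-neck-only or intertrochanteric-only
cases against all controls, excluding cases of unclassifiable site.
T-score strata partition the line as normal T > −1, osteopenic
−2.5 ≤ T ≤ −1 (both boundaries), osteoporotic T < −2.5; strata where a
model cannot be estimated are reported as such rather than failing.
T-scores are taken as input data; converting BMD to T-scores inside the
risk module would require a reference population mean/SD, which the module
deliberately does not invent.

**Permutation null check.** Case/control labels are reassigned at ratio r
controls per case with exactly floor(n/(1+r)) cases (at n = 399, r = 1.38:
167/232), and the adjusted 10-mode model refitted. The original analysis
drew a single relabeling per ratio; this implementation generalizes to
many replicates (default 200) because one draw cannot support a
quantitative "no association" conclusion. The summary reports, per mode
and ratio, the fraction of replicates significant at α = 0.05 and whether
it lies within the binomial 99% band around α; unconverged replicates are
counted and excluded.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed once:

* **Template** (mm): head radius 24, neck length 50, neck width 31, shaft
  width 30, neck-shaft angle 130°, trochanter landmarks 24 mm either side
  of the neck-axis origin along a 40° intertrochanteric line. The
  trochanters sit symmetrically about the axis origin and the mid-neck
  borders run parallel to the axis, so the geometry module recovers the
  length/width/diameter parameters exactly on the noiseless template —
  making the geometry code testable against closed-form truth.
* **Modes**: an orthonormal 10-column basis of smooth low-frequency
  deformation fields. The designated mode-4 analog is the normalized
  difference between a template with a 10% longer neck, 12% smaller head
  and 8% narrower neck/shaft and the mean template, reproducing the
  reported "long neck / small head / narrow neck" fracture-risk shape
  axis; rigid-motion and scale directions are projected out of every mode
  so the planted variation lives where Procrustes alignment cannot remove
  it.
* **Spectrum**: λ_j = 36 · 0.6^(j−1) mm² with isotropic landmark noise
  σ = 0.15 mm (well below √λ₁₀ ≈ 0.6 mm), chosen so ten modes capture
  ≥ 95% of total variance by design (realized ≈ 97%).
* **Nuisance transforms**: per-subject rotation ±15°, scale 0.9–1.1,
  translation ±20 mm — the digitization variation GPA must remove.
* **Outcomes**: fracture ~ Bernoulli(logistic(α + Σ γ_j s_j)) on the true
  SD-unit scores, with per-SD odds ratios 2.48 (mode 4), 1.32 (mode 5),
  0.56 / 0.78 / 0.66 (modes 6/8/10) and zeros elsewhere; α is calibrated
  by bisection to a target case fraction of 168/399. Case sites are drawn
  femoral neck : intertrochanteric : other = 86 : 75 : 7.
* **Covariates** are drawn conditionally on realized case status with the
  baseline-table group means (age 71.7/70.6 y, BMI 25.5/26.6 kg/m²,
  femoral-neck BMD 0.60/0.65 g/cm², total-hip 0.70/0.76,
  intertrochanteric 0.82/0.88) and *pooled* within-group SDs. Equal group
  SDs are deliberate: if X | Y is Gaussian with equal covariance across
  outcomes, the implied conditional model P(Y | s, X) is exactly logistic
  with the mode coefficients γ unchanged, so fitting the adjusted model
  recovers the planted odds ratios without bias. The printed
  intertrochanteric spread of ±0.01 is SEM-scale, not a plausible SD; the
  generator uses 0.12, comparable to the other BMD SDs. Covariates are
  mutually independent given outcome, and mode–BMD correlation is zero —
  the simplest structure consistent with a group-means table;
  consequences: the synthetic AUROCs are not calibrated to any clinical
  value, and adjustment covariates carry outcome information only through
  their group-mean shifts.
* **T-scores** are (BMD − 0.85)/0.12 against a fixed young-adult-style
  reference, chosen so the three diagnostic strata all have realistic
  occupancy.
* **Randomness**: one master seed feeds named child streams
  (basis/scores/noise/transforms/covariates) via `SeedSequence.spawn`;
  outputs record a config hash.

The truth ledger (true scores, basis, eigenvalues, planted log-odds,
template geometry, calibrated intercept) is serialized with every cohort,
and recovery tests consume only that file.

**What the generator does not emulate:** pixel data and its artifacts,
digitization error structure beyond isotropic landmark noise, correlated
covariates, mode–BMD correlation, left hips, and any attempt to match the
real shape distribution beyond the planted low-rank structure. Passing
tests therefore demonstrate the *machinery* — alignment invariances,
standardization identities, unbiased planted-parameter recovery, correct
null behavior — not clinical performance on radiographs.

## Problem sizes and numerical choices

The default analyses run at the study scale (n = 399, k = 60); the
parameter-recovery check uses n = 5000 so the 5%-relative-error criterion
on the mode-4 odds ratio is inside sampling precision, and the permutation
summary uses 200 replicates per ratio. GPA tolerance 1e-8 (converges in a
handful of iterations at k = 60); logistic convergence 1e-10 on the
log-likelihood; report rounding is half-up at the precision each quantity
is conventionally printed (percentages 1 dp, ratios 2 dp, mm 3 dp,
stratum percentages whole numbers). Degenerate inputs (all-coincident
landmarks, collinear circle points, single-class outcomes, constant or
collinear predictors, zero-variance modes) raise structured errors naming
the offender.

## Known limitations

* In-sample AUROC is optimistic for models with many predictors; a
  cross-validated variant is out of scope by design.
* The DeLong CI is a normal approximation; near-perfect separation it
  degrades and the bootstrap fallback engages.
* The mode-4 analog's geometric interpretation (longer neck, smaller
  head, narrower neck) holds for the planted basis; after PCA estimation
  the direction is recovered up to sign and the small mixing that finite
  samples induce between neighbouring modes.
* Landmark semantics (which indices are head/neck/trochanter) must be
  supplied for real digitization protocols; defaults describe only the
  synthetic template.
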