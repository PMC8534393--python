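# Methods

## Model and procedure

A voxel in non-contrast CT is classified as thrombus iff its HU exceeds a
patient-specific threshold. The threshold is estimated in two ways:

* **ROC scan.** Given labeled samples (36 thrombus, 36 contralateral-vessel
  and 100 parenchyma voxels; the last two pooled as non-thrombus), the scan
  evaluates sensitivity and specificity at every integer t in a grid
  (default 0–100 HU) with the rule *thrombus iff HU ≥ t* and picks
  T\* = argmax J(t), J = sens + spec − 1 (Youden). When several integers
  attain the maximum, T\* is the midpoint of the longest contiguous optimal
  run, rounded toward the lower integer — this centres the cut in the
  separating gap instead of hugging either class. If all pooled samples are
  identical the classes are inseparable and the scan refuses. Integer-grid
  scanning makes the estimator shift-equivariant: adding c HU to all
  samples moves T\* by exactly c.
* **Linear prediction.** In routine use T\* is predicted from one tissue
  measurement by the cohort regressions
  T\* = 0.45·(artery HU) + 31 or T\* = 0.62·(parenchyma HU) + 30.0.
  Predictions are kept at full precision in all statistics and rounded to
  the nearest integer HU only when they feed volume growing, because CT
  data are effectively integer-valued while the regressions are continuous.

Segmentation is: crop to a user-drawn bounding box around the hyperdense
sign → Perona–Malik smoothing → region growing from user seeds, keeping
voxels connected to a seed through the HU band [lower, upper]. `fixed45`
mode uses lower = 45 HU; `patient_specific` predicts it from the mean of a
raw (unsmoothed) 10×10 parenchyma ROI. Model fitting (slope, intercept,
R², F, AIC/BIC) is ordinary least squares; pairwise cohort associations use
Pearson's r when both margins pass a Shapiro screen at α = 0.05, else
Spearman's ρ (constant columns are reported as undefined).

## Key parameters

| Parameter | Default | Why |
|---|---|---|
| ROC grid | 0–100 HU, step 1 | brain tissue and clot live well inside; integer steps match CT quantization |
| Upper growing threshold | 100 HU | excludes calcium-density voxels; can be disabled |
| Connectivity | 26-neighbourhood | clots are thin oblique tubes; 6-connectivity fragments them |
| Smoothing | 5 iterations, dt 0.0625, conductance 3 HU | conservative denoising; 3 HU ≈ the noise scale, so noise diffuses while ≥10 HU tissue edges pass almost no flux |
| Registration | Mattes MI, 32 bins, 10% seeded sampling, 3-level pyramid, line-search gradient descent | the standard multi-resolution MI recipe; line search copes with the flat MI valley along a vessel axis where fixed-step descent stalls |
| Resampling background | −1024 HU | air, the CT floor |

The smoothing operates in index space (unit voxel steps) with conductance
in HU; the explicit scheme with dt ≤ 1/(2·ndim) makes each update a convex
combination of neighbours, so the maximum principle holds exactly and
0 iterations is the identity.

## The phantom generator

Each synthetic subject is a 128×128×64 volume at 0.625 mm isotropic spacing
(the thin-slice regime): uniform parenchyma (34 HU), two mirrored straight
arterial tubes of 1.5 mm radius running along x (44 HU), a 12 mm clot
segment in one tube (55 HU on NCCT; on CTA a contrast filling defect at
parenchyma level while patent lumen carries +150 HU), three CSF-density
(8 HU) ventricle-like ellipsoids, and additive Gaussian noise (default
3 HU). Geometry is evaluated analytically in physical coordinates, so the
CTA can be generated under a rigid offset with no interpolation error and
the truth mask is exact: with zero noise every truth voxel equals the clot
HU exactly. The defaults sit where the clinical data lived: parenchyma
34 HU predicts a threshold of ≈51 HU via the parenchyma model, the cohort
median, and artery 44 HU gives ≈51 via the artery model. Optional slice
averaging (`degrade_slices`) emulates thick-slice partial-volume blending
along z only.

Design choices worth noting:

* **Straight tubes.** Real M1 segments curve; straight cylinders keep
  analytic volume/length oracles available. An arc would change nothing in
  the thresholding statistics.
* **Ventricle ellipsoids.** Two parallel straight tubes constrain neither
  translation along the tube axis nor rotation about it, so rigid
  registration on a tubes-only phantom is ill-posed. Three asymmetric
  CSF-density ellipsoids (placed clear of both tubes and the default
  parenchyma ROI) anchor all six degrees of freedom, standing in for real
  anatomy.
* **Cohort tables.** `generate_cohort` draws parenchyma ~ N(34, 3²) and
  artery ~ N(44, 4²) and generates the optimal-threshold column from the
  published linear predictor plus N(0, noise²); hematocrit is coupled to
  the artery deviate at population correlation 0.43. With zero noise an OLS
  refit returns the generating coefficients to numerical precision.
* **Elevated-parenchyma cohorts.** `sample_phantom_params` shifts artery
  and clot HU jointly with parenchyma (+10 and +21 HU, the default
  contrasts) — a hematocrit-like global density shift. This is the regime
  where the fixed 45 HU threshold floods parenchyma (parenchyma > 45)
  while the predicted threshold (≈59 HU at parenchyma 46) stays above it;
  it requires the clot to ride up with parenchyma, which the joint shift
  guarantees.
* **Randomness.** One integer seed is split through counter-based
  `SeedSequence` spawn keys, so each stream (NCCT noise, CTA noise, every
  cohort column) is independently reproducible.

What the phantoms deliberately omit: skull and beam hardening,
calcifications, curved vessels, texture inside tissue classes, and
partial-volume blending except along z. Passing phantom tests therefore
demonstrates the correctness of the algorithms under their stated model,
not clinical performance on real scans — in particular the published
regression coefficients are treated as ground truth of the simulator, not
re-derived from images.

## Evaluation conventions

Correspondence between a 3D model and the reference is the coverage
fraction f = |model ∩ reference| / |reference| mapped to the 0–4 ordinal
scale: empty intersection → 0, f < 0.5 → 1, then closed-left intervals
[0.5, 0.75) → 2, [0.75, 0.9) → 3, [0.9, 1] → 4. The empty-intersection
rule for grade 0 and the closed-left endpoints are declared conventions.
Dice of two empty masks is defined as 1.0 (flagged with a warning).
Per-subject mode preference is the higher Dice, with |ΔDice| < 0.01
declared "equal". Clot length is the span of voxel-centre projections onto
the principal axis, so it understates the true extent by up to one voxel
(and a single voxel reports 0 mm); the two-point case equals the
centre-to-centre distance exactly.

## Numerical and degenerate-input choices

* Surface meshing upsamples the binary mask 2× per axis before marching
  cubes at iso-level 0.5: marching cubes applied directly to single grid
  samples encloses an octahedron of only ~1/6 voxel volume, whereas after
  upsampling the enclosed volume is within ~20% of the voxel volume for a
  single voxel and within a few percent for solid shapes.
* Volumes store HU as float64 regardless of file dtype; masks are written
  as uint8, volumes as float32.
* Region growing is implemented by connected-component labelling of the
  thresholded band restricted to the box, keeping components containing a
  valid seed — equivalent to breadth-first flood fill (property-tested
  against an independent dilation-fixpoint oracle) and independent of seed
  order. Seeds whose own HU is outside the band are logged and ignored; if
  none survives the result is an empty mask plus a warning, not an error.
* Registration results are extracted by numerically probing the optimized
  transform at basis points (convention-proof against Euler-angle-order
  mismatches between toolkits) and re-expressed about the fixed-image
  centre.

## Problem sizes

The test and acceptance workloads use 200 replicates of 70-subject cohorts
for regression recovery, 1000 random sample sets for the ROC oracle check,
500 random 20³ volumes for the region-growing oracle check, a 40-phantom
elevated-parenchyma cohort, and 3 registration recovery cases at
128×128×64. These sizes give Monte-Carlo error comfortably below the
asserted tolerances (e.g. ±0.05 on a replicate-mean slope whose SE is
≈0.003).

## Known limitations

* The correlation structure of real cohorts (age, slice thickness) is
  modelled only minimally; those columns exist to exercise the reporting
  machinery, not to mimic epidemiology.
* Mutual-information registration is validated on phantoms with identical
  grids and moderate offsets (≤5 mm / 5°); large initial misalignments may
  need a coarser pyramid or an explicit initialization.
* The 0–4 grading operationalizes an expert visual judgement as voxel
  coverage; agreement with human consensus reading is outside what desk
  experiments can show.
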