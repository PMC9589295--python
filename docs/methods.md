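# Methods

This note documents the models behind `sctqa`, the parameters that matter,
and the numerical choices made where the design was genuinely open. It
states no empirical claim that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Synthetic pelvic cohort

The phantom stands in for a clinical prostate cohort. Anatomy is analytic
on a regular grid (default 96×96×48 at 2 mm; the test and acceptance runs
use 64×64×32 at 3 mm to keep runtimes in minutes): an elliptical body
cylinder, a pelvic bone ring (elliptical shell) with a dense cortical layer
(≥ 3.5 mm or one voxel, whichever is larger) around a spongy core, bladder
and prostate ellipsoids, two seminal-vesicle ellipsoids fused to the
prostate (CTV1 = prostate ∪ vesicles; CTV2 = prostate), and a gently curved
rectum tube with an interior air pocket.

CT values are drawn i.i.d. per tissue class: soft 35 ± 30 HU, cortical
900 ± 150, spongy 250 ± 180, bladder content 5 ± 12, prostate 40 ± 25,
rectal air −750 ± 60, background −1000 HU. The resulting bone compartment
is strongly heterogeneous (bright thin shell around a darker core), which
is what makes the bulk-density method's single bone value fail most in
bone. The MRI-like channel uses a *different* monotone map (bone dark,
bladder bright, soft intermediate), multiplied by a smooth random bias
field (±15%, 60 mm correlation) plus noise — only the relative contrast
matters, and it is deliberately not CT-like.

Inter-patient variability combines per-organ lognormal volume scales
(CV 0.15; bladder 0.35, since bladder filling dominates real variability),
3 mm positional jitter, and a smooth random warp of the whole body (2.5 mm
RMS, 30 mm correlation) whose analytic field is kept as registration ground
truth. These defaults are the "moderate variation" regime: initial organ
Dice between patients of roughly 0.3–0.8, which the registration must
recover. Organs that collide with the bones or the body boundary at a drawn
jitter are redrawn (≤ 10 attempts). With all variation coefficients zero
the generator intentionally returns bit-identical patients (texture
included), so degenerate-cohort determinism is testable.

Smooth random fields (warp, bias, learned-like errors) are white noise
smoothed with a *circular* Gaussian filter and divided by the circular
kernel's ℓ2 norm, making the field exactly stationary with unit pointwise
variance; per-tissue amplitudes are therefore pointwise SDs. The
learned-like sCT is CT + such a field scaled per tissue (defaults: soft
15 HU, bone 60 HU, air 40 HU, 12 mm correlation) — a stand-in, built here,
for the residual-error structure of a trained generator: small smooth
errors, largest in bone.

What the phantom does *not* emulate: MR physics (no sequence model, no
susceptibility/geometric distortion), Hounsfield calibration subtleties,
pathology, weight change between scans, or delineation error. Passing tests
therefore demonstrate the *pipeline's* correctness and sensitivity under
controlled conditions, not clinical performance of any sCT method.

## Bulk-density sCT

Water-equivalent soft tissue (0 HU), bones 350 HU, rectal air −450 HU —
the latter two being cohort-mean values in the clinical setting. Rectal air
is thresholded on the MRI inside the rectum contour at 0.3 × the
body-median MRI intensity; the source workflow gives no number, so this
default was chosen once as robust on the phantom (air is ~8× darker than
soft tissue there) and is exposed in the configuration. Precedence on
overlapping masks is air > bone > soft; outside the body −1000 HU.

## Dose surrogate

A deliberately simple, deterministic engine — not a TPS: n equally spaced
coplanar parallel beams aimed at the CTV2 centroid; per voxel,
`aperture × exp(−μ · ∫ρₑ dl)` with μ = 0.005 mm⁻¹ per unit relative
electron density and ρₑ(HU) piecewise linear through (−1000, 0), (0, 1),
(1000, 1.6). The depth integral is a midpoint cumulative sum along the
beam axis after rotating the ρₑ volume (order-1 interpolation, which
preserves monotonicity: raising HU anywhere never increases dose
downstream). The aperture is a smooth box (erf penumbra, σ = 5 mm) shaped
to the target projection + 6 mm margin. Two plans are calibrated **once on
the reference CT**: the plan-1 weight sets the CTV1 median to 50 Gy, and
the boost weight is solved (Brent) so the CTV2 median *total* is 78 Gy;
the same weights and apertures are reused verbatim for every sCT, so HU
errors propagate into dose errors exactly as in clinical recomputation.
The single-beam homogeneous case reduces to the closed form
exp(−μρ(i+½)Δx), which the tests check to 1e-6 relative.

## Native-space error metrics

E = reference − prediction (positive = sCT underestimates), AE = |E|,
APE = |E/reference|. APE is undefined where |reference| < ε (ε = 1 HU /
0.01 Gy) because HU crosses zero in soft tissue; MAPE averages only valid
voxels and reports the count used. With a 0 HU bulk soft tissue, APE is
exactly 1 wherever the reference is nonzero — a known artifact of the
metric that the tests pin down.

## Organ-driven registration

Per organ a scalar field in [0,1]: outside, 0.5 + 0.5·clip(d/20 mm) of the
signed Euclidean distance d; inside, half the Laplace field for the rectum
(sink = slice-wise centroid chain along z, i.e. the central path) and the
prostate (sink = barycenter voxel), or the mirrored distance ramp
otherwise. Laplace fields solve the discrete Dirichlet problem (surface 1,
sink 0) exactly with a sparse direct solve — same harmonic solution as the
usual Jacobi sweep, without an iteration tolerance. The *global* organ
description assigns each organ a band amplitude (body 0.2, bones 0.4,
rectum 0.6, prostate 0.8, bladder 1.0) times a localized bump (1 inside,
fading over 20 mm), combined by maximum: each organ's vicinity keeps a
distinct level and the field is flat far from structure, which keeps the
global Demons stage from chasing structure that is not there. An
MRI-blended merged description `(1−w)·MRI_norm + w·organSD` is also built
(w configurable); with the phantom's bias field the mean-squared Demons
metric degrades monotonically as MRI weight grows, so the registration
stages drive on the organ component.

Template = patient minimising Σ_organ |v − median(v)|/median(v) over
bladder, rectum, prostate (ties → lowest id). Pipeline per case:

1. translation (body centre-of-mass + ±5 mm MSD search, zero-centred grid);
2. coarse b-spline prealignment on the bladder channel (control spacing 16
   voxels, mean squares, L-BFGS-B);
3. diffeomorphic Demons stages in the order bladder → whole pelvis →
   prostate → rectum → bones, iteration counts per resolution level
   (300,300,200,20), (200,200,100,0), (200,200,150,5), (100,100,100,5),
   (100,100,150,50), Gaussian regularization σ = 1 voxel.

Numerical choices that proved essential at this grid size:

* **Pyramid**: shrink factors 4/2/1/1. An 8× level of a 64³ grid is 8×8×4
  voxels and cannot resolve any organ.
* **Increment composition**: each stage warps the moving image by the
  current field and estimates an increment from zero, composed at full
  resolution. Resampling the accumulated field through coarse pyramid
  levels erases what earlier stages aligned.
* **Regularization flavour**: the global whole-pelvis stage smooths the
  accumulated deformation field (elastic-like; fluid smoothing there
  drifts without bound in flat regions), while the local organ stages
  smooth the per-iteration update (fluid-like; elastic smoothing caps
  their accuracy well below what the small organs need).
* **Locality and protection**: a per-organ stage only sees its own
  channel, so its increment is confined to the organ's vicinity (25 mm
  falloff; bones 12.5 mm), and organs already aligned are frozen for later
  stages — interiors only against the fine organ stages, a solid 3 mm halo
  against the broad whole-pelvis and bones stages, which otherwise dilate
  the small organs they border. Without this, each stage undoes its
  predecessors, since the stated stage inputs give no view of other organs.
* **Metric warps** replicate edge values; a constant background fill
  fabricates border gradients that fluid Demons chases.
* **Mask warping** interpolates the indicator linearly and re-thresholds
  at 0.5 — binarity-preserving like nearest-neighbour sampling but without
  its systematic boundary dilation.

Validation per case: Dice of every warped gate organ (body, bones,
bladder, rectum, prostate) against the template, pass iff strictly > 0.85;
Dice of two empty masks is defined as 1 (vacuous agreement). Jacobian
determinants of (id + u) are computed by central differences;
diffeomorphic intent is monitored as the fraction > 0. Self-registration
is an exact fixed point: every stage sees identical images and returns a
zero field.

Bone refinement: bones are split cortical/spongy by Otsu on a lightly
smoothed CT (σ = 0.5 voxel; raw voxel noise speckles the partition, and
heavier smoothing erases the one-voxel shell at 3 mm), each sub-mask's
distance channel is registered with a short elastic Demons schedule
(50,50,30,10), and the refined field is applied to sCT, dose and error
maps only — the quality gate keeps the unrefined field. On this phantom
the refinement improves spongy alignment while costing a little whole-bone
Dice (the shell is one voxel thin), so "refinement never hurts" is
asserted only as: spongy not degraded, bones stay above the gate.
Near-uniform bone HU skips refinement.

All volumes are propagated from native space with exactly one resample
through the fully composed field.

## Population statistics

vMAE/vME/vMAPE average the per-voxel error across patients inside the
template body contour; RSD_AE = sqrt(mean_j (AE − vMAE)²)/vMAE is the
coefficient of variation of the absolute error, left undefined (NaN) where
vMAE < ε. The paired permutation test studentizes D_j = ref_j − pred_j per
voxel, T = mean(D)/(sd(D)/√p) with the sample (p−1) sd, and simulates the
null by n random sign-flip vectors (pair swap ≡ negating D_j), identical
across voxels (marginal p-values are unaffected and the flips are drawn
once from the seed). Two-sided p = (1 + #{|T*| ≥ |T|})/(n+1) — the add-one
estimator, so p ≥ 1/(n+1) > 0. Degenerate voxels: all D_j = 0 gives p = 1
(no evidence); all D_j equal and nonzero gives |T| = ∞, matched only by
constant-sign flip vectors, so the p-value floor ≈ 2^(1−p) emerges from
the exact flip count. ESR = {p < α} (strict), α = 0.05, no correction
beyond the permutation scheme itself; an FDR step is deliberately not
applied by default, matching the source workflow.

Calibration conditions (also used by the acceptance script): 26 patients,
i.i.d. N(0,1) differences on a 20×20×5 grid, 2000 permutations — the
rejection rate at α = 0.05 must sit in 0.05 ± 0.01 and the p-values must
be (super-)uniform; a 3 SD shift must reject > 99% of voxels.

## Dose QA

* **MADE-VH**: cumulative histogram of the dose vMAE over an ROI
  (bin 0.05 Gy); V(t) accessors count exactly rather than reading bins.
  The pelvis ROI is the body cropped to 2 cm above/below the rectum along
  z; organ ROIs are not cropped.
* **DVH criteria**: Dx% = (100−x)th percentile with linear interpolation
  between order statistics; differences are absolute.
* **3D gamma**: γ(i) = min over displacements r within 3×DTA of
  sqrt((ΔD/δ)² + |r|²/DTA²), δ local (percent of the reference voxel dose)
  or global (percent of max); search sampled at spacing/3 with trilinear
  interpolation, ordered by |r| with early pruning (voxels whose current γ
  already beats the distance term are skipped — exact, not approximate).
  Voxels below 10% of the reference maximum are not evaluated; pass is
  γ ≤ 1 (the measure-zero γ = 1 boundary is counted as pass). Values are
  upper bounds beyond the 3×DTA search radius, as is standard. Defaults
  local/1%/1 mm/10%, computed on the mean CCS doses.

## Problem sizes

Unit tests run on 48×48×24 at 4 mm; the registration, convergence and
discrimination checks on a 10-patient 64×64×32 cohort at 3 mm (about five
minutes end to end); the permutation calibration on 2000 voxels × 26
patients × 2000 permutations. These sizes were chosen so a full validation
cycle stays in the minutes range on a single CPU while every organ still
spans several voxels.

## Known limitations

* The dose engine has no scatter, no heterogeneity kernels and arbitrary
  absolute units fixed only by the calibration constraint; only *relative*
  dose-error behaviour is meaningful.
* At 3 mm the cortical shell is one voxel thin; partition-based bone
  refinement is noise-limited there.
* The permutation test's spatially shared flip matrix preserves marginal
  p-values but not the joint null across voxels; any analysis of ESR
  *shapes* under the null should redraw flips per realisation.
* Registration accuracy statements hold for the phantom's smooth analytic
  anatomy; clinical images with sliding interfaces or delineation noise
  are harder.
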