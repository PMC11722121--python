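# Methods

## Scope and model

The package reproduces the computation behind a two-group clinical study
design: per-eye vascular morphometry from averaged en face OCTA of the
macula, and inference on a 48-eye / 33-patient cohort labelled for
peripheral retinal non-perfusion (PNP present/absent), with eyes nested in
patients. Everything runs on synthetic data with exact ground truth; no
patient data are included or required.

## Image chain

**Quality gate.** A frame enters the stack if its signal strength index
exceeds 50 or its scan quality score exceeds 8 (strict inequalities). A
frame carrying neither score is an error, not a silent pass.

**Inhomogeneity correction.** The image is divided by a Gaussian-smoothed
background estimate (σ = `kernel_mm`, default 0.5 mm) and rescaled to
preserve the global mean. Division by a content-dependent background can
only recover the uncorrupted image up to one global gain, and leaks where
local structure varies at the kernel scale (e.g. across the FAZ); the test
of bias-field recovery therefore matches a free scalar gain.

**Registration.** Stages run in the fixed order translation → affine →
elastic; the dissimilarity score is the negative normalized
cross-correlation (NCC), and a stage estimate is kept only if it does not
worsen the score. Translation comes from upsampled phase correlation
(1/20 px grid); the affine stage is a Powell search over rotation,
log-scales, shear and translation; the elastic stage is a coarse
(default 32 px) control-grid displacement driven by the image residual and
upsampled with cubic interpolation. Resampling composes all stages into
one interpolation pass (bilinear). A frame whose translation stage cannot
improve the score is excluded as non-overlapping. The reference frame is
the gated frame with the highest quality score, ties to the lowest index.

**Averaging.** Pixelwise mean by default; max-intensity projection is
provided because display practice differs from quantification practice.
All metrics default to the mean image.

**Segmentation.** The published chain used a CNN whose weights are not
available; a deterministic classical operator replaces it: Sato multiscale
vesselness (σ ∈ {0.8, 1.2, 1.8, 2.6} px) followed by hysteresis
thresholding at 1.0× / 1.3× the Otsu threshold of the vesselness response,
removal of components below 10 px, and filling of holes below 40 px. The
hole filling matters structurally: ridge filters respond weakly at the
center of wide bifurcations, and the resulting holes would otherwise turn
every large junction into a spurious loop that corrupts Strahler
ordering. Downstream metrics are defined on the binary mask, so any
segmenter meeting the phantom Dice ≥ 0.85 bar is interchangeable here.

**Vessel graph.** The skeleton (topology-preserving thinning) is parsed
into a multigraph: contiguous pixels with ≠2 neighbours become nodes
(endpoint/junction/border), junction-free runs become edges carrying their
centerline polyline, length and a mean calibre sampled from twice the
Euclidean distance transform. Two clean-up passes follow: contraction of
sub-6-px junction–junction edges (thinning splits one anatomical
bifurcation into a small cluster) and iterative removal of
endpoint-terminated spurs below 6 px with through-merging of the resulting
degree-2 nodes.

**Strahler ordering.** Orders are defined on trees, so each connected
component is reduced to a shortest-path spanning tree (edge weight =
centerline length); chords — capillary loops — are dropped for ordering
and assigned order 1. The automatic root is the degree-1 tip whose
incident edge is widest, ties broken toward the image border: a vessel
tree is entered where its trunk meets the field of view. Leaves get order
1; a parent whose children attain maximal order k gets k + 1 if at least
two children attain k, else k; an edge inherits the order of its
child-side node. Edges of order 2–4 are classified arteriole/venule (AV),
everything else capillary; arterioles are not distinguished from venules.
A user-supplied AV mask can replace the order band, mirroring the
interactive delineation used clinically; the recovery experiments use the
generating AV mask for exactly that reason.

**Metrics.** Perfusion density = vessel pixels / field pixels and vessel
density = skeleton pixels / field pixels, both after removing AV pixels
from numerator *and* denominator (so PD is the capillary coverage of the
non-AV field; a numerator-only convention is a config switch, since the
published wording does not fix it). Mean calibre = mean over skeleton
pixels of (2·EDT − 1) px (pixel centers sit half a pixel inside the region
edge) times the pixel size. Fractal dimension = least-squares slope of
log N(s) vs log(1/s) over dyadic boxes s ∈ {2…64} px. Tortuosity method 1
is the arc-chord ratio of the sub-pixel polyline, arc length by summed
Euclidean steps. Method 2 is a composite index
`0.1 · sd(θ) · N · M · (L_arc/L_chord)` on the arc-length-resampled
centerline, with θ the (lightly smoothed) tangent-angle sequence, N the
number of curvature sign changes and M the mean chord-relative amplitude
between consecutive sign changes; it is 0 for straight centerlines and
grows with both amplitude and frequency of oscillation. The constants and
the exact amplitude definition are this package's reconstruction and are
flagged as such in output provenance. Per-class tortuosity is the
unweighted mean over edges at least 10 px long; closed loops are excluded
(no chord).

## FAZ morphometry

The FAZ is the 4-connected avascular component containing the fovea
(default: image center) after closing the vessel mask with a 5 px disk.
Area is the pixel count; the perimeter is the length of the
marching-squares boundary after a 7-point circular moving average (raw
marching-squares staircase overestimates smooth boundaries); eccentricity
comes from second central moments; the axis ratio is the long/short ratio
of the axis-aligned bounding box (≥ 1); the acircularity index is
`P / (2·sqrt(pi·A))` — the printed clinical values (≈1.6) exceed 1 and
match this perimeter-normalized form at the printed group means, not the
literal "area over squared perimeter" gloss; minimum/maximum FAZ distances
are Feret (rotating-caliper) diameters of the convex hull, consistent with
the printed means bracketing the equivalent circular diameter.
Magnification: `q = 0.01306 · (AL − 1.82 mm)`; the device-assumed axial
length defaults to 23.95 mm; linear metrics scale by `q_eye/q_device`,
areas by its square, dimensionless descriptors not at all, and a second
correction of the same metrics object is an error.

## Statistics chain

**Imputation** follows the iterative random-forest scheme for mixed-type
data: mean/mode initialization, per-variable forests (100 trees) swept in
increasing-missingness order, stopping when the normalized change of the
imputed values first rises for both the numeric and the categorical set
and returning the previous sweep. Identifier columns are excluded as
predictors. Deterministic for a fixed seed.

**Univariate screen.** Welch t-test for numerics (pooled-variance
optional), exact Fisher test for categoricals, at α = 10 %. The Fisher
test sums, under the fixed-margin null, the probabilities of all tables at
most as probable as the observed one; r × c tables are fully enumerated
(feasible at n = 48). Degenerate margins give p = 1. The forced-retest
list (FAZ area and both capillary tortuosity indices by default) is
re-examined by mixed models regardless of the screen.

**Mixed models.** Gaussian responses: REML linear mixed model
(statsmodels) with the group fixed effect and a patient random intercept;
Shapiro–Wilk on residuals and Levene across groups are reported, and a
square-root or power-1.05 transformation is tried when residual normality
fails. Binary responses: logistic mixed model fitted by maximum
likelihood with adaptive Gauss–Hermite quadrature (15 nodes; per-group
posterior modes by Newton, curvature-scaled nodes); the likelihood was
verified against brute-force numerical integration. Predictors are
standardized internally so optimizer bounds and steps are
scale-meaningful; estimates and covariances are transformed back.
Multinomial responses: baseline-category logits sharing one scalar random
intercept, quadrature-estimated, with the overall group effect tested by
likelihood ratio. A fit with random-intercept variance below 1e-6 is
flagged singular; complete separation is flagged, not raised. With one
binary pair per patient the ML variance estimate is weakly identified (its
null distribution has a heavy right tail), so the "reduces to plain
logistic" property is exercised with the variance constrained to the
boundary, where coefficients and standard errors coincide with ordinary
logistic regression.

**Selection.** Candidates are all features minus identifiers, manual
exclusions (PRP by default — PNP is itself an indication for PRP), and one
member of every pair with |r| > 0.9 (the member with the larger mean
absolute correlation to the rest is dropped). Candidates are ordered by
single-term likelihood contribution and added while the fit converges,
capped at n/4 terms (a logistic model with parameters approaching the row
count separates); then backward elimination removes, at each step, the
term whose deletion lowers AIC most, stopping when no deletion lowers AIC.
AIC uses the ML fits. Finally, terms without Wald significance at
α = 0.05 are discarded from the reported model — the same post-filter the
clinical analysis applied to its final model. Plain backward-AIC alone
retains a pure-noise term with probability ≈ P(χ²₁ > 2) ≈ 0.16; the
significance filter brings the null false-selection rate down to ≈ 0.05
per term. The filter is a config switch (`significance_filter=None`
restores raw AIC selection).

**LOOCV ROC.** One eye per fold by default (leave-one-patient-out is a
config option, since bilateral eyes are correlated); held-out
probabilities are population-averaged (the random intercept is integrated
out, as nothing is known about a new patient's intercept); AUC over the
held-out scores with a DeLong (midrank) confidence interval. Folds whose
training set loses a class are skipped and counted.

**Threshold stratification.** Eyes are cross-classified against normative
cut-offs: perfusion density strictly above 0.45 is "normal" (the boundary
value falls in the reduced group), FAZ area strictly below 0.3 mm² is
"preserved".

## Synthetic data

**Phantoms** emulate a 3 × 3 mm, 304 × 304 full-slab en face scan:
arteriole/venule trees grow by recursive bifurcation from the border
toward the fovea, each node owning an angular wedge split between its two
children (with a 14–22° minimum half-angle) so branches diverge; a small
child-loss probability makes topologies non-perfect, and true Strahler
orders are computed from the realized topology. A jittered triangular
capillary lattice (Delaunay links) fills the field, connects to the trees
only at their terminal tips, and a terminal capillary ring bounds the FAZ
ellipse so the avascular area equals the generating π·a·b. Tortuosity is
injected as a sinusoidal displacement normal to each segment (zero at the
ends), one half-wave for AV segments and one or two for capillaries; the
generating arc-chord ratio is stored per polyline. A collision pass
truncates any branch approaching an earlier centerline (clearance 9 px
outside a 14 px junction zone) and drops stubs shorter than ~22 px —
a few-pixel stub is not a resolvable vessel and would only blur the ground
truth. Widths grow with order (≈2.95–5.8 px); capillaries are 2.3 px.
Rasterization stamps each polyline with its width using exact
point-to-segment distances, so an independent brute-force rasterizer
reproduces the mask bit for bit. Default FAZ semi-axes (0.39, 0.29) mm
give area 0.355 mm² and eccentricity 0.67, near the middle of the reported
clinical range; the default capillary density target (0.35) puts PD in
the low-0.4s. The reference image is the mask lightly blurred (σ=0.5 px)
on a 0.1 background.

**Frame stacks** warp the reference by Normal(0, `motion_sd`) translations
(optionally small rotations), multiply by unit-mean gamma speckle and add
Gaussian noise; the true transforms are recorded.

**Cohorts** have 33 patients, 15 bilateral (48 eyes), with exactly 22
PNP-present eyes. Each variable is sampled conditionally on the group via
a shared-latent model: latent = ρ·z_patient + sqrt(1−ρ²)·z_eye with
ρ = `patient_random_sd` (default 0.6, i.e. ICC 0.36), so printed group
SDs are preserved exactly. Numerics use the printed group means/SDs;
binaries and ordinals threshold the latent at the printed prevalences
(percentages with internal inconsistencies in the printed tables are
renormalized from the printed counts). Categorical variables are
conditionally independent given group and patient — the source reports no
covariance structure to emulate. Default missingness: 1 HbA1c cell and 2
cells each for diabetes duration, LDL, HDL, past anti-VEGF and past
steroids, deleted completely at random.

What the phantoms do *not* emulate: projection artifacts, capillary
dropout patterns, flow-dependent signal, device-specific speckle spectra,
layer-segmentation errors, or the real covariance among clinical
variables. Passing recovery tests therefore demonstrates correctness of
the measurement chain on images with known geometry, not clinical-grade
segmentation performance.

## Problem sizes and numerical choices

Test simulations use: 50 stacks (128 px phantoms) for registration
recovery; 50 default-size phantoms for FAZ area; 30 phantoms with
class-specific amplitudes for tortuosity recovery; 50 seeds of 200
patients × 2 eyes for LMM variance recovery; 25 planted / 50 null cohorts
of 200 eyes for selection behaviour; 1000 null replicates at n = 48 for
screen calibration. Optimizer: L-BFGS-B with bounds (±30 standardized
coefficients, σ ∈ [1e-5, 50]), ftol 1e-10; inner Newton mode-finding to
1e-10. Ties in correlation pruning fall to the first-listed variable.
Degenerate inputs (empty masks, constant images, all-missing columns,
coincident polyline endpoints, fovea on a vessel) raise errors rather
than returning silent defaults.

## Known limitations

* The elastic registration stage is a coarse residual-driven control-grid
  model; it is guarded (never worsens NCC) but not a full B-spline
  optimization, and pure-translation/affine stacks do not exercise it
  deeply.
* Strahler orders depend on the automatic root when vessel trees touch in
  the projection; the root policy and the spanning-tree reduction of
  capillary loops are this package's choices, recorded in output metadata.
* Tortuosity method 2's constants follow the cited composite-index
  construction, not a published parameter set; only its qualitative
  properties (zero for straight, monotone in amplitude and frequency) are
  contractual.
* Wald standard errors near a σ = 0 boundary condition on σ; p-values
  there are approximate.
* The cohort-level published results (specific six-variable model,
  AUC = 1.000) require the unpublished patient data and are out of reach
  by design; the statistics chain is validated by calibration and recovery
  on synthetic cohorts instead.
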