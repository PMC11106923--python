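# Methods

## Scope and model

`fourchamber` measures two clinical biometrics of the fetal four-chamber
echocardiographic plane from multi-label segmentation masks, scores
segmentations, and quantifies rater-vs-model agreement. It operates strictly
downstream of segmentation: producing the masks (by a network or by hand) is
out of scope.

The 15-label annotation covers the four chambers (LA, LV, RA, RV), the
interventricular and interatrial septa (IVS, IAS), the two ventricular walls
(LVW, RVW), both lungs, the descending aorta, the spine, ribs, and two
region outlines — Heart Area (HA) and Thorax Area (TA). Because HA/TA
spatially overlap the structural labels, a case is stored as two aligned
single-valued rasters: an *anatomy* map (13 structural labels) and an *area*
map (HA, TA), bundled under one case id.

## Cardiac axis (CAx)

Definition: the acute angle between the long axis of the interventricular
septum and the thoracic anteroposterior (AP) axis, reported in `[0, 90]`
degrees.

Pipeline:

1. IVS mask → largest 8-connected component → topological thinning to a
   1-pixel skeleton.
2. Skeleton pruning: the skeleton pixels form an 8-connected graph; two
   breadth-first sweeps find the longest geodesic path between endpoints and
   everything off that path is discarded. Without pruning, short side
   branches produced by boundary noise bias the subsequent fit.
3. Septal axis: total (orthogonal) least squares through the pruned points —
   the principal eigenvector of the coordinate covariance about the
   centroid. Orthogonal rather than ordinary regression because septa are
   frequently near-vertical in image coordinates, where ordinary regression
   is undefined and unstable.
4. AP axis: the line through the spine-mask centroid and the thorax-mask
   centroid, oriented posterior → anterior. "Center-of-mass line" admits
   more than one reading (e.g. per-row centroid traces); the two-point
   centroid line is implemented as the simplest estimator that is exact for
   bilaterally symmetric anatomy.
5. CAx = `arccos(|d_septal · d_AP|)` in degrees. A signed variant (positive
   when the apex points to the fetal left of the AP axis, from the 2-D cross
   product after orienting the septal axis anteriorly) is attached to the
   result but is not the primary output, which matches how the angle is
   reported clinically as a magnitude range.

Coordinates are rescaled to physical units (pixel spacing in mm) before any
line fit: angles are not invariant under anisotropic scaling. A warning is
recorded when the pruned skeleton has fewer than 10 points or when spacing
is anisotropic. If the dedicated TA label is absent (common in predictions),
the thorax mask falls back to the union of all foreground labels.

## Cardiothoracic ratio (CTR)

Definition: with `E_c = F(m_c)` and `E_t = F(m_t)` the ellipses fitted to
the heart and thorax masks, `CTR = A(E_c) / A(E_t)` where
`A = π·(major/2)·(minor/2)`.

Pipeline per mask: largest component → ordered outer boundary by
Moore-neighbor tracing (8-connected, pixel-exact, clockwise from the
top-left boundary pixel; every contour point is a foreground pixel
4-adjacent to background) → direct least-squares ellipse fit.

The ellipse fit is the Halir–Flusser formulation of the direct algebraic
conic fit with the ellipse constraint `4ac − b² = 1` built into the
eigenproblem — the same least-squares problem OpenCV's `fitEllipse` solves.
Points are centered and scaled to RMS radius 1 before fitting (ellipse
parameters transform simply under that similarity), which keeps the
scatter-matrix eigenproblem well conditioned; the geometric parameters are
then read off the conic via the eigen-decomposition of its quadratic-form
matrix. On noiseless points sampled from an ellipse, recovery is exact to
~1e-14 relative in all five parameters. Fits with fewer than 5 distinct
points, collinear points, or a non-elliptical solution raise a
`DegenerateGeometryError` rather than returning a bounding ellipse.

When HA/TA are annotated, those masks are used (in a single-valued area
raster the heart overwrites the thorax, so the TA region is an annulus; only
its *outer* contour is traced, which recovers the full thorax ellipse).
Fallbacks when absent: heart = union of the eight cardiac structural labels,
thorax = union of all foreground. No sub-pixel contour refinement is done:
the ellipse fit averages boundary quantization, and the phantom-grid
validation shows the residual CTR error is ≈1%.

## Segmentation metrics

Per class, Dice `2|x∩y|/(|x|+|y|)` and IoU `|X∩Y|/|X∪Y|`; mDice/mIoU are
arithmetic means over the scored classes. Conventions:

* a class empty in both maps is excluded from the means and reported absent
  (a trivially absent class, e.g. ribs out of plane, should not inflate the
  average); empty in exactly one map scores 0;
* background is never scored;
* over a test set, scores are averaged per image first (class-mean per
  image, then image-mean), the convention used by the `evaluate` command;
* scores are fractions in `[0, 1]` in the library; the CLI renders percent
  with two decimals.

The identity `IoU = Dice/(2 − Dice)` holds exactly and is used as an
internal consistency oracle in the tests.

## Agreement statistics

For n paired measurements (rater, model) of one quantity:

* **Routing.** Shapiro–Wilk on the paired differences; P > α (default
  α = 0.05) → paired t-test, P ≤ α → Wilcoxon signed-rank. Normality of the
  differences is what the t-test actually assumes; the per-series
  Shapiro–Wilk p-values are additionally reported for completeness, since
  clinical tables often gate on the series. All-zero differences make both
  tests degenerate; this is reported as P = 1 with a warning.
* **Bland–Altman.** Differences are `rater − model` (positive bias = rater
  reads higher than the model). bias = mean difference; 95% limits of
  agreement = bias ± 1.96·SD (no small-sample LoA correction); 95% CI of the
  bias = bias ± t₀.₉₇₅,ₙ₋₁·SD/√n.
* **ICC.** ICC(2,1): two-way random-effects, absolute agreement, single
  measurement, from the ANOVA mean squares
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)` with k = 2, and a
  95% CI from the F distribution with Satterthwaite degrees of freedom
  (McGraw & Wong). Absolute agreement is deliberate: the question is whether
  the automated reading can replace the rater, so a constant offset must
  lower the coefficient. ICC(3,1) (consistency) would not, and would report
  systematically higher values.

## Synthetic phantom

The phantom emulates the *geometry* that drives CAx and CTR, not ultrasound
appearance. Layout (anterior = decreasing row, all sizes in pixels at the
default 512×512):

| parameter | default | rationale |
|---|---|---|
| thorax axes (full) | 380 × 300 | fills the frame with margin, mildly oval like a transverse fetal thorax |
| heart axes | from target CTR, aspect 1.5 | aspect capped so the heart clears the posterior spine disc at any rotation |
| septum thickness | 10 | thick enough to survive thinning, thin relative to the heart |
| spine radius | 13 | posterior midline disc just inside the thorax |
| rib arcs | 6 | short boundary arcs, posterior sector kept free |
| atrial fraction | 40% of the long axis | fixes the IVS/IAS split; clinically naive but irrelevant to CAx/CTR |
| boundary jitter | 0 | Gaussian radial noise per boundary vertex when > 0 |

The heart long axis makes exactly the prescribed angle with the AP axis and
the septal band runs along it, so true CAx is exact by construction; true
CTR is the axis-product ratio `(h_M·h_m)/(t_M·t_m)`, again exact because the
area-map ellipses are the constructed ellipses. The spine is painted last
and symmetric about the midline column, so the ground-truth AP axis is
exactly vertical. Jitter perturbs boundary vertices radially with seeded
Gaussian noise and re-rasterizes the polygon, keeping regions simply
connected (salt-and-pepper noise would not).

What the phantom does **not** model: speckle, shadowing, dropout-induced
ragged mask borders, anatomical variation (chamber disproportion, abnormal
situs), and inter-structure ambiguity at boundaries. Passing the recovery
grid therefore validates the *measurement* pipeline — skeletonization, line
and ellipse fitting, the angle and area arithmetic — and not the upstream
segmentation quality on clinical images.

`degrade_prediction` produces imperfect "predictions" by per-label seeded
dilation/erosion and label dropout, for exercising the metrics; mDice is
non-increasing in the degradation radius.

## Validation problem sizes

The built-in validation (tests and `scripts/acceptance.py`) uses the 8×4
recovery grid CAx ∈ {10°,…,80°} × CTR ∈ {0.15, 0.25, 0.35, 0.45} at 512²
with zero jitter (worst-case errors observed: ≈1.1° CAx, ≈1.0% relative
CTR, against acceptance bounds of 2° and 3%); 100 random noiseless ellipses
for fit exactness; 200 random mask pairs for the metric identities; and
n = 100 / n = 10 000 synthetic paired tables for the agreement closed forms.
These sizes were chosen to bound the worst case tightly while keeping the
whole validation in seconds on one CPU.

## Numerical choices and edge cases

* Ties in largest-component selection are broken by raster order of the
  first foreground pixel (deterministic).
* Line-fit direction is canonicalized (first non-zero component positive);
  isotropic point clouds raise rather than returning an arbitrary axis.
* Ellipse rotation is reported in `[0, 180)` measured from the column axis;
  for circles the rotation is arbitrary (axis lengths still correct).
* PNG label maps carry no spacing metadata and read back as 1 mm isotropic;
  NIfTI round-trips spacing through the header. Only 2-D (or singleton
  third dimension) NIfTI volumes are accepted.
* All randomness (phantom jitter, degradations) flows from explicit integer
  seeds; repeated runs are bit-identical.

## Known limitations

* The two-point centroid AP axis assumes the spine lies on the thorax
  midline; severe spine-segmentation failure tilts the axis.
* The CTR fallback union is only as complete as the structural labels; a
  prediction missing a lung under-estimates the thorax ellipse.
* Agreement tooling handles exactly two measurement columns; multi-rater
  designs (> 2) are out of scope.
* The phantom's chamber proportions and wall thicknesses are schematic; do
  not use it to validate chamber-level segmentation realism.
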