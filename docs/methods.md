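# Methods

## Problem and model

The package evaluates how well six caliper-style formula methods estimate the
volume of a solitary intracranial tumor against planimetry (summing voxel
volumes inside a segmentation), the practical gold standard. The formulas are
ellipsoid approximations: with A the maximum in-slice length (cm), B the
maximum width perpendicular to A (cm), S the largest axial cross-section area
(cm²) and C = H the tumor height (cm, slice thickness × tumor-bearing slice
count),

    V_kABC = k·A·B·C      and      V_kSH = k·S·H,      k ∈ {1/3, 1/2, 2/3}.

For an exact ellipsoid — in any orientation — the central cross-section has
the largest area S₀, the axial extent is 2w, and V = (4/3)·S₀·w = (2/3)·S·H;
likewise A and B are the full axes of the central ellipse so
(π/6)·A·B·C = V and V_½ABC/V = 3/π ≈ 0.955. These identities are the analytic
calibration targets the test suite checks on rotated digital phantoms.

## Voxel model and conventions

A mask is a binary grid indexed (slice, row, col) with spacing (dz, dy, dx) in
mm; voxel (k, i, j) is the closed box centred at (k·dz, i·dy, j·dx). All
measurements use physical millimetres and are reported on clinical scales
(cm, cm², mL). Files whose NIfTI orientation places the superior–inferior axis
elsewhere are transposed on load; without orientation metadata the
slowest-varying axis is assumed axial and a warning is logged.

## Morphometry

* **Planimetric volume** — foreground count × voxel volume.
* **S and the reference slice** — the axial slice with the most foreground
  pixels; ties break to the lowest index so results are deterministic. S is
  pixel count × pixel area, consistent with planimetry (not a contour
  polygon).
* **A and B** — computed from pixel *centers*. A is the maximum pairwise
  distance (accelerated by reducing to convex-hull vertices, which provably
  contain the maximising pair; among equal pairs the lexicographically
  smallest index pair fixes the direction). B is the Feret width — the extent
  of center projections onto the direction perpendicular to A — which is
  rotation-stable, unlike a chord through the A midpoint. A single-pixel
  slice gives A = B = 0; the center-based underestimate is below one pixel
  (~0.45 mm at the default grid) and is accepted.
* **Height** — tumor-bearing slices only; interior empty slices (possible in
  pathological inputs) are not interpolated.
* **Maximum diameter** — largest pairwise distance between centers of surface
  voxels (foreground voxels with a face-exposed side, 6-connectivity).
  Production uses convex-hull pruning; an O(n²) scan over all surface centers
  gives bit-identical results because the extremal pair consists of hull
  vertices and the same distance arithmetic is used.
* **Connectivity** — masks must be a single 26-connected component
  (solitary-tumor inclusion rule); multi-component masks are rejected and, in
  the pipeline, logged as exclusions.

## Ellipsoidity and the MVEE

Ellipsoidity = planimetric volume / volume of the minimum-volume enclosing
ellipsoid (MVEE). The MVEE is fitted to the 8 box corners of every surface
voxel, reduced to convex-hull vertices first (the hull of all voxel corners is
the Minkowski sum of the surface-center hull with the corner offsets, so
nothing is lost). Because the ellipsoid then contains every voxel box, the
ratio is structurally ≤ 1 — the index is a true shape-regularity measure with
1 meaning perfectly ellipsoidal.

The MVEE solver is the Khachiyan first-order scheme with Wolfe–Atwood away
steps on the dual weights. Default tolerance 1e-6 on the normalised duality
gap, iteration cap 10⁵; when float64 precision stalls the gap just above
tolerance the solver accepts any solution within 10× the tolerance (the
documented contract). The returned ellipsoid is rescaled so containment of
all input points is *exact*, making derived volumes upper bounds and the
ellipsoidity bound rigorous. Rank-deficient point sets raise a degeneracy
error.

Note the corner-cloud construction has a resolution cost: it inflates the
enclosing ellipsoid by up to half a voxel diagonal. A digital sphere of
radius 20 mm at 1 mm voxels therefore measures ellipsoidity ≈ 0.89, not 1;
at 0.5 mm and radius 30 mm it reaches ≈ 0.96. Ellipsoidity values on thick
slices (dz = 4–5 mm) are systematically lower than an infinite-resolution
ideal, uniformly across shapes, so *comparisons* between shapes at a fixed
grid remain meaningful.

## Agreement statistics

Per-case error indexes: VD = v_est − v_plan (mL), PVD = 100·VD/v_plan (%),
AVD = |VD|, APVD = |PVD|. Per-method reports use:

* quartiles with the linear-interpolation (type-7) convention;
* Spearman rank correlation (average ranks for ties) with a 95% CI from the
  Fisher z-transform, SE = 1/√(n−3);
* ICC(2,1) — two-way random effects, absolute agreement, single measurement —
  from the ANOVA decomposition (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC −
  MSE)), with the standard F-based confidence bounds (Satterthwaite df). The
  absolute-agreement form penalises systematic offsets, which is the right
  question for method-vs-reference comparison;
* Bland-Altman on raw differences in mL, limits of agreement = mean ±
  1.96·SD (sample SD, n−1); points strictly outside the limits are counted;
* diagnostic accuracy: percentage of cases with APVD strictly below each
  threshold (default 10/20/30%), strictly increasing thresholds enforced;
* Mann-Whitney U, two-sided: exact enumeration of all C(n,nx) group
  assignments of the tied-rank vector when nx+ny ≤ 16, otherwise the normal
  approximation with tie and continuity corrections. The rank-based test is
  always used — synthetic and clinical volume distributions are right-skewed,
  so no normality gate is applied;
* subset analyses restrict to v_plan < threshold (strict), default 10 and
  20 mL; diameter-bin summaries use 1-cm bins [b, b+1) on the maximum
  diameter.

## Synthetic cohort

Phantoms emulate a surgical meningioma cohort's geometry:

* **volumes** lognormal with median 26.65 mL; σ = ln(51.21/11.38)/(2·0.6745)
  ≈ 1.115 reproduces the 11.38–51.21 mL interquartile range. The lognormal is
  fully determined by these two published summaries and matches the right
  skew of clinical volumes;
* **grid** (4.0, 0.449, 0.449) mm by default — a 230 mm field of view on a
  512 matrix with 4 mm slices; a 1 mm isotropic mode serves the analytic
  oracle tests;
* **shapes**: 60% rotated ellipsoids with axis ratios uniform in [0.6, 1.0]
  (the real shape mix is unpublished; these are configuration knobs, not
  claims), 40% lobulated — a parent ellipsoid united with 1–3 lobes scaled by
  0.4–0.7 whose centers are constrained inside the parent, guaranteeing a
  single connected component and lower ellipsoidity;
* **inclusion filter**: phantoms spanning ≤ 4 axial slices are redrawn from a
  fresh substream (mirroring a study-style exclusion rather than reshaping
  the distribution); each phantom draws from a counter-derived substream of
  the global seed, so cohorts are reproducible case-by-case.

What the generator does *not* model: intensity/noise, segmentation error,
partial-volume effects at the rim, anatomical placement, peritumoral
structures. Passing tests therefore demonstrate the correctness of the
measurement and statistics chain on known geometry — not the clinical
accuracy of manual segmentation itself.

## Numerical choices and problem sizes

* Max-area ties → lowest slice; equal-distance caliper pairs → smallest index
  pair; all outputs deterministic, and identical config + seed yields
  byte-identical pipeline CSVs (per-case table at 12 significant digits,
  derived reports at 6).
* NIfTI stores spacing as float32; on load zooms are rounded to 6 decimals
  (nm precision) so double-precision spacings round-trip exactly.
* Empty masks load fine but are rejected by morphometry; single voxels are
  valid (A = B = diameter = 0, ellipsoidity from the voxel's own corner box).
* Test and acceptance problem sizes — 100-phantom calibration cohorts at 1 mm
  isotropic, a 200-phantom mixed cohort at clinical spacing, 400 draws for
  distribution recovery — were chosen as the smallest sizes at which the
  stochastic checks are stable; the statistics oracles run on frozen 5–10
  case fixtures where hand computation is feasible.

## Known limitations

* Ellipsoidity depends on grid resolution (see above); absolute values are
  not comparable across spacings.
* B is a projection width, not a chord; alternative conventions differ by up
  to a few percent on concave slices.
* ICC confidence bounds use the standard approximation; other ICC variants
  (consistency, average-measures) are deliberately not computed.
* Lobulated phantoms have no closed-form volume, so only ellipsoid phantoms
  carry analytic truth.
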