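# Methods

This note documents the models, parameter choices and numerical conventions
behind `nodulecad`, and what the synthetic phantoms do and do not establish
about behaviour on clinical CT.

## Coordinate and intensity conventions

Arrays are indexed `(z, y, x)`; spacing and origin follow the same order in
mm; voxel indices are 0-based, and physical positions are
`origin + index · spacing`. All detection stages assume an isotropic 1 mm
grid (`resample_isotropic`, trilinear for intensities, nearest-neighbour for
masks). Intensities are normalized to [0, 1] on the lung window
`[level − width/2, level + width/2]` = [−1400, +200] HU and kept as floats:
8-bit re-quantization would round away the contrast of subtle nodules. The
inverse map is provided for HU export.

## Lung segmentation

Four sub-steps, each with an explicit contract:

* **Initial extraction.** Otsu's threshold (between-class variance over a
  256-bin histogram, implemented in-package and cross-checked against an
  independent reference implementation in the tests) selects the
  low-attenuation class; components 26-connected to the lateral image
  borders are background air and are removed, as are components below
  500 mm³.
* **Airway removal.** The tracheal seed is the most superior dark component
  with near-midline centroid (< 30 mm), plausible area (20–300 mm²) and
  circularity > 0.7 — these heuristics are this package's own. 3D region
  growing is iterative 26-connected dilation restricted to the air region; a
  leak guard aborts when the grown volume jumps by more than 1.5× between
  iterations. The guard arms only after 200 voxels: any tube's early
  spherical growth phase shows ratios above 1.5, and an always-armed guard
  froze normal trachea growth immediately. Without a seed the region passes
  through unchanged with a warning.
* **Fused-lung separation.** Per slice, a component is treated as fused when
  it spans the midline *and* its column-wise integral projection over the
  central 25 % of the x-extent dips below half the component's median column
  height — a true anterior junction is a thin bridge, a single wide lung is
  not. The cut follows the per-slice minimum-projection column, median-of-5
  smoothed across slices. Left/right labels are assigned by centroid
  (right lung at low x).
* **Boundary repair.** A rolling ball of radius 15 mm along each per-slice
  lung contour, implemented as 2D morphological closing with a radius-15
  disc (its set-theoretic equivalent for contour indentations), plus
  per-slice hole filling to recapture vessel interiors. Closing is extensive
  and idempotent, which the property tests assert. Repair is per-slice
  because the contour being rolled along is a slice contour; a 3D ball would
  additionally bridge across the lung apex.

## Dot enhancement

The Hessian is built from Gaussian-derivative filters (kernels truncated at
4σ) and γ-normalized by σ² so responses are comparable across scales; the
response is `|λ₃|²/|λ₁|` where all three eigenvalues are negative
(bright-blob curvature), else 0. For a unit-contrast Gaussian blob the
maximal γ-normalized eigenvalue magnitude over scale is
(2/3)·(3/5)^(5/2) ≈ 0.186, attained at σ = s/√1.5; the multi-scale map is
divided by this constant so a matched unit-contrast blob responds with ≈ 1
and the group thresholds 15/256 and 10/256 operate on a comparable scale.
The scale list {1, 1.5, 2, 4, 6, 10} mm covers blob diameters of roughly
3–30 mm. Eigen-decomposition can be restricted to a mask (the dilated group
mask) — the filters are cheap, the per-voxel 3×3 eigensolves are not.

Candidate growth uses geodesic distance *within* the group mask (26-connected
moves with Euclidean step lengths), never Euclidean distance through
background. Each binarized dot-response object grows individually; voxels
reachable from several objects are split by a watershed on the shared
distance map. Without the split, a nodule seed adjacent to a bifurcation
seed merged into one oversized candidate whose centroid matched nothing.

## Rule filter

Volume gates 14.14 mm³ and 14.14 cm³ are the volumes of 3 mm and 30 mm
spheres — the clinical size class. Elimination requires a *strict* violation
(elongation > 6, compactness < 0.3, sphericity < 0.3); boundary values
survive. Elongation uses the second-moment (covariance) ellipse of the
in-slice voxels with the 1/12 discrete-uniform variance correction, so thin
bars and single voxels stay finite; aggregation over slices is worst-case
(max elongation, min compactness) by default — the rules are deliberately
lax and must not delete juxta-vascular nodules riding on tiny vessels — with
a largest-slice variant behind a flag.

## Features

27 features in a fixed canonical order: 4 gray-level statistics; 7
surface-gradient statistics from 3×3×3 Sobel-type kernels
([1,2,1]⊗[1,2,1] smoothing / 16, central difference / 2) evaluated at
26-connectivity surface voxels; 10 shell features on (dilate 2 − erode 1)
with central-difference gradients — five magnitude statistics and five
orientation scores (cosine between the gradient and the inward radial
direction); and 6 shape features from the intensity-weighted inertia tensor
(elongation e₁/e₂, flatness e₂/e₃, non-compactness trace/V^(5/3)) plus 3D
compactness, sphericity and irregularity (1 − equivalent-sphere area /
face-counted surface area).

Numerical conventions worth knowing:

* The inertia-tensor geometry means a **rod** has two large equal moments,
  so the rod signal appears in flatness e₂/e₃ (≈ 43 for a 2×2×16 rod) while
  elongation e₁/e₂ ≈ 1; a **disc** has e₁/e₂ ≈ 2. Non-compactness is
  size-invariant for uniform bodies (≈ 0.462 for solid spheres of any
  radius), which the tests verify at two radii.
* The eigenvalue ratios are capped at 10³: near-planar candidates otherwise
  produce ratios of order 10²⁷ that destroy feature standardization for
  every other sample in the batch.
* Skewness defaults to the standard m₃/m₂^(3/2); a compatibility variant
  with m₂³ in the denominator exists behind a flag. Degenerate all-equal
  distributions define skewness and kurtosis as 0.
* On a 1 mm lattice the surface-gradient magnitudes of *any* sphere are
  left-skewed (≈ −1), because surface voxels sample different depths of the
  edge profile; the discriminating quantity is the shift relative to that
  baseline, which attached vessel stubs produce reliably.
* The shell orientation ratios use max |score| in the denominator so both
  squared ratios stay in [0, 1].

The 16-name `SELECTED_FEATURES` subset is the discriminating set for
clinical CT and is what `select_features` returns; the phantom study
(below) feeds the classifier the full 27-feature pool, since feature
relevance on phantoms need not match clinical data.

## Selection and classification

**RSFS.** Each of 600 iterations draws a feature subset (inclusion
probability 0.5), a fresh stratified 70/30 split, and scores a 3-NN
classifier on z-scored features by unweighted average recall. Re-splitting
each iteration is essential: with a fixed split, chance feature–label
correlations persist across iterations and the selection statistic drifts
linearly rather than as a random walk, inflating false selections several
fold. A feature is selected when its cumulative relevance exceeds
1.96·√(n_f) standard deviations of the per-iteration deltas. At these
settings the method recovers 5/5 informative dimensions (separation 3,
n = 400) across seeds with ≤ 2 false picks, and selects almost nothing under
label permutation.

**Undersampling.** All positives are kept; the ratio·n_pos negatives closest
(z-scored Euclidean) to any positive are retained — the hard negatives near
the decision boundary. Ties break by sample index for determinism.

**Weighted SVM and nested CV.** RBF kernel; the positive class carries a
misclassification weight equal to the residual imbalance after
undersampling. `two_layer_cv` uses outer K = 10 / inner L = 3 stratified
folds (the best-performing combination), cost grid 2⁻¹…2¹³, gamma grid
{2⁻⁷, 2⁻⁵, 2⁻³, 2⁻¹, 2⁰}, integer sample ratios 1…imbalance; the inner
search maximizes mean Gmean with ties broken toward the smallest cost, then
gamma, then ratio. Standardization is fit on training folds only.

## Synthetic phantoms

`generate_phantom` renders, on a (88, 120, 120) grid at 1 mm: a soft-tissue
thorax ellipsoid (0.90), two lung ellipsoids (parenchyma 0.15) in background
air (0.05), an enclosed tracheal air tube above the lungs, one recursively
bifurcating vessel tree per lung (root radius 3 mm, five levels, branch
taper ≈ Murray's law 0.79/generation floored at 1.2 voxels, random
bifurcation angles 25–50°), low-contrast tiny peripheral vessels (0.40) with
a terminal Y, and nodules as antialiased spheres at parenchyma + 0.5
contrast in four placements (isolated, juxta-pleural, attached to the tree,
attached to a tiny vessel). Solid structures are blurred by a 0.5-voxel
Gaussian — enough partial-volume softening to make bifurcations blob-like
(the confounder the classifier must beat) while keeping each lung's tree one
26-connected component in the attenuation image, as in real thin-slice CT; a
heavier blur disconnects terminal branches at the multilevel-Otsu threshold
and breaks the grouping premise. Additive Gaussian noise (sd 0.015) comes
last. One seeded generator drives everything, so volumes are bit-reproducible.

What the phantoms do **not** emulate: ground-glass opacities, airway trees
beyond the trachea stub, lobar fissures, cardiac and diaphragm anatomy,
scanner-specific noise and reconstruction kernels, or pathology that
partitions the parenchyma. Passing phantom tests therefore demonstrates the
internal consistency and the geometric selectivity of the pipeline, not
clinical-grade performance; the published clinical operating points are
reproduced only at the arithmetic level, from their printed counts.

## The phantom study

`run_phantom_study` generates a seeded batch (default ten phantoms, five
nodules each — one isolated, one juxta-pleural, two on the vessel tree, one
on a tiny vessel, diameters 6–12 mm; the vessel-tree share mirrors the
clinical predominance of juxta-vascular nodules). Vessel-group candidates
are labeled positive when they contain the truth center voxel or their
centroid falls inside the truth sphere — containment matters, because a
candidate that swallowed nodule + vessel stub is still that nodule's
detection while an adjacent vessel fragment grazing the truth sphere is not.
The classifier is trained leave-one-volume-out on the full 27-feature pool
with fixed cost 8, gamma 2⁻⁶ and undersampling ratio 8: with only a few
dozen positives per batch, per-batch Gmean grid search proved too noisy and
collapsed specificity, whereas the smooth fixed operating point generalizes
across volumes. Final detections (non-vessel survivors + classifier
positives) are matched at centroid-within-truth-radius. Batch size and
problem dimensions are chosen so the whole study runs in about 90 seconds
on one CPU.

## Evaluation

Sensitivity = TP/(TP+FN), FPs/scan = FP/n_scans; matching is greedy
nearest-first one-to-one, checked against brute-force optimal matching at
test scale. The composite arithmetic multiplies prescreening sensitivity by
classifier sensitivity (and prescreening FPs/scan by the classifier FP rate)
for the vessel group, then pools groups over the total truth count. ROC/AUC
is trapezoidal over all distinct score thresholds and equals the
Mann–Whitney pair-counting statistic. Where two sets of composite numbers
circulate for the same counts, the set whose derivation is printed
(85.39 %, 0.8098, 87.81 %, 1.057) is taken as authoritative.

## Known limitations

* Pathological lungs (effusion, pneumonectomy, parenchyma-partitioning
  masses) are out of scope; segmentation assumes two air-filled lung fields.
* Ground-glass nodules are not detectable: the dot filter keys on solid
  blob contrast.
* The rule thresholds and binarization constants are the published clinical
  values; they are configurable but have been validated here only on
  phantoms.
* `load_volume` handles plain DICOM series and NIfTI; compressed transfer
  syntaxes, DICOM-RT and 4D series are unsupported.
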