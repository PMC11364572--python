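# Methods

## Coordinate frame and angle conventions

All geometry lives in one canonical patient frame fixed at load time: array
axis 0 runs inferior→superior (S), axis 1 posterior→anterior (A), axis 2
left→right (R), with per-axis voxel spacing in mm. Orientation metadata in
NIfTI/MetaImage headers is reduced to this frame by permuting/flipping axes
along the dominant direction of each image axis; volumes whose direction
matrix is so oblique that an image axis has no dominant anatomical axis
(dominant cosine ≤ √½) are rejected rather than resampled.

Endplate plane normals are unit vectors sign-normalized to the cranial
hemisphere (`n_S > 0`; ties broken by `n_R > 0`, then `n_A ≥ 0`). The
**coronal angle** of a plane is `asin(n_R)` and the **sagittal angle** is
`asin(n_A)`, both signed, in (−90°, 90°]; positive coronal angles lean
toward the patient's right, positive sagittal angles anteriorly.

Why `asin(n_R)` rather than the angle of the normal projected onto the
coronal plane (`atan2(n_R, n_S)`): the two coincide exactly when the spine
carries no sagittal tilt, but the projected angle of a coronally tilted
endplate changes by roughly `θ·(sec g − 1)` under a global sagittal
rotation `g` (≈1.2° at θ = g = 20°). `asin(n_R)` is the coronal component
of the normal itself and is *exactly* invariant under any rotation about
the LR axis, so lumbar lordosis, L5's steep sagittal slope, or a tilted
acquisition cannot leak into the coronal measurement. This decoupling is a
core advantage of measuring in 3D over annotating a 2D projection.

A normal with no usable component in the requested view (e.g. a near-pure
AP normal asked for its coronal angle, `hypot(n_S, n_R) < 1e−6`) raises an
undefined-angle error; such a plane is not an endplate.

## Disc surface fitting

Each disc mask is meshed by marching cubes at iso-level 0.5 on the binary
mask (zero-padded by one voxel so surfaces close at the array border),
with vertices scaled to physical mm. Masks thinner than 2 voxels along any
axis, or empty, are rejected as degenerate.

Plane fits come in two flavours:

* `fit_plane_pca(points)` — classic vertex PCA: centroid = arithmetic mean,
  normal = eigenvector of the point covariance with the smallest
  eigenvalue. Used for raw point clouds and exposed for general use.
* `fit_plane_surface(mesh)` — **surface-integral PCA**, the default for
  disc fitting (`GeometryConfig.area_weighted = True`): centroid and
  covariance are the exact area integrals of a uniform density over the
  triangle mesh, accumulated from the closed-form per-triangle moments
  `∫ x x^T dA = (A/12)(Σᵢ vᵢvᵢᵀ + (Σᵢ vᵢ)(Σᵢ vᵢ)ᵀ)`.

The surface integral matters for two measured reasons. First,
marching-cubes vertex *density* depends on voxel anisotropy and surface
orientation — at the standard sagittal resolution (3.29 mm between
sagittal slices) the annulus wall carries ~2× the vertex density of the
endplate faces and vertex PCA under-reads endplate tilts by 5–6%. Second,
vertex positions of a mirror-symmetric mask are symmetric but the
triangulation's diagonal splits are not, and per-vertex weights inherit
that chirality (≈0.8° spurious tilt on a flat disc at 1.2 mm voxels); the
exact integral is invariant to how planar patches are triangulated and
returns 0.000° there. Fine-resolution results are unchanged (< 0.05°).

The disc's mid-plane (fitted to the whole surface) splits the surface into
an upper and a lower half; vertices exactly on the mid-plane go to the
lower half (deterministic, measure-zero tie-break). Halves with fewer than
`min_half_vertices = 30` vertices abort with a degenerate-disc error — a
guard against fragmented or tiny segmentations, for which a plane fit
would be numerically meaningless. Per-half planes are then fitted the same
way (for the surface-integral fit, triangles are assigned to the half
containing their centroid).

### Wedge-shaped discs

The method assumes the half-surfaces are parallel to the adjacent
endplates. For a *wedged* disc (upper and lower surfaces at different
coronal tilts), each half also contains part of the annulus wall, which
pulls the fitted normal toward the disc's mean tilt: on the default
phantom geometry, a +8°/−3° wedge is recovered as ≈ +5.4°/−0.3° — about
half the deviation from the mean is lost, while the mean tilt itself is
preserved. No wedge-specific correction is attempted: a correction would
need shape assumptions that fail exactly in the pathological cases
(Schmorl nodes, herniations) where robustness matters most. The test suite
asserts this attenuation characterization rather than pretending exact
wedge recovery; Cobb angles of curves whose wedging sits in the vertebrae
(parallel-surfaced tilted discs) are unaffected.

## Cobb enumeration

Disc *i*'s lower half-plane angle is the superior endplate of the vertebra
below it; its upper half-plane angle is the inferior endplate of the
vertebra above. For every pair of discs (a cranial to b) the candidate
Cobb angle is `|θ_lower(a) − θ_upper(b)|` between top level = vertebra
below a and bottom level = vertebra above b; signed angles make opposite
tilts add, matching the clinical definition. Adjacent discs produce
single-vertebra candidates; a `min_span` option excludes them if desired.
The Cobb angle is the maximum candidate; exact ties are broken first by
larger vertebral span, then by the more cranial top level. Endplates of
the field-of-view-terminal vertebrae (no disc beyond them) are simply
unavailable — no extrapolation.

`cobb_at_levels` evaluates the same quantity at arbitrary requested levels,
which is what comparing against human readers requires.

## Synthetic phantoms

The phantom generator is the package's test bed: labeled volumes with the
same contract as segmentation-model output, but with closed-form truth.

A phantom is a cranio-caudal stack of elliptic-cylinder vertebral bodies
(default cross-section 40 mm LR × 30 mm AP, height 28 mm) and discs
(default height 10 mm), five vertebrae by default (L1–L5, SPIDER-like
labels: vertebrae numbered caudal→cranial from 1, discs at the label of
the vertebra above plus 200). Every interface between structures is a
plane with a configurable coronal tilt — one tilt per vertebral endplate —
so all endplate angles, the full candidate matrix, and the true maximal
Cobb angle and levels are known exactly before rasterization.

Crucially, each segment is **rigidly rotated** about the AP axis by the
mean tilt of its two end surfaces and laterally offset along the resulting
bent center line, rather than sheared between tilted planes with vertical
walls. This is what a scoliotic curve does anatomically, and it matters
numerically: PCA of a *sheared* prism does not recover the shear angle
(the vertical wall rotates the minor eigenvector by 6–8%), whereas PCA of
a rotated body is exact by symmetry. With rotated segments the pipeline
recovers configured tilts to < 0.4° even at a 38° curve.

Additional generator features, each emulating a property of real data:

* **global sagittal tilt** — the whole stack is rotated about the LR axis
  analytically before rasterization (supine patient tilt / lordosis
  surrogate); true coronal angles are unchanged by construction.
* **boundary noise** — smooth seeded jitter of every interface surface
  (uniform amplitude, default 0.2 mm, correlation length 8 mm),
  approximating segmentation boundary irregularity while keeping each
  structure a single watertight component.
* **disc collapse defect** — one disc restricted to a fraction of its LR
  footprint (kept on the left), reproducing the one-sided collapse that is
  the clinically observed segmentation failure mode.
* **voxel spacings** — defaults follow sagittal MRI acquisitions, where
  the coarse axis is the slice (LR) direction: high resolution
  (0.47, 0.47, 0.90) mm and standard resolution (0.59, 0.59, 3.29) mm in
  canonical (S, A, R) order.
* `smooth_c_curve` — the single-curve morphology of degenerative
  scoliosis: disc tilts progress monotonically with near-plateaus at the
  curve ends, so measuring one level off the apex pair changes the angle
  only gradually. This is the family used for the simulated reader study;
  free per-endplate tilts remain available for arbitrary (including
  S-shaped and wedged) configurations.

Configurations whose tilts would make adjacent interfaces cross inside a
structure (allowing for noise amplitude) are rejected as infeasible.

What the phantom does **not** emulate: MRI intensities (only labels),
posterior vertebral elements, axial rotation, curved (non-planar)
endplates, and segmentation texture errors other than the three injected
defect types. Tests passing on phantoms therefore validate the geometry
pipeline and its resolution/orientation robustness, not the upstream
segmentation model.

`simulate_readers` turns phantom truths into manual-measurement tables:
each simulated reader starts from the true maximal levels, moves each
endpoint to an adjacent level with a configurable probability, and reports
the true angle at the chosen levels plus Gaussian noise (floored at 0°).

## Segmentation quality control

Report-only heuristics over a labeled volume and its scheme:

* **missing disc** — an expected disc with zero voxels while both adjacent
  vertebrae are present;
* **fragmentation** — a disc split into more than one connected component
  of at least 100 voxels (smaller satellites are treated as noise);
* **coverage** — a disc whose axial footprint covers less than 0.6 of the
  adjacent vertebra's footprint (the one-sided collapse signature).

Both thresholds are configurable; the defaults are chosen so the injected
phantom defects are flagged while intact phantoms at any tested resolution
pass. QC never blocks measurement — the CLI measures anyway and signals
the failure through a distinct exit code.

## Reliability statistics

* **MAE** — mean ± SD of absolute pairwise differences; the SD is the
  population SD (ddof = 0) by default, with ddof exposed.
* **ICC** — two-way random effects, absolute agreement, single measurement
  (ICC(2,1)), computed from the ANOVA mean squares, with the F-based 95%
  confidence interval using Satterthwaite degrees of freedom (McGraw &
  Wong). Interpretation bands: < 0.50 poor, 0.50–0.75 moderate, 0.75–0.90
  good, ≥ 0.90 excellent. Negative estimates are clipped to 0 and flagged;
  missing cells are an error (no imputation). The implementation is
  cross-checked in the tests against an independently coded mean-squares
  decomposition (to 1e−10) and against pingouin.
* **Bland–Altman** — bias = mean(a−b), limits = bias ± 1.96·SD(a−b)
  (sample SD, no t-correction); plots draw the ±5° clinical band.
* **Consensus level** — the median of an odd reader panel's levels under
  cranio-caudal ordering (three distinct choices → the middle one). Even
  panels are refused rather than interpolated: the median of an even panel
  can fall between vertebrae.
* **5° acceptance** — a manual measurement counts as "would have accepted
  the automatic result" iff the absolute difference to the automatic angle
  *at the same levels* is strictly below the tolerance (default 5°, the
  clinically accepted Cobb measurement error).
* **Level agreement** — per reader, the distribution of
  |Δtop| + |Δbottom| (in level steps, vs the algorithm's maximal-angle
  levels) over the buckets 0 / 1 / 2 / >2.

## Validation problem sizes

The acceptance test suite and `scripts/acceptance.py` use: 20 (tests) or
12 (script) random curves with true max Cobb 5–40° at high resolution,
each re-rasterized at standard resolution for the cross-resolution check;
3 curves × sagittal tilts {5°, 10°, 20°} for the invariance check
(boundary noise disabled there, since the tilted volume lives on a
different grid and re-drawn jitter would mask the null effect being
tested); 1,000 random angle tables against the brute-force oracle; 50
jittered plane fits; and a 20–30-phantom simulated three-reader study at
coarser spacing (0.8–1.2 mm) with angle noise SD 2.5° and 20%
adjacent-level errors. These sizes keep a full run in the low minutes on
one CPU while every check retains clear statistical margin.

## Known limitations

* Accuracy is bounded by segmentation quality; the package consumes masks
  and cannot correct a wrongly segmented disc (it can only flag shapes).
* Wedge-disc endplate angles are attenuated toward the disc mean (above);
  strongly degenerated, collapsed or irregular discs inherit this.
* Only the lumbar field of view is measured; curves continuing beyond the
  imaged region are truncated, and terminal endplates are unavailable.
* Supine MRI angles are systematically smaller than standing radiograph
  angles; no supine-to-standing conversion is applied.
* The coronal-angle convention decouples sagittal tilt exactly, at the
  price of differing from a literal 2D projection measurement by up to
  ~1° when large coronal and sagittal tilts combine.
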