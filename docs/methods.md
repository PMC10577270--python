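# Methods

`vdissect` geometrically parses a segmented cardiac blood-pool shell — the
left atrium (LA) together with its pulmonary veins (PVs) and the left
atrial appendage (LAA) — into anatomically labelled structures. The
underlying model is deliberately simple: the LA body is an ellipsoid, each
PV a circular cylinder attached radially to it, and the LAA a paraboloid
pouch. Everything the pipeline does — the convexity-driven stopping rules,
the radial ostial cut planes, the residual-based rescue of swallowed
appendages — follows from that primitive decomposition.

## The dissection model

A shell is a 3D boolean voxel grid with anisotropic spacing in mm
(axis order x, y, z; anatomical frame +x left, +y anterior, +z superior;
world coordinates use the voxel-centre convention). Dissection proceeds in
four stages.

**1. Iterative erosion with the Erosion Index.** The shell is eroded one
structuring-element step at a time (default: the 6-connected, face-adjacency
element — one step removes roughly one voxel layer). After each step only
the largest 6-connected component is kept as the LA candidate, and its
*Erosion Index* is recorded: the digital solidity

> solidity = (component voxel count) / (voxel count of the voxelized
> convex hull of the component's voxel centres).

This is the regionprops-style solidity convention: axis-aligned boxes score
exactly 1, digitized balls and ellipsoids score 1 (their centre hull is
inscribed in the continuous body and captures no extra voxel centres), and
concavities deeper than one voxel push the index below 1. Tubular veins
and the appendage junction make the intact shell markedly concave
(index ≈ 0.5 on typical synthetic shells); as erosion severs them, the
candidate converges to the convex eroded ellipsoid and the index jumps to
≈ 0.95–1.0. Erosion stops at the smallest n with index ≥ `tau_e`
(default **0.94**); if the threshold is never reached within `n_max`
(default 15) iterations the argmax iteration is used and the trace is
flagged low-confidence. The threshold was calibrated so the rule agrees
with an exhaustive ground-truth sweep on dedicated synthetic calibration
cases at 1 mm: on those cases the index trace shows a sharp knee at the
sweep-optimal iteration, with 0.94 separating the pre-knee plateau
(≤ ~0.9) from the post-knee values.

**2. Geodesic dilation with the Dilation Index.** The eroded core is
restored by geodesic dilation (dilate one step, intersect with the shell).
The *Dilation Index* at step n is the restored volume fraction
|core_n| / |shell|. Candidate steps run from 0 to n_e + 4: the residual
surface rind left by opening only fragments one to three steps *past* the
erosion count, so stopping exactly at n_e would leave a single merged
remnant wrapping the LA. The selected step is the one at which the number
of *structure-scale* remnant components of shell \ core_n peaks — every
appendage has detached but none has been swallowed — with ties broken
toward the smallest step. A remnant component is structure-scale when its
volume is ≥ `min_structure_volume` (default 300 mm³, about a 4 mm-radius,
6 mm-long PV stump) *and* its maximum interior radius is ≥ 2.5 mm: veins
and appendages are tubular or bulky, whereas rind residue forms thin
slab-like shells that pass a volume test but not a thickness test. The
scan ends early when the marginal index gain drops below `gamma` (default
0.005 of the shell volume; per-step gains on realistic shells are 0.3–7%,
so this only fires at the reconstruction fixed point).

**3. Anatomical classification.** Structure-scale remnants receive
anatomical labels from the octant of their centroid relative to the LA
centroid: left is x > 0; anterior-left remnants are the LAA (largest
wins); posterior remnants split left/right and superior/inferior.
A single left posterior remnant where two are expected is the common left
trunk (label 7); anything beyond the expected set becomes supplemental
(labels ≥ 8). The rule is deterministic and independent of remnant
enumeration order. It presumes the fixed anatomical frame; oblique NIfTI
orientations are snapped to the nearest axis permutation on load with a
logged warning.

**4. Ellipsoid-guided refinement.** Because the LA body is modelled as an
ellipsoid, a trimmed moment-matched ellipsoid fitted to the LA label (for
a uniform ellipsoid the voxel covariance is diag(a², b², c²)/5; the fit is
re-run excluding voxels protruding > 2.5 mm so that mislabelled appendage
tissue cannot inflate it) defines the reference surface on which every
ostium lies. Two mechanisms use it:

* *Rescue.* Structure-scale connected components of LA-labelled voxels
  protruding more than 3 mm beyond the fitted surface, and not adjacent to
  an already-detected structure, are appendages the restoration stage
  swallowed — typically a wide-mouthed LAA whose mouth radius approaches
  its inscribed radius, for which no erosion/dilation count pair separates
  the pouch. They are relabelled as fresh structures before refinement.
* *Cut planes.* For each structure a medial centerline is traced from the
  LA centroid to the structure centroid: the minimum-cost path on the
  voxel graph under the medialness potential 1/(d + 0.1 mm)², where d is
  the anisotropy-aware Euclidean distance to the background — the discrete
  analogue of a Voronoi/medial-axis centerline (per-step cost is the step
  length times the mean potential of its two endpoints). The cut plane
  sits where the centerline crosses the fitted surface (falling back to
  the first non-LA path voxel if it never crosses), with its normal along
  the fit's radial direction — appendages attach radially in the primitive
  model, and a radial plane at the surface of a convex body keeps the
  entire LA on the atrial side, making the cut safe however large its
  influence region. Voxels of the LA or the structure within the influence
  radius (twice the local medial radius, extended to the structure's
  farthest voxel so an invaded lens is fully reclaimed) are reassigned by
  plane side; on-plane voxels go to the LA. Boundaries already planar to
  within one voxel (mean absolute deviation of the boundary-face axial
  positions about their median ≤ the largest spacing) are left untouched —
  a planar recut could only re-voxelize them.

The label partition of the shell is preserved exactly through every stage.

## Iteration-count prediction from seed data

Where ground truth exists for a handful of "seed" shells,
`sweep_optimal_iterations` finds the best counts by exhaustive search
(n_e in [1, n_max], n_d in [0, n_e + 4], maximizing mean per-structure IoU
against truth, ties to the lexicographically smallest pair; the scan
shares erosions and incremental dilations, so it costs ~n_max erosions
plus O(n_max²) dilation steps). An `IterationPredictor` is then fitted on
global shape features of the shells — volume, face-counted surface area,
isoperimetric sphericity, solidity, bounding-box extents, principal-axis
elongation — using RBF support-vector **regression** (C = 1, ε = 0.5),
rounded and clamped to the training range. Regression rather than
classification because iteration counts are ordinal: with the typical five
seed cases a classifier latches onto the majority count, while the
regressor degrades gracefully toward the central training value.
In honesty, with so few seeds the features carry limited signal (the
optimal count is driven mostly by the widest appendage mouth, which global
shell descriptors see only weakly); the predictor's value is robustness —
it anticipates the sweep optimum to within ±1 for the bulk of shells whose
optima cluster around the central value, and cannot anticipate outliers.

## Synthetic digital atria

`sample_spec(seed, variant)` draws a parametric atrium: LA volume uniform
in 71–140 ml with mild axis anisotropy (b/a in 0.78–0.95, c/a in
0.62–0.85); four PVs in the posterior left/right × superior/inferior
octants (radius 4–9 mm clamped below half the smallest semiaxis, length
15–30 mm, directions jittered up to 15° about the canonical octant
diagonals); an LAA pointing left-anterior-superior (mouth radius 6–12 mm,
depth 15–30 mm). Variants: `common_left_trunk` replaces the left PVs with
one trunk (radius 7–9 mm, z ≈ 0), `supplemental_pv` adds a right middle
vein (radius 4–6 mm, 8° jitter so it stays clear of its neighbours),
`no_laa` removes the appendage.

`rasterize` evaluates approximate signed-distance functions of the
primitives on the grid, perturbed by a smooth zero-mean "bump" field (sum
of 10 random-direction cosines, wavelengths 30–60 mm, default amplitude
1.5 mm) added to the level set, so shells are not ideal quadrics.
Primitives overlap into the ellipsoid (cylinders by 8 mm, the paraboloid
mouth by 6 mm) so that wide, obliquely attached appendages remain
connected across the curved, perturbed surface. Ground truth assigns each
shell voxel to its owning primitive with the LA winning all overlaps, so
truth boundaries coincide with the analytic ostial surfaces; the analytic
ostial plane of each appendage passes through the intersection of its axis
with the ellipsoid, normal along the axis. The analytic
centroid-boundary distance is computed by quadrature on the ideal
ellipsoid surface inside each appendage cross-section (the bump field is
zero-mean, so its residual effect on the mean is well below the
millimetre). The shell is guaranteed a single 6-connected component;
bump-induced specks below 1% of the foreground are dropped, larger
disconnections raise a generation error.

Default test spacing is 1 mm isotropic (fast); a CT-resolution preset
(0.42 × 0.42 × 0.7 mm) is available. What the generator does *not*
emulate: image intensities and noise, myocardium, mitral-valve anatomy,
non-radial vein take-offs, and the shape diversity of real patient atria.
Passing tests on these phantoms therefore demonstrate the geometric
correctness and internal consistency of the parsing machinery under the
model's own assumptions, not clinical-grade accuracy on patient CT.

## Evaluation metrics

Per structure: Dice 2|A∩B|/(|A|+|B|); IoU with the strict IoU > 0.5
success criterion; directed average surface distance (mean distance from
prediction boundary-voxel centres to the nearest reference boundary-voxel
centre; a symmetric variant averages both directions); and the
centroid-boundary distance — the mean distance from the whole-shell
centroid to the centres of the faces shared by the LA and the structure.
Both-empty inputs score Dice = IoU = 1 by convention. LA volume is
reported in ml; the sphericity index is the isoperimetric
π^(1/3)(6V)^(2/3)/A with face-counted A. Face counting overestimates the
area of smooth surfaces by a factor converging to 3/2 (a digital ball's
sphericity converges to 2/3, not 1); the bias is identical for the two
maps being compared, so agreement statistics are unaffected. Cohort
statistics: Bland–Altman mean difference with ±1.96·SD limits of agreement
(n−1 denominator), Pearson correlation with its t-transform p-value, and
the exact binomial McNemar test on paired success flags,
p = min(1, 2·BinomCDF(min(b,c); b+c, ½)).

## Numerical and engineering choices

* Morphology, connected components and distance transforms delegate to
  `scipy.ndimage`; convex hulls to Qhull via `scipy.spatial`; the hull is
  voxelized exactly by intersecting its facet half-spaces with scan
  columns. Minimum-cost paths use `skimage.graph.MCP_Geometric` with
  per-axis sampling, so anisotropic spacing is handled throughout.
* Erosion iterations count element steps, not millimetres: with
  anisotropic spacing the physical step differs per axis. The synthetic
  test preset is isotropic; at CT resolution the z-step is 0.7 mm versus
  0.42 mm in-plane.
* Ties in the erosion argmax fallback and the sweep go to the smallest
  iteration counts (least distortion); centerline ties are resolved
  deterministically by the path-finder's fixed scan order.
* Degenerate inputs: an already-convex shell selects zero erosion
  iterations and dissection flags "no remnants" with the whole shell
  labelled LA; a single-voxel structure yields a single-point centerline;
  collinear/coplanar components count as convex (solidity 1).
* NIfTI volumes are reduced to the internal frame on load; writing encodes
  that frame in the affine so read∘write is the identity on labels, shape
  and spacing.

## Problem sizes in the test suite

The bundled tests and the acceptance script run entirely on generated
data: 20-case standard cohorts, 10 + 5 variant cases, and 5 + 10 shells
for predictor tuning, all at 1 mm isotropic resolution (grids around
130³–160³ voxels, LA volumes 71–140 ml). These sizes exercise every
stage — including the exhaustive sweeps — while a full run stays in the
tens of minutes on a single core; larger cohorts change the statistics'
precision, not the code paths.

## Known limitations

* The classification frame assumes near-axis-aligned anatomy; heavily
  rotated volumes are snapped, not registered, and the octant rules may
  then misname structures.
* The ellipsoid fit underlies both rescue and cut-plane placement; atria
  that deviate strongly from an ellipsoid (e.g. post-surgical remodelling)
  would degrade both.
* A single left posterior remnant is always called a common trunk — a
  missed LIPV is indistinguishable from a true trunk without atlas
  information.
* The LAA/LSPV distinction rests on the anterior-centroid heuristic; a
  posteriorly rotated appendage would be mislabelled.
* Wide-mouthed appendages whose mouth radius approaches their inscribed
  radius sit at the edge of what erosion-based separation can do; the
  ellipsoid-residual rescue recovers most but not all of them (the
  residual failure appears in the acceptance statistics rather than being
  hidden).
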