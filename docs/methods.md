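# Methods

## Scope and data model

The package analyses 3D grayscale voxel stacks of fruit cortex
parenchyma (multi-page TIFF or a directory of per-slice images) with an
isotropic voxel pitch of ~5 μm, the resolution at which intercellular
air channels and cell outlines are resolvable but cell walls are not.
All images are `(z, y, x)` arrays; physical outputs use one unit
convention throughout: volumes in mm³, surfaces in mm², lengths in μm.
Cropping is exposed as explicit lateral/axial margins in μm (default
1000 μm when emulating the excision protocol) rather than a
"cell-layer" heuristic, because cell layers are not identifiable before
segmentation.  The retained extent is `floor((N·pitch − 2·margin)/pitch)`
voxels, centered.

## Segmentation

Cells (bright, watery) and voids (dark, air) are separated by a single
global Otsu threshold on a 256-bin histogram of the full 3D stack; the
contrast between the two phases is large enough that adaptive methods
add nothing.  A connected-component filter then removes speckle smaller
than `min_voxels` (default 51 voxels ≈ 6.9×10⁻⁶ mm³ at 5.14 μm pitch,
the smallest void the protocol retains) at 26-connectivity.  The filter
is applied to both phases by default, with voxels removed from the cell
phase rejoining the voids so the two masks always partition the domain;
which phase is dark is a flag, since phase-contrast data can invert
edge contrast.

## Cell isolation

The binary cell phase is split into individual cells by
marker-controlled watershed on the negated Euclidean distance map
(EDM), computed in physical units so anisotropic pitches would remain
correct.  Markers are the regional maxima of the EDM after h-maxima
suppression with depth `h_min_um` (default 10 μm ≈ two voxels at CT
pitch): deep enough to absorb discretization maxima, shallow enough not
to merge genuine ≥150 μm cells.  Flooding assigns every masked voxel to
exactly one label (no zero-thickness ridge walls are left unlabeled).
Labels touching any of the six faces are removed (their volume fraction
is reported), and a virtual sieve drops labels longer than 400 μm or
with sphericity below 0.75 — thresholds that discard unseparated clumps
and fragments while keeping single cells, whose representative diameter
is about 200 μm.

Per-object measures:

* **volume** — voxel count × voxel volume;
* **surface** — triangulated isosurface (marching cubes at level 0.5)
  of the mask after Gaussian smoothing with σ = 1 voxel.  The smoothing
  matters: marching cubes on the raw binary mask tracks the voxel
  staircase and overestimates a sphere's area by ~9 %, which would
  corrupt every sphericity and shape-factor threshold; with smoothing
  the estimator is within ~1 % on digital balls down to ~20 voxels
  across.  A raw face-count estimator is available for cross-checks
  (`surface_method="faces"`); it overestimates smooth surfaces by up to
  50 % but is exact on voxel geometry;
* **ESD** — equivalent spherical diameter `(6V/π)^(1/3)`;
* **elongation** — `sqrt(λ_max/λ_min)` of the voxel second-moment
  tensor, with a per-voxel cube term `pitch²/12` added to the
  covariance so single-voxel and planar objects stay finite (a voxel
  cube has elongation exactly 1; a 2:1 ellipsoid measures 2.0);
* **sphericity** — `π^(1/3)(6V)^(2/3)/A`, 1 for a sphere;
* **length** — maximum caliper extent over the 13 canonical digital
  directions (axes, face diagonals, space diagonals) plus one voxel
  pitch; this approximates the true 3D Feret length of convex bodies to
  within ~3 %;
* **cell-to-void area fraction** — boundary faces adjacent to void
  voxels over all boundary faces of the label.

## Void network

Voids are 26-connected components (one shared vertex suffices).  Void
counting is edge-corrected with the Miles–Lantuéjoul weighting: each
void that touches no face counts for
`IxIyIz / ((Ix−Px)(Iy−Py)(Iz−Pz))`,
the reciprocal probability that a congruent object placed uniformly in
the window avoids its border; border-touching voids are excluded from
counting and size statistics (their volume share is reported) but kept
in porosity, anisotropy and fragmentation, which are whole-mask
descriptors.  One discretization subtlety: a void spanning P voxel
planes stays clear of both border planes over I−(P+1) center positions,
so the weights are evaluated with exclusion extents one pitch larger
than the bounding-box coverage.  With the raw extents a Monte-Carlo
check against a hard-core Boolean ball model shows a systematic −6 %
bias; with the corrected extents the weighted count is within two
standard errors of the true density while the naive interior count is
biased low by design.

The void shape factor `τ = A·d_eq/(4V)` compares the void surface to
the lateral surface of the equal-volume, equal-ESD cylinder (no end
caps, exactly as the identity implies); it is 1.5 for a ball,
dimensionless, and scale-invariant.

**MIL anisotropy.**  Parallel test lines (2-voxel grid spacing, 1-voxel
steps) are cast along n directions drawn uniformly on the sphere
(deterministic from a seed; 512 by default, fewer suffices for small
volumes).  Per direction, MIL = total in-domain line length / number of
void–cell crossings; directions without crossings are dropped with a
warning.  The directional MILs are fitted by the standard MIL ellipsoid
(least squares on `nᵀAn = MIL(n)⁻²`); anisotropy = 1 − shortest/longest
semi-axis.  Isotropic Boolean-ball fixtures measure ≤ 0.05; aligned
cylinders measure far higher.

**Fragmentation index.**  FI = (A₁−A₂)/(V₁−V₂) between the mask and its
one-step 6-connected dilation, in mm⁻¹, following the trabecular-bone
convention.  Surfaces here are counted on voxel faces, not with the
smoothed mesh: the index differences two surfaces one dilation step
apart, so the uniform staircase bias cancels, whereas isosurface
smoothing destroys one-voxel-thin channel sheets and can flip the sign.
FI is negative for the well-connected concave channel network of an
unfragmented phantom and rises monotonically with the fragmentation
parameter; its absolute value carries no physical meaning.

## Skeletonization

The void space is thinned to centerlines by sequential
distance-ordered, direction-subiterated removal of *simple points*
(deletions that preserve the topology of both phases, characterized by
one 26-connected foreground component among the 26 neighbours and one
face-adjacent 6-connected background component in the 18-neighbour-
hood).  Sequential deletion makes component conservation exact by
construction; visiting voxels in increasing EDM order centers the
surviving curves on the medial axis; and cycling over the six face
directions thins fronts symmetrically.  Voxels with ≤ 2 foreground
neighbours are protected: interior curve voxels are non-simple
regardless, and the protection prevents even-width rods from being
consumed tip-first (their tips never pass through a one-neighbour
state).  The cost is an occasional short stub at blunt tips, which is
removed at the graph stage.  The kernel is numba-compiled; a 2-million-
voxel tissue mask thins in about two seconds.

The centerline becomes a spatial graph: junction voxels (≥ 3 skeleton
neighbours) within Chebyshev distance 2 merge into one branching point
(thinning smears junctions over a few voxels); endpoint voxels become
terminal nodes; chains between nodes become branches.  Arc length uses
chamfer weights (1, √2, √3 voxel pitches per step), which removes most
of the digital length bias — a 1000 μm tube measures within 5 %.  Every
polyline point carries the EDM value of the void mask as local
thickness.  Terminal branches hanging off a junction that are shorter
than 2 voxels or than twice their maximum local thickness are pruned as
thinning artifacts.  Reported network statistics: branching points per
mm³, total path length per mm³ (mm/mm³), and mean path length per void
component.

## Size distributions

Histograms of cell/void ESD are volume weighted (bin mass = % of total
object volume), matching how a few large voids dominate the tissue.
Parametric fits (normal, Weibull) are maximum-likelihood on a
volume-weighted bootstrap resample (default 1000 draws with probability
∝ volume).  Goodness of fit uses a Kolmogorov–Smirnov statistic whose
null distribution comes from a parametric bootstrap under the fitted
parameters; crucially, each null replicate repeats the *entire*
procedure (simulate a fresh object set of the original size, resample
with the same weights, refit, recompute KS), because the resampling
step injects duplication noise that a naive "simulate-and-test" null
does not carry — without this the test rejects a true model ~40 % of
the time at α = 0.05, with it the measured type-I error is 3.5–6.5 %.

## Effective oxygen diffusivity

Constants: D_air = 2.15×10⁻⁵ m²/s, D_water = 2.75×10⁻⁹ m²/s, Henry
constant H = 0.0137 mol m⁻³ kPa⁻¹, R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K
(the temperature that reproduces the conventional cellular diffusivity;
all constants overridable).  The cell-phase diffusivity is
`D_water·R·T·H` with R·T expressed in kPa·m³/mol to match H's pressure
unit — numerically `D_water·R·T·H·10⁻³` ≈ 9.3×10⁻¹¹ m²/s.

The serial pathway uses the standard Maxwell–Eucken form for a dilute
dispersion of air voids in a continuous cell matrix,
`D_ser = D_c[2D_c + D_a − 2ε(D_c−D_a)] / [2D_c + D_a + ε(D_c−D_a)]`,
which is the only form consistent with the full set of genotype values
it must reproduce (1.1–1.9×10⁻¹⁰ m²/s over ε = 0.057–0.254).  The
parallel pathway is `ε·D_air/τ²`; τ defaults to the measured void shape
factor, whose square is a fair tortuosity estimate.  The combination is
harmonic in the weighing factor w (fraction of the path through
connected pores), so `D_ser ≤ D_eff ≤ D_par` for all w, D_eff is
monotone in w, and the inversion
`w = (1/D_ser − 1/D_meas)/(1/D_ser − 1/D_par)` is closed-form; measured
diffusivities outside the open interval clip w to [0, 1] with a
warning.  Theoretical ε-only tortuosity laws are *not* implemented:
none reproduces the reported porous-media range, so τ is always
user-supplied or structure-derived.

## Synthetic phantoms

The generator emulates the geometry the analysis chain must handle,
not the physics of tissue growth.  Cell centers are a Poisson-disk
(dart-throwing) sample at spacing 0.9 × mean cell diameter; cells are
the Voronoi regions of those centers (giving convex, wall-to-wall
polyhedral cells, and a voxel-level ground-truth label map); voids are
slabs along the Voronoi faces, `d₂ − d₁ < t`, with the half-thickness t
bisected so the voxelized porosity hits the target within ±0.02 (t can
instead be fixed directly to study porosity at constant channel
radius).  Fragmentation deletes the channels of a random subset of
cell pairs; each pair carries a fixed hash-derived uniform score, so
the deleted set is *nested* in the parameter and the void component
count rises monotonically.  Anisotropy stretches the distance metric
along one axis, elongating cells and channels and producing a
controllable MIL signal.  The grayscale rendering is two-level (cells
170, voids 60) with additive Gaussian noise at a configurable
contrast-to-noise ratio (default 5, at which Otsu misclassifies < 1 %
of voxels).  Defaults — mean cell 200 μm, porosity 0.15, fragmentation
0.2, SNR 5 — represent a mid-porosity apple cortex.

What the phantom does not emulate: curved cell walls and turgor-driven
cell shapes, stone-cell clusters, partial-volume gray levels, CT
artifacts (rings, beam hardening), and — importantly — the fact that
its channels follow planar Voronoi faces all the way to the domain
border, so at low fragmentation nearly all void volume is
border-connected and interior-void statistics only populate at high
fragmentation.  Passing tests therefore demonstrate correctness of the
estimators on known geometry, not end-to-end accuracy on real CT data.

## Problem sizes and determinism

Test and example runs use 0.7–1.2 mm domains at 8 μm pitch (0.7–3.4
million voxels), 24–128 MIL directions, 200-replicate Monte-Carlo
checks and 200×500 bootstrap calibrations; these sizes give stable
statistics for every property under test while keeping a full run in
minutes on one CPU.  Every stochastic component (phantom, MIL
directions, bootstrap) takes an explicit integer seed, and the pipeline
echoes its full configuration into the summary provenance, so identical
config yields identical output.

## Known limitations

* The thinning leaves a short central segment (~half a radius) rather
  than a single point for large digital balls; spheres are not the
  target geometry of a channel-network skeletonizer.
* Tube skeletons lose about one radius of length at each blunt end
  (960 μm measured for a 1000 μm × 40 μm tube), inherent to endpoint-
  preserving thinning of capped cylinders.
* The watershed ridge assignment follows the flooding order of the
  marker-controlled implementation rather than an explicit
  larger-EDM-neighbour rule; on phantom cells the label count matches
  ground truth within 4 % and mean ESD within 4 %.
* Absolute morphometric panels of real cultivars require the original
  CT scans; the package reproduces the procedures and the printed
  closed-form diffusivity results, and validates everything else on
  synthetic geometry.
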