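# Methods

`spinemesh` turns a 3D electron-tomographic volume of a dendritic spine,
plus a co-registered compartment mask, into an attributed filament-network
graph and a battery of morphometric statistics. This note records the
models, the numerical choices, and what the synthetic phantoms do and do
not establish.

## Processing model

**Coordinates and units.** Volumes live on an isotropic voxel grid
(default pitch 2 nm, the binned resolution of modern multi-tilt
tomograms); voxel `(z, y, x)` has its centre at
`origin + (index + 0.5) * pitch`. Lengths are reported in nm, angles in
degrees, densities in μm⁻³.

**Masking.** The compartment mask assigns each voxel to extracellular
space, cytosol, membrane, ER, PSD or mitochondria. Only cytosol voxels
are analyzed; all other compartments are excluded and, for
distance-transform purposes, count as boundary.

**Denoising.** Gaussian smoothing with σ = 2 nm (masked, renormalized
convolution so boundary voxels are not dragged toward the sentinel
value). Smaller kernels leave too much voxel noise; larger ones start
erasing 8 nm filaments.

**Binarization.** A local threshold adapts to the slow luminance drift
along the z-axis: within a cubic window (20 nm ≈ 11 voxels; the odd span
nearest to window/pitch) the mean *m* and SD *s* of valid voxels are
computed, and a voxel is foreground iff its intensity strictly exceeds
`T = m − k·s` (Niblack form; a pure mean-offset form `T = (1−k)·m` is
available behind `threshold_form`). Binarization is defined on
*absorption* polarity — stained structure bright; raw luminance volumes
are negated on load. Windows with fewer than 8 valid voxels classify as
background; an epsilon guard on the strict inequality makes constant
regions background despite box-filter rounding.

The operating point of *k* depends on the contrast statistics of the
data: the criterion is the Pearson correlation between smoothed
intensity and the binary field over the cytosol, and the analysis is
insensitive to *k* over a wide band around that optimum (the
threshold-sweep stability test demonstrates this on phantoms). For the
bimodal stain distribution of real tomograms the optimum sits near
k ≈ 0.1; for the package's phantoms, whose background is water-flat, it
sits near k ≈ −0.4. `AnalysisConfig.k` therefore deserves a per-dataset
sweep rather than a blind default.

**Skeletonization.** The binarized foreground is reduced to a
one-voxel-wide skeleton by deleting voxels in ascending order of their
Euclidean distance transform, subject to three rules: a voxel is deleted
only if it is a *simple point* (removal preserves local topology under
26-connectivity for foreground / 6-connectivity for background), is not
a branch end (≤ 1 foreground neighbour), and is not the last contact of
its component with the bounding-box faces (filaments exiting the imaged
volume stay anchored). Ties in the distance transform break by
lexicographic (z, y, x) order, so the result is deterministic; the
simple-point test is memoized on the 26-bit neighbourhood configuration.
Because simple-point deletion never splits or merges components,
component labels are computed once and the anchor rule reduces to a
per-component anchor count.

**Stub pruning.** Terminal chains shorter than 4 nm — the smallest
expected structure — are removed, as are isolated speckle components
below that size. The stub walk recognizes *redundant attachment*
voxels (a chain tip whose remaining neighbours form a single connected
run) so that diagonal-contact stubs are removed completely while genuine
junction voxels are retained.

**Graph construction.** Junction voxels (> 2 neighbours) are clustered
by 26-adjacency into nodes at their centre of mass; maximal chains of
degree-2 voxels become branches; chain ends become rank-1 nodes; isolated
voxels are dropped; isolated closed chains become self-loop branches on a
carrier node. Branch curves are smoothed once with the sliding kernel
(1, 2, 3, 2, 1)/9, pinned to the adjacent node positions, with the kernel
truncated and renormalized at the ends. Arc length is the polyline
segment sum; tortuosity is arc length over the Euclidean span (undefined
and excluded for closed branches). Branches touching the bounding-box
faces are flagged as artificial cuts: retained for connectivity, excluded
from length/tortuosity statistics. The graph is a true multigraph —
parallel branches and self-loops occur in dense meshes and are kept.

**Distance field.** The Euclidean distance transform of the cytosol with
respect to everything else (membrane, ER, PSD, organelles). One pitch is
subtracted from the centre-to-centre transform so the field vanishes at
boundary-adjacent voxels. The normalized central-difference gradient
points from the membrane toward the interior and is the reference
direction for branch orientations (angles folded to [0°, 90°], averaged
along each branch). `dt_norm` rescales by the per-domain maximum for
"relative depth" profiles. Open bounding-box faces are not membrane:
the field simply continues there.

**Volume fraction.** The skeleton is rasterized, convolved with a 3D
Gaussian of σ = 4 nm, and thresholded at `exp(−1/2)` of the peak
response of an infinite line (in voxel units,
`exp(−1/2)·pitch²/(2πσ²)`), which reconstructs tubes of radius σ — i.e.
8 nm diameter filaments.

**Neck width.** The neck's principal axis is found by PCA of its voxel
coordinates; voxels are binned into one-pitch slabs along that axis, each
slab's maximal inscribed radius is its largest centre-to-boundary
distance, and the neck width is twice the smallest slab radius. This is
a discrete minimum-over-medial-axis estimate; it replaces interactive
measurement and agrees with closed-form cylinders and hourglasses to
within two pitches.

**Branching angles.** At each rank-3 node the tangent of each incident
branch is the first principal direction of the first three curve points
(starting at the node), oriented into the branch. The three pairwise
angles are sorted; their sum (≤ 360°) measures planarity. The
standardized frame maps the vector with the largest summed angle to
(−1, 0, 0), puts the vector forming the globally intermediate pairwise
angle into the z = 0 plane with positive y (falling back to the
larger-angle partner when the intermediate angle is between the other
two), and reflects the third vector to non-negative elevation; pairwise
angles are preserved exactly and the construction is invariant under
rotations and mirror images.

**Elementary loops.** For every node *v*, Dijkstra (weighted by branch
length, parallel edges collapsed to their minimum for pathfinding) runs
between every pair of neighbours on the graph without *v*; the loop adds
back the two incident branches. Parallel branch pairs give two-node
loops, self-loops one-node loops. Deduplication keys on the frozen set
of branch ids, so the result is independent of iteration order. Loop
geometry: PCA of member-node positions; planarity is the in-plane
variance fraction, elongation ε the SD ratio of the first two components
(axis-length, not variance, ratio). The pore estimate is
`circumference/(π·ε) − filament diameter`, clipped at zero.

**Spanning trees.** Per connected component, a minimum spanning tree
under edge weight 1/length drops short branches (putative cross-links)
first; self-loops can never be tree edges. Rank-2 nodes left by pruning
are merged by concatenating their two branches (a pure rank-2 cycle
resolves to a self-loop on a carrier node). Reduction percentages count
the merged graph, so "branch reduction" includes both dropped branches
and merged pairs — the convention that matches the reported
density-vs-tree comparisons.

**Null models.** Uniform directions are normalized 3D Gaussian draws
(exactly uniform on the sphere). The random-orientation reference is the
sin(α) law with mean exactly 1 rad = 57.2958°. The random-branching
reference sorts the three pairwise angles of independent uniform triples
(10⁵ triples by default). The rigid-rod model samples cos α uniformly on
[0, min(1, 2d/L)] — the exact conditional law for rods not crossing a
flat wall — and has the closed form
`(1 − sin α₀ + α₀ cos α₀)/cos α₀` with `α₀ = arccos(min(1, 2d/L))`.
Buckling force is `π²κ/L²` with κ = 0.040 pN·μm². Tortuosity *t* maps to
the isosceles base angle `arccos(1/t)`. The branch-end clustering test
compares observed nearest-neighbour distances of rank-1 nodes within
10 nm of the membrane against uniformly placed points in the same shell
(distinct voxels, jittered within voxels) with a two-sided Mann–Whitney
U test.

## The synthetic phantom

The generator is the package's test bed: a spherical head on a capsule
neck opening onto a flat dendrite face (membrane shell, optional ER
inclusion and PSD cap), a ground-truth filament network grown inside the
cytosol, and a tomogram-like rendering.

Growth model: filaments nucleate at the membrane or in voids (sites at
least one separation radius from all existing filaments — void-directed
nucleation keeps the mesh spatially uniform, matching the observed
homogeneity of real spines), extend as persistent random walks whose
curvature is calibrated through the worm-like-chain relation to hit the
target tortuosity, and insert 3-way junctions at contour spacings of
`min_branch_spacing + Exp(mean − min)`. At each junction the mother
continues straight and the daughter leaves at the configured law
(planar 70°/110°/180° by default, i.e. 70° from the continuation);
the first segment of both children is laid down exactly, so the
realized angle law is exact. Unrelated filaments are sterically
excluded (default 12 nm between axes — the spacing implied by a 20–30%
tube volume fraction at 8 nm diameter); a blocked filament redirects
or, if shorter than the branch spacing, retracts entirely
(depolymerization), dissolving its junction via a rank-2 merge.
Cross-links are short straight connectors between nearby filaments,
snapping onto a junction within one filament radius (the rank-4
mechanism) or splitting branches at points that keep both pieces above
0.6 of the mean branch length. The default cross-link rate of 0.4 per
junction reproduces the loop richness implied by the measured rank
prevalences (72/20/6/2% for ranks 3/4/5/6+, 34% ends) together with the
~41% branch reduction under MST pruning: those numbers give roughly
0.4 independent cycles per junction.

Rendering: filament curves become tubes of 8 nm diameter with unit
absorption contrast over the cytosol (membrane, ER and PSD get their own
stain levels), blurred by a Gaussian PSF, overlaid with a sinusoidal
luminance drift along z, plus i.i.d. Gaussian voxel noise, clipped to
[−1, 3]. A flag flips to luminance polarity (filaments dark).

**What the phantom does not model.** Tilt-series/missing-wedge
anisotropy, stain granularity, the diffuse cytoplasmic stain of
aldehyde-fixed tissue (phantom water is flat at zero — which is why the
correlation-optimal k is negative here and positive on real data),
membrane-parallel alignment of filaments touching the surface, and
filament identity across junctions. Passing phantom tests therefore
validates the *machinery* — topology preservation, graph extraction,
statistics — not the biology of any particular spine.

**Resolvability and the recovery benchmark.** At 2 nm pitch an 8 nm
tube occupies 4 voxels across; two junctions closer than ~12 nm merge
into one skeleton blob, and structure below ~10 nm cannot be recovered
by any pipeline at this resolution (the package's resolvability test —
two parallel tubes 20 nm apart — marks the scale where separation is
safe). The end-to-end recovery benchmark therefore uses a phantom in
the *resolvable regime*: quasi-uniform mesh, 15 nm steric separation,
at least 14 nm between junctions, junction density at the lower end of
the measured range (~0.9×10⁵ μm⁻³), rendered at SNR ≈ 10 with k chosen
by the correlation criterion. Under those conditions the full pipeline
recovers junction count, mean branch length and rank-3 fraction within
the stated tolerances (20%, 15%, 10 points), averaged over three
replicates. Denser phantoms at the in-situ-typical 1.3×10⁵ μm⁻³ with 8 nm
minimum spacing produce meshes whose tube *union* has different
topology from the generating curve network (tubes touch), so graph-level
recovery is not a well-posed goal there; the statistics the package
reports for such volumes are properties of the imaged union — exactly as
for real tomograms.

## Problem sizes

Tests and examples use spine phantoms of roughly 0.0016–0.003 μm³
(~10⁶ voxels), a few hundred junctions each — small enough for the whole
suite to run in a few minutes while leaving every statistic with a few
hundred samples. Monte-Carlo references default to 10⁵ draws
(standard errors well below the 0.5° comparison tolerance).

## Known limitations

- The thinning is O(foreground voxels × neighbourhood work) in pure
  Python with memoized simple-point tests; volumes much beyond ~10⁷
  foreground voxels call for chunking.
- Recovered branch lengths carry a small digitization bias (~+5%
  for oblique straight tubes) inherited from voxel-centre polylines;
  the single-pass curve smoothing removes most but not all staircase
  excess.
- The neck-width estimator assumes an approximately straight neck
  (PCA axis); strongly curved necks would need a geodesic axis.
- Growth can saturate below very high junction-density targets when
  steric exclusion leaves no admissible sites; the generator tops up in
  rounds and accepts 90% of target with a warning, erroring below that.
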