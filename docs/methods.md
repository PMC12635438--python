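# Methods

This note documents the models and algorithms implemented in `mitoscape`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-phantom validation does and does not
establish about real microscopy data.

## Conventions

Volumes are 3D integer grids in fixed (z, y, x) axis order — the microscopy
stack convention — with 0 as background. Voxel spacing is stored in the
same order in µm; all lengths, surfaces and volumes are physical (µm, µm²,
µm³). Coordinates are 0-based voxel indices. Binary masks contain {0, 1}.
TIFF (ImageJ metadata carries spacing) and plain NRRD (raw/gzip) are read
and written; 3DSlicer `.seg.nrrd` segment metadata is out of scope — such
files are expected to be exported as plain label volumes first.

## Distance maps

`geodesic_dist` solves the unit-speed eikonal equation restricted to a
binary mask, with the marker as the zero level set. The solver is
fast marching with a second-order upwind stencil per axis (falling back to
first order where only one upwind value is frozen), honoring anisotropic
spacing. Two accuracy measures:

- Near a point-like marker, any gridded upwind scheme commits an O(1)
  relative error in its first shells. The marker's near field (by default
  within 5 voxel pitches) is therefore frozen at its exact anisotropic
  Euclidean distance wherever the straight segment to the nearest marker
  voxel stays inside the mask — a provably correct value, since the
  free-space distance is both a lower bound on the geodesic and attained
  when the line of sight is unobstructed. With this initialization the
  solver is within 2% of the exact distance everywhere on convex masks and
  within a fraction of a percent along tubes.
- Second-order extrapolation is disabled across the marker itself
  (distance 0), where the front is kinked and extrapolation underestimates.

A Dijkstra solver on the 26-connected voxel graph with physical edge
weights (`method="dijkstra"`) is kept as an independent cross-check; note
its chordal metric overestimates true geodesics by up to ~8% in the worst
off-lattice directions, so comparisons in tests are made on tube phantoms
and away from the marker.

Mask voxels disconnected from the marker are flagged *unreached* (NaN in
the map, counted in `n_unreached`, excluded from downstream aggregation
with a warning) rather than silently zeroed. Marker voxels outside the
mask are projected onto marker∩mask; an empty intersection is an error.

`euclidean_dist` is the exact anisotropic Euclidean distance transform,
appropriate for landmarks with no intervening obstacles (e.g. the
ventricular surface in tissue); an optional domain restricts reporting.

## Compartments

`cell_annotation` decomposes cell∖soma into 26-connected candidates. A
candidate's **length** is the maximum geodesic distance-from-soma attained
inside it — measured against the soma mask passed in, which makes the
process set stable under re-running with the updated soma. Candidates
shorter than `min_process_len` (default 2 µm, the absorption threshold for
minor protrusions) are merged into label 1 ("updated soma"); the survivors
are labeled 2, 3, … in decreasing length (ties broken by ascending first
voxel index). Components not connected to the soma (segmentation debris)
are dropped with a warning, so voxel conservation (Σ labels = cell mask)
holds exactly for connected cells.

`apical_progenitor_compartment_annotation` additionally tags polarity. The
attachment region of a process is the set of its voxels 26-adjacent to the
updated soma. A process is *apical* when the mean landmark distance of its
attachment is smaller than the soma reference distance, else *basal*; only
the attachment decides, so a basal process bending toward the landmark
stays basal. The soma reference statistic is configurable
(`soma_reference="centroid"`, the default: landmark distance at the updated
soma's centroid voxel; or `"mean"` over all soma voxels) because the exact
statistic is a genuinely open choice; centroid is the simplest reading and
the two agree for compact somas.

## Skeleton graphs

Binary structures are thinned with 3D homotopic (Lee-style) thinning from
scikit-image; anisotropy is ignored at thinning time and honored at the
graph stage, where each skeleton voxel becomes a node and each 26-adjacent
pair an edge with physical length. Homotopic thinning can annihilate small
round blobs outright; any input component whose skeleton would vanish gets
its central voxel restored, preserving the component count. The thinning
algorithm is deliberately swappable behind `skeletonize`.

Branches are maximal degree-2 chains between endpoint (degree 1) /
junction (degree > 2) nodes; an isolated cycle is one branch; an isolated
voxel yields zero branches (length 0 — a punctum candidate). In junction
clusters (mutually adjacent junction-class voxels) each chain terminates at
the first junction voxel; no junction merging is performed. The barycenter
is the node minimizing Σ shortest-path distances within its component, with
deterministic tie-breaking toward the lowest (z, y, x); it is validated
against a brute-force all-pairs oracle.

## Strahler analysis

The cell skeleton is made acyclic by a minimum spanning tree whose edge
weight is the mean of the two node distances-from-soma (a `max` reduction
is available) — within every cycle the most distal edge is removed, so
apparent loops open at the side away from the soma. The root of each
component is the end node with minimum soma distance (ties: lowest
(z, y, x)); a root mask can override this for cases like the radial-glia
endfoot, where the root is the end node nearest the mask. Orders follow the
branch-level recurrence: leaf branches 1, a parent takes the maximum of its
children's orders, +1 only when at least two attain it. Orders are assigned
per branch and painted onto member nodes; junction nodes shared between
branches take their root-side branch's attributes so node annotations are
single-valued. The branch table carries branch id, component, order, length
and (when an annotation is given) the majority compartment of the branch's
nodes; the skeleton is computed on the full cell mask, so branches inside
the soma appear with compartment = soma.

`annotate_from_network` paints every cell voxel with the order (or branch
id) of its nearest skeleton node under the anisotropic metric (feature
transform); background is untouched and every cell voxel receives a label.

## Mitochondrial elements

Elements are 26-connected components of the binary mitochondria volume.
Per element:

- **volume** — positive voxels × voxel volume (exact by definition);
- **surface** — 13-direction Crofton estimate: transitions along each
  direction's line grid, weighted by the spherical-Voronoi area fractions
  of the 26 physical direction vectors (computed with
  `scipy.spatial.SphericalVoronoi`), which handles anisotropic spacing
  naturally. Accuracy on digital balls of realistic size is ~0.5%,
  cross-checked against marching-cubes mesh area;
- **length** — Σ skeleton branch lengths (= Σ edge lengths). This is the
  field-standard skeleton measure; on obliquely oriented thin rods the
  26-step staircase of the thinned centerline inflates or deflates it with
  a heavy tail (±20% worst case on short capsules, ~7% mean — measured on
  spherocylinder phantoms). Smoothing the skeleton would bias topology and
  is deliberately not done;
- **diameter** — mean over skeleton voxels of twice the Euclidean distance
  to the element boundary (local thickness on the centerline);
- **sphericity** — ψ = π^⅓(6V)^⅔ / A, the standard definition (1 for a
  ball); Crofton bias can push digitized balls slightly above 1 (bounded by
  1.1 in tests);
- **center** — the graph barycenter of the element's skeleton; for elements
  whose skeleton is a single voxel, that voxel.

Classification: any element with ≥ 1 junction is a *network*; unbranched
elements are *punctus* when ψ ≥ `sphericity_threshold` and *rod* otherwise.
The threshold (default **0.8**) is the single free classification
parameter; with phantom geometries (balls r 0.25–0.4 µm vs. capsules
L ≥ 1.2 µm, r ≤ 0.18 µm) the two classes sit well on either side of it
(≈ 1.0 vs ≤ 0.79). An unbranched rod has `n_branches == 1`; a single-voxel
punctum has 0 branches and length 0.

## Aggregation

Two volume accountings coexist by design: the per-compartment aggregate
mitochondrial volume counts every mito voxel in the compartment it lies in
(voxel-wise, exactly conserving the total), while element counts, class
fractions and features are assigned to the compartment at the element's
barycenter. The two differ only for boundary-spanning elements; both are
reported. Elements whose center falls on background are flagged unassigned,
excluded from compartment aggregates, and counted in the QC report.
Mitochondria outside the cell mask are clipped before analysis by default
(the clipped volume is reported in QC), which also keeps density =
mito/compartment volume in [0, 1]. Density uses the full compartment
volume; a nucleus-excluded variant can be had by passing a compartment
labeling with the nucleus carved out. Element-level distance is the
distance-map value at the center voxel.

`process_analysis` histograms process and mito∩process voxels into
half-open bins [k·b, (k+1)·b) of thickness b (default **0.5 µm**) on any
reference distance map — soma distance for along-process profiles,
lysosome distance for proximity densities. Bin sums conserve voxel counts
exactly; non-perpendicular subsections of twisted processes deform bins
slightly, which is accepted. Unreached voxels are excluded with a warning.

`picture_analysis` automates multi-cell images: each cell label is cropped
to its padded bounding box (the analysis is cropping-invariant; centers are
reported in full-image coordinates), annotated, and analyzed; extracellular
mitochondria are reported in QC. `filter_by_volume` retains elements with
volume ≥ threshold (≥ at the boundary); the default is off (0), with
0.05 µm³ recommended only for comparisons against pipelines that apply that
cutoff implicitly.

## Phantoms

The phantom generator is the test and demo backbone. It rasterizes
ellipsoidal somas, curved tubular processes (polyline paths dilated by a
radius), nuclei, planar landmarks, and mitochondria primitives — balls,
spherocylinders, Y-tubes — each with analytic volume, length, diameter and
class. Rasterization sets a voxel iff its center (at index × spacing) lies
inside the primitive; recovery tolerances in tests budget for this
discretization. Mitochondrial primitives that overlap or touch under
26-adjacency are rejected so ground-truth rows map 1:1 onto labeled
components. Default spacings: isotropic 0.05 µm for feature-accuracy
phantoms; anisotropic (0.35, 0.14, 0.14) µm for realism phantoms, matching
the axial/lateral resolution regime of Airyscan confocal stacks.
`random_population` builds reproducible populations with exact class
counts (largest-remainder apportionment) on jittered grid slots.

Phantoms are binarized-world objects: no point-spread function, noise,
intensity variation, or segmentation error is simulated, because the
pipeline contract starts at masks. Passing phantom tests therefore
establishes the correctness of the geometry and graph computations given a
segmentation, not the robustness of any upstream binarization.

## Problem sizes in tests

The shipped suite and acceptance script use phantom volumes up to ~95 × 80
× 80 voxels, 100 random graphs ≤ 200 nodes (barycenter) and ≤ 500 nodes
(Strahler), 50 random spherocylinders, and a 50-element class-mix
population split over two cells — sizes chosen so the full validation runs
in well under a minute while every code path (anisotropy, loops, junction
clusters, unreached voxels, multi-cell images) is exercised.

## Known limitations

- Geodesic distance through thick varicosities slightly underestimates the
  centerline path (the front cuts the inner side); no correction applied.
- Skeleton-length staircase error (above); lengths of near-voxel-scale
  elements are quantized.
- Dijkstra mode is an oracle/fallback, not metric-exact off-lattice.
- No intensity-based analysis anywhere: inputs are segmentations, and
  upstream binarization choices dominate real-data variance.
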