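# mitoscape

Graph-based 3D quantification of mitochondrial morphology and subcellular
localization at single-cell resolution, plus whole-cell branch (Strahler)
morphometry.

## The problem

Mitochondria in developing neural tissue — apical radial glia, neurons,
cultured cell lines — range from isolated spherical *punctae* through
elongated *rods* to branched *networks*, and their position within a cell
(soma vs. apical/basal process, proximal vs. distal) carries biological
meaning. Quantifying this requires measuring, for every mitochondrial
element in a pre-segmented 3D stack: its shape (length, volume, surface,
branching, diameter, sphericity), its morphology class, and its location
relative to cellular landmarks — where "distance" must follow the cell's
geometry (a geodesic along a curved process), not a straight line through
background.

`mitoscape` consumes labeled volumes produced by any upstream segmentation
(cells, somas/nuclei sharing their cell's label, a binary mitochondria
mask, optional landmarks such as the ventricular surface or lysosomes)
together with the physical voxel spacing (z, y, x, in µm; anisotropy is
honored everywhere), and produces compartment labelings, distance maps,
Strahler-ordered skeletons, and per-compartment / per-element result
tables.

## Core methods

- **Geodesic distance maps** solve the unit-speed eikonal equation
  |∇T| = 1 restricted to the cell mask, with the marker (nucleus, soma,
  tip…) as zero level set, via second-order upwind fast marching on the
  anisotropic grid; a Dijkstra solver on the 26-connected voxel graph with
  physical edge weights serves as an independent oracle. Euclidean maps use
  the exact anisotropic distance transform.
- **Compartment identification** labels the soma 1 and each process 2, 3, …
  (by decreasing length, measured as the maximum geodesic distance-from-soma
  attained inside the process). Minor processes shorter than a threshold
  (default 2 µm) are absorbed into the soma. Against a landmark, each
  process is tagged *apical* or *basal* by the position of its attachment to
  the soma — a basal process that bends toward the landmark stays basal.
- **Skeleton graphs**: binary structures are thinned to a centerline; every
  skeleton voxel becomes a node, every 26-adjacent pair an edge of physical
  length ℓ = √((Δz·dz)² + (Δy·dy)² + (Δx·dx)²). Branches are maximal
  degree-2 chains; the element's center is the **graph barycenter** — the
  node minimizing Σ shortest-path distances to all other nodes.
- **Strahler ordering**: the most distal branches are order 1, and a parent
  branch's order is max(children), +1 only when ≥ 2 children attain it.
  Cycles are opened by a minimum spanning tree weighted by distance-from-soma
  (loops open at their most distal side); the root is the end node nearest
  the soma (or a user-supplied root mask).
- **Element morphometry**: volume = positive voxels × voxel volume; surface
  by the 13-direction Crofton formula (anisotropy-aware); diameter = mean
  local thickness (2 × EDT) sampled on the centerline; sphericity
  ψ = π^⅓(6V)^⅔ / A. Classification: branched ⇒ *network*; unbranched with
  ψ ≥ 0.8 ⇒ *punctus*; else *rod* (the 0.8 threshold is the one free
  classification parameter).
- **Aggregation**: each element is assigned to the compartment at its
  barycenter; per-compartment tables report voxel-wise mitochondrial volume
  and density plus center-based element counts and class fractions; volume
  profiles histogram process and mitochondrial volume in distance bins
  (default 0.5 µm) along any reference distance map.

Everything is validated end-to-end on synthetic phantoms (ellipsoidal somas
with curved tubular processes, nuclei, planar landmarks, and
ball/spherocylinder/Y-tube mitochondria with analytic ground truth) — no
external data needed.

## Worked example

Generate an apical-progenitor-like phantom (soma at 10 µm from a ventricle
plane, an 8 µm apical and a 5 µm basal process, a 1 µm stub, two somatic
punctae and one rod per process) and run the pipeline:

```python
from mitoscape import (phantoms, apical_progenitor_compartment_annotation,
                       cell_analysis)

vols = phantoms.rasterize(phantoms.rgc_phantom())
lab = apical_progenitor_compartment_annotation(
    vols.cell, vols.soma, vols.landmark, vols.cell.spacing)
print(lab.to_table().to_string(index=False))
```

```
 process  length_um  n_voxels polarity
       2   7.808802      3019   apical
       3   5.092423      1902    basal
```

The 1 µm stub was absorbed into the soma (below the 2 µm threshold); the
two real processes are recovered with the correct polarity and lengths
(7.8 and 5.1 µm vs. the constructed 8 and 5 µm — process tips are rounded
by the tube caps). Then:

```python
res = cell_analysis(vols.mito, lab, lab.soma_dist, vols.cell.spacing)
print(res.element_table[["element_id", "class", "length_um", "volume_um3",
                         "diameter_um", "sphericity", "compartment",
                         "distance_from_soma_um"]].round(3).to_string(index=False))
```

```
 element_id   class  length_um  volume_um3  diameter_um  sphericity  compartment  distance_from_soma_um
          1     rod      1.600       0.162        0.400       0.786            2                    4.0
          2 punctus      0.200       0.174        0.617       1.050            1                    0.0
          3 punctus      0.000       0.094        0.447       1.036            1                    0.0
          4     rod      1.671       0.186        0.400       0.758            3                    1.4
```

Every element is classified correctly (punctae: sphericity > 0.8, no
branching; rods: elongated, sphericity < 0.8), measured diameters equal the
constructed 0.4 µm, and each element sits in its constructed compartment
(1 = soma, 2 = apical process at 4.0 µm geodesic distance from the soma,
3 = basal process). The companion compartment table aggregates volumes,
densities and class fractions per compartment.

The same pipeline is available from the shell (`mitoscape phantom`,
`mitoscape dist`, `mitoscape compartments`, `mitoscape strahler`,
`mitoscape mito`, `mitoscape analyze`); see `mitoscape --help`.

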