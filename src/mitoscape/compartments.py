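"""Split a segmented cell into soma + individually labeled processes.

The cell∖soma residue is decomposed into 26-connected candidate processes;
each candidate's length is the maximum geodesic distance-from-soma attained
inside it. Minor processes shorter than a threshold (default 2 µm) are
absorbed into the soma ("updated soma"); surviving processes are labeled
2, 3, … in decreasing length order. For apical progenitors, each process is
additionally tagged apical or basal by comparing its attachment region's
distance from a tissue landmark (the ventricular surface) with the soma's
— only the attachment decides, so a basal process that bends toward the
ventricle stays basal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .distance import DistanceMap, euclidean_dist, geodesic_dist
from .volumes import LabeledVolume, VoxelSpacing

log = logging.getLogger(__name__)

__all__ = [
    "ProcessInfo",
    "CompartmentLabeling",
    "cell_annotation",
    "apical_progenitor_compartment_annotation",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

SOMA_LABEL = 1


@dataclass
class ProcessInfo:
    label: int
    length_um: float
    n_voxels: int
    attachment: np.ndarray  # (N, 3) voxel indices 26-adjacent to the updated soma
    polarity: str | None = None  # "apical" | "basal" | None


@dataclass
class CompartmentLabeling:
    """0 = background, 1 = soma (incl. absorbed minor processes), 2.. = processes."""

    grid: np.ndarray
    spacing: VoxelSpacing
    processes: list[ProcessInfo] = field(default_factory=list)
    soma_dist: DistanceMap | None = None  # geodesic distance-from-soma, kept for reuse

    @property
    def shape(self):
        return self.grid.shape

    @property
    def n_processes(self) -> int:
        return len(self.processes)

    def as_volume(self) -> LabeledVolume:
        return LabeledVolume(self.grid, self.spacing)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "process": p.label,
                "length_um": p.length_um,
                "n_voxels": p.n_voxels,
                "polarity": p.polarity if p.polarity is not None else "",
            }
            for p in self.processes
        ]
        return pd.DataFrame(rows, columns=["process", "length_um", "n_voxels", "polarity"])


def _binary(vol, name: str) -> np.ndarray:
    if isinstance(vol, LabeledVolume):
        return vol.require_binary()
    arr = np.asarray(vol)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def cell_annotation(
    cell,
    soma,
    spacing,
    min_process_len: float = 2.0,
) -> CompartmentLabeling:
    """Label the soma 1 and every surviving process 2.. (decreasing length).

    ``min_process_len`` (µm) is the absorption threshold: candidate
    processes whose maximum distance-from-soma is below it are reassigned
    to the soma. Residual components not connected to the soma
    (segmentation debris) are dropped with a warning.
    """
    cell_b = _binary(cell, "cell")
    soma_b = _binary(soma, "soma")
    if cell_b.shape != soma_b.shape:
        raise ValueError("cell and soma shapes differ")
    if not cell_b.any() or not soma_b.any():
        raise ValueError("empty cell or soma mask")
    spacing = VoxelSpacing.coerce(spacing)
    if (soma_b & ~cell_b).any():
        n = int((soma_b & ~cell_b).sum())
        log.warning("soma extends %d voxel(s) outside the cell; clipping", n)
        soma_b = soma_b & cell_b
        if not soma_b.any():
            raise ValueError("soma does not intersect the cell")

    dist = geodesic_dist(cell_b, soma_b, spacing)

    residue = cell_b & ~soma_b
    labels = np.zeros(cell_b.shape, dtype=np.int32)
    labels[soma_b] = SOMA_LABEL
    comp_lab, n_comp = ndimage.label(residue, structure=_STRUCT_26)
    candidates = []  # (length, first_flat_index, component id)
    for c in range(1, n_comp + 1):
        sel = comp_lab == c
        d = dist.values[sel]
        if not np.isfinite(d).any():
            log.warning(
                "dropping %d voxel(s) of cell residue not connected to the soma",
                int(sel.sum()),
            )
            continue
        length = float(np.nanmax(d))
        if length < min_process_len:
            labels[sel] = SOMA_LABEL  # absorbed minor process
        else:
            first = int(np.flatnonzero(sel.ravel())[0])
            candidates.append((length, first, c))
    # decreasing length; ties broken by ascending first voxel index
    candidates.sort(key=lambda t: (-t[0], t[1]))

    soma_updated = labels == SOMA_LABEL
    soma_dilated = ndimage.binary_dilation(soma_updated, structure=_STRUCT_26)
    processes: list[ProcessInfo] = []
    for i, (length, _first, c) in enumerate(candidates):
        lab = i + 2
        sel = comp_lab == c
        labels[sel] = lab
        attach = np.argwhere(sel & soma_dilated)
        processes.append(
            ProcessInfo(label=lab, length_um=length, n_voxels=int(sel.sum()), attachment=attach)
        )
    return CompartmentLabeling(labels, spacing, processes, soma_dist=dist)


def apical_progenitor_compartment_annotation(
    cell,
    soma,
    landmark,
    spacing,
    min_process_len: float = 2.0,
    soma_reference: str = "centroid",
) -> CompartmentLabeling:
    """Run :func:`cell_annotation`, then tag each process apical or basal.

    A process is apical when its attachment region lies closer to the
    landmark (Euclidean distance) than the soma reference point does, else
    basal. ``soma_reference`` selects the soma statistic the attachment is
    compared against: ``"centroid"`` (default) uses the landmark-distance
    at the updated soma's centroid voxel; ``"mean"`` uses the mean landmark
    distance over all updated-soma voxels.
    """
    landmark_b = _binary(landmark, "landmark")
    if not landmark_b.any():
        raise ValueError("empty landmark")
    labeling = cell_annotation(cell, soma, spacing, min_process_len=min_process_len)
    spacing = labeling.spacing
    ldist = euclidean_dist(landmark_b, spacing).values

    soma_sel = labeling.grid == SOMA_LABEL
    if soma_reference == "centroid":
        centroid = np.round(ndimage.center_of_mass(soma_sel)).astype(int)
        centroid = np.clip(centroid, 0, np.array(soma_sel.shape) - 1)
        d_soma = float(ldist[tuple(centroid)])
    elif soma_reference == "mean":
        d_soma = float(ldist[soma_sel].mean())
    else:
        raise ValueError(f"unknown soma_reference {soma_reference!r}")

    for p in labeling.processes:
        if len(p.attachment) == 0:
            p.polarity = None
            continue
        d_attach = float(ldist[tuple(p.attachment.T)].mean())
        p.polarity = "apical" if d_attach < d_soma else "basal"
    return labeling
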