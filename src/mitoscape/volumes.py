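"""Labeled and binary 3D volumes with physical voxel spacing.

Axis order is fixed as (z, y, x) throughout the package, matching the
microscopy stack convention; spacing is stored in the same order and all
physical quantities are expressed in µm / µm² / µm³. Coordinates are
0-based voxel indices.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from . import _nrrd

log = logging.getLogger(__name__)

__all__ = [
    "VoxelSpacing",
    "LabeledVolume",
    "PairingReport",
    "read_volume",
    "write_volume",
    "validate_pairing",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical edge lengths of one voxel, in µm, ordered (z, y, x)."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel spacing {name}={v!r} must be finite and > 0")
            object.__setattr__(self, name, v)

    @property
    def tuple(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dz * self.dy * self.dx

    @classmethod
    def coerce(cls, spacing) -> "VoxelSpacing":
        if isinstance(spacing, VoxelSpacing):
            return spacing
        dz, dy, dx = spacing
        return cls(float(dz), float(dy), float(dx))


@dataclass
class LabeledVolume:
    """A 3D integer grid (0 = background) with voxel spacing.

    Carries cells, somas, nuclei, compartment labelings, or binary masks
    (binary volumes contain only {0, 1}).
    """

    grid: np.ndarray
    spacing: VoxelSpacing = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.dtype == bool:
            grid = grid.astype(np.uint8)
        if not np.issubdtype(grid.dtype, np.integer):
            if np.issubdtype(grid.dtype, np.floating) and np.all(grid == np.round(grid)):
                grid = grid.astype(np.int64)
            else:
                raise ValueError("label volume must hold integers")
        if grid.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) volume, got ndim={grid.ndim}")
        if grid.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.grid = grid
        if self.spacing is None:
            raise ValueError("missing spacing")
        self.spacing = VoxelSpacing.coerce(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the volume."""
        lab = np.unique(self.grid)
        return lab[lab > 0]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.grid, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        return self.grid > 0

    def require_binary(self) -> np.ndarray:
        if not self.is_binary:
            raise ValueError("expected a binary {0, 1} volume")
        return self.grid > 0


def _as_grid(vol) -> np.ndarray:
    return vol.grid if isinstance(vol, LabeledVolume) else np.asarray(vol)


def read_volume(path, spacing_override=None) -> LabeledVolume:
    """Read a 3D TIFF or NRRD label/binary volume.

    Spacing is taken from file metadata when present (ImageJ ``spacing`` +
    resolution tags for TIFF, ``spacings``/``space directions`` for NRRD),
    else from ``spacing_override``; an error is raised if neither is
    available.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = path.lower()
    if ext.endswith((".nrrd", ".nhdr")):
        grid, spacing = _nrrd.read(path)
    else:
        grid, spacing = _read_tiff(path)
    if grid.ndim == 4 and grid.shape[0] == 1:  # single-timepoint stack
        grid = grid[0]
    if grid.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {grid.shape}")
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise ValueError(f"{path}: missing spacing (no metadata and no override)")
    if not np.issubdtype(grid.dtype, np.integer):
        if np.all(grid == np.round(grid)):
            grid = grid.astype(np.int64)
        else:
            raise ValueError(f"{path}: non-integer labels in a label volume")
    return LabeledVolume(grid, VoxelSpacing.coerce(spacing))


def _read_tiff(path):
    with tifffile.TiffFile(path) as tif:
        grid = tif.asarray()
        spacing = None
        dz = dy = dx = None
        meta = tif.imagej_metadata or {}
        if "spacing" in meta:
            dz = float(meta["spacing"])
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                dx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                dy = den / num
        if dz is not None and dy is not None and dx is not None:
            spacing = VoxelSpacing(dz, dy, dx)
    return grid, spacing


def write_volume(vol: LabeledVolume, path) -> None:
    """Write a volume to TIFF (ImageJ metadata carries spacing) or NRRD."""
    path = os.fspath(path)
    grid = vol.grid
    sp = vol.spacing
    if path.lower().endswith((".nrrd", ".nhdr")):
        _nrrd.write(path, grid, sp)
        return
    # choose the narrowest unsigned dtype that holds the labels
    vmax = int(grid.max()) if grid.size else 0
    if vmax <= np.iinfo(np.uint8).max:
        out = grid.astype(np.uint8)
    elif vmax <= np.iinfo(np.uint16).max:
        out = grid.astype(np.uint16)
    else:
        out = grid.astype(np.uint32)
    tifffile.imwrite(
        path,
        out,
        imagej=out.dtype != np.uint32,
        photometric="minisblack",
        resolution=(1.0 / sp.dx, 1.0 / sp.dy),
        metadata={"spacing": sp.dz, "unit": "um", "axes": "ZYX"},
    )


def write_distance_tiff(values: np.ndarray, spacing: VoxelSpacing, path) -> None:
    """Write a float32 distance map; undefined/unreached voxels are NaN."""
    tifffile.imwrite(
        os.fspath(path),
        np.asarray(values, dtype=np.float32),
        imagej=True,
        resolution=(1.0 / spacing.dx, 1.0 / spacing.dy),
        metadata={"spacing": spacing.dz, "unit": "um", "axes": "ZYX"},
    )


@dataclass
class PairingReport:
    """Consistency report between a cell labeling and its nucleus/soma markers.

    Markers must carry the same label value as their cell; this reports cells
    without a marker, markers without a cell, and marker voxels lying outside
    the territory of their cell (reported, never repaired).
    """

    cells_without_marker: list[int]
    markers_without_cell: list[int]
    misplaced_voxels: dict[int, int]  # marker label -> count outside its cell
    misplaced_coords: dict[int, np.ndarray] = None  # marker label -> (N, 3) voxels

    @property
    def ok(self) -> bool:
        return (
            not self.cells_without_marker
            and not self.markers_without_cell
            and not self.misplaced_voxels
        )

    def messages(self) -> list[str]:
        out = [f"cell {c} has no marker" for c in self.cells_without_marker]
        out += [f"marker {m} has no cell" for m in self.markers_without_cell]
        out += [
            f"marker {m} has {n} voxel(s) outside cell {m}"
            for m, n in sorted(self.misplaced_voxels.items())
        ]
        return out


def validate_pairing(cells: LabeledVolume, markers: LabeledVolume) -> PairingReport:
    """Check the marker-label convention: each nucleus/soma shares its cell's label."""
    cg, mg = _as_grid(cells), _as_grid(markers)
    if cg.shape != mg.shape:
        raise ValueError(f"shape mismatch: cells {cg.shape} vs markers {mg.shape}")
    cell_labels = set(np.unique(cg[cg > 0]).tolist())
    marker_labels = set(np.unique(mg[mg > 0]).tolist())
    misplaced: dict[int, int] = {}
    coords: dict[int, np.ndarray] = {}
    for m in sorted(marker_labels):
        out = (mg == m) & (cg != m)
        n_out = int(np.count_nonzero(out))
        if n_out:
            misplaced[m] = n_out
            coords[m] = np.argwhere(out)
    return PairingReport(
        cells_without_marker=sorted(cell_labels - marker_labels),
        markers_without_cell=sorted(marker_labels - cell_labels),
        misplaced_voxels=misplaced,
        misplaced_coords=coords,
    )
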