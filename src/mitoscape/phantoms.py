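"""Synthetic 3D phantoms with exact ground truth for every pipeline stage.

Phantoms emulate the geometries the pipeline is built for: an ellipsoidal
soma with attached curved tubular processes, a nucleus inside the soma,
spherocylinder / ball / branched-tube mitochondria of known length,
diameter, volume and class placed at known positions, and a planar tissue
landmark (the ventricular surface). Rasterization rule: a voxel is set iff
its center (at ``index × spacing``, 0-based) lies inside the primitive —
tolerances in feature-recovery tests budget for this discretization.

Default spacings: isotropic 0.05 µm for feature-accuracy phantoms;
anisotropic (0.35, 0.14, 0.14) µm for realism phantoms, matching the axial
vs lateral resolution regime of Airyscan confocal stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabeledVolume, VoxelSpacing

__all__ = [
    "Ball",
    "Spherocylinder",
    "YTube",
    "Ellipsoid",
    "ProcessSpec",
    "PhantomSpec",
    "PhantomVolumes",
    "rasterize",
    "rgc_phantom",
    "hek_phantom",
    "random_population",
    "rasterize_primitive",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

ISOTROPIC = VoxelSpacing(0.05, 0.05, 0.05)
AIRYSCAN = VoxelSpacing(0.35, 0.14, 0.14)


def _seg_dist(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment p0–p1 (all in µm)."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ d / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


@dataclass(frozen=True)
class Ball:
    """Spherical punctum: center (z, y, x) µm, radius µm."""

    center: tuple
    r: float

    truth_class = "punctus"

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - np.asarray(self.center), axis=1) <= self.r

    @property
    def analytic_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.r**3

    @property
    def truth_length(self) -> float:
        return 0.0

    @property
    def truth_diameter(self) -> float:
        return 2.0 * self.r

    @property
    def bounds(self):
        c = np.asarray(self.center)
        return c - self.r, c + self.r

    @property
    def reference_point(self):
        return tuple(self.center)


@dataclass(frozen=True)
class Spherocylinder:
    """Capsule (rod): segment p0–p1 dilated by radius r; caps are hemispheres."""

    p0: tuple
    p1: tuple
    r: float

    truth_class = "rod"

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return _seg_dist(pts, np.asarray(self.p0), np.asarray(self.p1)) <= self.r

    @property
    def analytic_volume(self) -> float:
        L = float(np.linalg.norm(np.asarray(self.p1) - np.asarray(self.p0)))
        return np.pi * self.r**2 * L + 4.0 / 3.0 * np.pi * self.r**3

    @property
    def analytic_surface(self) -> float:
        L = float(np.linalg.norm(np.asarray(self.p1) - np.asarray(self.p0)))
        return 2.0 * np.pi * self.r * L + 4.0 * np.pi * self.r**2

    @property
    def truth_length(self) -> float:
        """Medial-axis length: the core segment (caps add no centerline)."""
        return float(np.linalg.norm(np.asarray(self.p1) - np.asarray(self.p0)))

    @property
    def truth_diameter(self) -> float:
        return 2.0 * self.r

    @property
    def bounds(self):
        a, b = np.asarray(self.p0), np.asarray(self.p1)
        return np.minimum(a, b) - self.r, np.maximum(a, b) + self.r

    @property
    def reference_point(self):
        return tuple(0.5 * (np.asarray(self.p0) + np.asarray(self.p1)))


@dataclass(frozen=True)
class YTube:
    """Branched tube (network): three capsules from a junction to three tips."""

    junction: tuple
    tips: tuple  # three (z, y, x) µm points
    r: float

    truth_class = "network"

    def contains(self, pts: np.ndarray) -> np.ndarray:
        j = np.asarray(self.junction)
        hit = np.zeros(len(pts), dtype=bool)
        for tip in self.tips:
            hit |= _seg_dist(pts, j, np.asarray(tip)) <= self.r
        return hit

    @property
    def truth_length(self) -> float:
        j = np.asarray(self.junction)
        return float(sum(np.linalg.norm(np.asarray(t) - j) for t in self.tips))

    @property
    def analytic_volume(self) -> float:
        # arms overlap near the junction; lower bound is the sum minus overlaps —
        # tests treat Y volumes as approximate, so report the capsule-sum
        j = np.asarray(self.junction)
        vol = 4.0 / 3.0 * np.pi * self.r**3  # junction ball counted once
        for t in self.tips:
            L = float(np.linalg.norm(np.asarray(t) - j))
            vol += np.pi * self.r**2 * L + 2.0 / 3.0 * np.pi * self.r**3
        return vol

    @property
    def truth_diameter(self) -> float:
        return 2.0 * self.r

    @property
    def bounds(self):
        pts = np.vstack([self.junction, *self.tips])
        return pts.min(axis=0) - self.r, pts.max(axis=0) + self.r

    @property
    def reference_point(self):
        return tuple(self.junction)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    radii: tuple  # (rz, ry, rx) µm

    def contains(self, pts: np.ndarray) -> np.ndarray:
        q = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return (q**2).sum(axis=1) <= 1.0

    @property
    def bounds(self):
        c, r = np.asarray(self.center), np.asarray(self.radii)
        return c - r, c + r


@dataclass(frozen=True)
class ProcessSpec:
    """Curved tubular process: polyline path (µm points) dilated by radius."""

    path: tuple  # tuple of (z, y, x) µm points
    r: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pts), dtype=bool)
        path = [np.asarray(p) for p in self.path]
        for a, b in zip(path[:-1], path[1:]):
            hit |= _seg_dist(pts, a, b) <= self.r
        return hit

    @property
    def bounds(self):
        pts = np.vstack(self.path)
        return pts.min(axis=0) - self.r, pts.max(axis=0) + self.r


@dataclass
class PhantomSpec:
    """Full scene description; the seed and spec fully determine the volumes."""

    shape: tuple
    spacing: VoxelSpacing
    soma: Ellipsoid
    nucleus: Ellipsoid | None = None
    processes: list = field(default_factory=list)  # ProcessSpec
    landmark_z_um: float | None = None  # planar landmark: voxels with z ≤ this
    mitochondria: list = field(default_factory=list)  # (primitive, compartment hint)
    seed: int = 0


@dataclass
class PhantomVolumes:
    cell: LabeledVolume
    soma: LabeledVolume
    nucleus: LabeledVolume | None
    landmark: LabeledVolume | None
    mito: LabeledVolume
    mito_labels: LabeledVolume
    truth: pd.DataFrame


def _voxel_centers(shape, spacing: VoxelSpacing, sl=None):
    sl = sl or tuple(slice(0, s) for s in shape)
    axes = [np.arange(s.start, s.stop) * d for s, d in zip(sl, spacing.tuple)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])


def rasterize_primitive(prim, shape, spacing: VoxelSpacing) -> np.ndarray:
    """Binary rasterization of one primitive on the voxel-center grid."""
    lo, hi = prim.bounds
    sp = np.asarray(spacing.tuple)
    start = np.maximum(np.floor(lo / sp).astype(int) - 1, 0)
    stop = np.minimum(np.ceil(hi / sp).astype(int) + 2, np.asarray(shape))
    if np.any(start >= stop):
        raise ValueError(f"primitive {prim!r} lies outside the volume")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(start, stop))
    pts = _voxel_centers(shape, spacing, sl)
    sub = prim.contains(pts).reshape(tuple(s.stop - s.start for s in sl))
    out = np.zeros(shape, dtype=bool)
    out[sl] = sub
    return out


def _to_voxel(point_um, spacing: VoxelSpacing):
    return tuple(int(round(p / d)) for p, d in zip(point_um, spacing.tuple))


def rasterize(spec: PhantomSpec) -> PhantomVolumes:
    """Deterministic rasterization + ground-truth table.

    Mitochondrial primitives that overlap or touch (26-adjacency) are
    rejected so ground-truth rows map 1:1 onto rasterized components.
    """
    sp = spec.spacing
    shape = tuple(spec.shape)

    soma = rasterize_primitive(spec.soma, shape, sp)
    cell = soma.copy()
    for proc in spec.processes:
        cell |= rasterize_primitive(proc, shape, sp)
    nucleus = None
    if spec.nucleus is not None:
        nucleus = rasterize_primitive(spec.nucleus, shape, sp) & soma

    landmark = None
    if spec.landmark_z_um is not None:
        landmark = np.zeros(shape, dtype=bool)
        k = max(int(np.floor(spec.landmark_z_um / sp.dz)), 0)
        landmark[: k + 1] = True

    mito = np.zeros(shape, dtype=bool)
    masks = []
    for prim, _hint in spec.mitochondria:
        m = rasterize_primitive(prim, shape, sp)
        if not m.any():
            raise ValueError(f"primitive {prim!r} rasterized to nothing")
        masks.append(m)
        mito |= m
    lab, n_comp = ndimage.label(mito, structure=_STRUCT_26)
    if n_comp != len(masks):
        raise ValueError(
            f"{len(masks)} mitochondrial primitives rasterized into {n_comp} "
            "connected components — primitives overlap or touch"
        )

    rows = []
    for (prim, hint), m in zip(spec.mitochondria, masks):
        ref = _to_voxel(prim.reference_point, sp)
        element_id = int(lab[ref]) or int(lab[m][0])
        rows.append(
            {
                "element_id": element_id,
                "class": prim.truth_class,
                "length_um": prim.truth_length,
                "volume_um3": prim.analytic_volume,
                "diameter_um": prim.truth_diameter,
                "n_voxels": int(m.sum()),
                "compartment": hint,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["element_id", "class", "length_um", "volume_um3", "diameter_um", "n_voxels", "compartment"],
    ).sort_values("element_id", ignore_index=True)

    as_vol = lambda g, dtype=np.uint8: LabeledVolume(g.astype(dtype), sp)  # noqa: E731
    return PhantomVolumes(
        cell=as_vol(cell),
        soma=as_vol(soma),
        nucleus=as_vol(nucleus) if nucleus is not None else None,
        landmark=as_vol(landmark) if landmark is not None else None,
        mito=as_vol(mito),
        mito_labels=LabeledVolume(lab.astype(np.int32), sp),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# presets


def rgc_phantom(
    spacing: VoxelSpacing = VoxelSpacing(0.2, 0.1, 0.1),
    stub_len_um: float = 1.0,
    seed: int = 0,
) -> PhantomSpec:
    """Apical-progenitor-like cell against a ventricular plane at z ≈ 0.

    Soma at z = 10 µm with a nucleus; an 8 µm apical process descending to
    the ventricle, a 5 µm basal process ascending (with a slight bend), and
    a short stub below the absorption threshold. Mitochondria: two punctae
    in the soma, one rod in each main process.
    """
    cy = cx = 4.0
    soma = Ellipsoid(center=(10.0, cy, cx), radii=(2.2, 2.0, 2.0))
    nucleus = Ellipsoid(center=(10.0, cy, cx), radii=(1.2, 1.1, 1.1))
    apical = ProcessSpec(path=((8.2, cy, cx), (0.4, cy, cx)), r=0.5)
    basal = ProcessSpec(
        path=((11.8, cy, cx), (14.5, cy + 0.6, cx), (16.6, cy + 1.2, cx)), r=0.5
    )
    stub = ProcessSpec(path=((10.0, cy + 1.8, cx), (10.0, cy + 1.8 + stub_len_um, cx)), r=0.4)
    mito = [
        (Ball(center=(9.4, cy - 0.9, cx - 0.7), r=0.35), "soma"),
        (Ball(center=(10.7, cy + 0.8, cx + 0.7), r=0.30), "soma"),
        (Spherocylinder(p0=(4.5, cy, cx), p1=(3.0, cy, cx), r=0.18), "apical"),
        (Spherocylinder(p0=(12.6, cy + 0.2, cx), p1=(14.3, cy + 0.56, cx), r=0.18), "basal"),
    ]
    shape = (
        int(round(19.0 / spacing.dz)),
        int(round(8.0 / spacing.dy)),
        int(round(8.0 / spacing.dx)),
    )
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        soma=soma,
        nucleus=nucleus,
        processes=[apical, basal, stub],
        landmark_z_um=0.2,
        mitochondria=mito,
        seed=seed,
    )


def hek_phantom(spacing: VoxelSpacing = ISOTROPIC, seed: int = 0) -> PhantomSpec:
    """Round cell with one element of each morphology class inside the soma."""
    soma = Ellipsoid(center=(3.0, 3.0, 3.0), radii=(2.7, 2.7, 2.7))
    mito = [
        (Ball(center=(2.0, 2.0, 2.0), r=0.3), "soma"),
        (Spherocylinder(p0=(4.0, 1.6, 3.8), p1=(4.0, 3.6, 3.8), r=0.15), "soma"),
        (
            YTube(
                junction=(2.6, 4.2, 2.4),
                tips=((2.6, 5.0, 1.6), (2.6, 5.0, 3.2), (2.6, 3.2, 2.4)),
                r=0.12,
            ),
            "soma",
        ),
    ]
    shape = tuple(int(round(6.0 / d)) for d in spacing.tuple)
    return PhantomSpec(shape=shape, spacing=spacing, soma=soma, mitochondria=mito, seed=seed)


def _exact_counts(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment: counts sum to n exactly."""
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def random_population(
    n_elements: int,
    class_mix=(0.3, 0.5, 0.2),
    seed: int = 0,
    spacing: VoxelSpacing = ISOTROPIC,
    n_cells: int = 1,
) -> list[PhantomSpec]:
    """Reproducible phantom population with exact per-class element counts.

    ``class_mix`` gives (punctae, rods, networks) fractions, which must sum
    to 1; elements are distributed round-robin over ``n_cells`` box-shaped
    cells and placed on a jittered grid so no two elements touch.
    """
    if not np.isclose(sum(class_mix), 1.0):
        raise ValueError("class_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_p, n_r, n_n = _exact_counts(n_elements, class_mix)
    kinds = ["punctus"] * n_p + ["rod"] * n_r + ["network"] * n_n
    rng.shuffle(kinds)

    per_cell = [kinds[i::n_cells] for i in range(n_cells)]
    specs = []
    pitch = 2.4  # µm between element slots; elements stay well clear of each other
    for ci, cell_kinds in enumerate(per_cell):
        n = len(cell_kinds)
        grid_n = max(int(np.ceil(n ** (1.0 / 3.0))), 1)
        extent = grid_n * pitch + 2.0
        # radius exceeds the half-diagonal, so the rasterized soma fills the
        # whole box and every element slot sits inside the cell
        soma = Ellipsoid(center=(extent / 2,) * 3, radii=(extent,) * 3)
        mito = []
        slots = [(i, j, k) for i in range(grid_n) for j in range(grid_n) for k in range(grid_n)]
        for kind, slot in zip(cell_kinds, slots):
            base = np.asarray(slot) * pitch + pitch / 2 + 1.0
            jitter = rng.uniform(-0.15, 0.15, size=3)
            c = base + jitter
            if kind == "punctus":
                prim = Ball(center=tuple(c), r=float(rng.uniform(0.25, 0.4)))
            elif kind == "rod":
                L = float(rng.uniform(1.2, 1.9))
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                half = axis * L / 2
                prim = Spherocylinder(
                    p0=tuple(c - half), p1=tuple(c + half), r=float(rng.uniform(0.12, 0.18))
                )
            else:
                r = float(rng.uniform(0.1, 0.14))
                tips = []
                for ang in (0.0, 2.1, 4.2):
                    direction = np.array(
                        [0.35, np.cos(ang + rng.uniform(0, 0.3)), np.sin(ang + rng.uniform(0, 0.3))]
                    )
                    direction /= np.linalg.norm(direction)
                    tips.append(tuple(c + direction * rng.uniform(0.7, 0.95)))
                prim = YTube(junction=tuple(c), tips=tuple(tips), r=r)
            mito.append((prim, "soma"))
        shape = tuple(int(np.ceil(extent / d)) + 1 for d in spacing.tuple)
        specs.append(
            PhantomSpec(
                shape=shape,
                spacing=spacing,
                soma=soma,
                mitochondria=mito,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
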