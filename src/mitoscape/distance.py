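"""Distance maps inside a cell mask (geodesic) or in free space (Euclidean).

The geodesic map solves the unit-speed eikonal equation restricted to a
binary mask, with the marker structure as the zero level set, honoring
anisotropic voxel spacing — shortest paths are forced to stay inside the
cell, so a distance measured along a curved process follows the process
rather than cutting across background. The Euclidean map is the exact
anisotropic distance transform, appropriate when nothing obstructs straight
lines (e.g. distance from a tissue landmark such as the ventricular
surface).

Two geodesic backends are provided: a first-order upwind fast-marching
solver (default) and Dijkstra on the 26-connected voxel graph with physical
edge lengths. Dijkstra overestimates true geodesics by up to ~8% in the
worst off-lattice direction; it is retained as an independent cross-check
and as a dependency-free fallback.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from .volumes import LabeledVolume, VoxelSpacing

log = logging.getLogger(__name__)

__all__ = ["DistanceMap", "geodesic_dist", "euclidean_dist"]


@dataclass
class DistanceMap:
    """Distances in µm, defined where ``mask`` is true.

    ``values`` is NaN outside the mask and on unreached voxels (mask
    components disconnected from the marker); ``unreached`` flags the
    latter explicitly so downstream aggregation can exclude them.
    """

    values: np.ndarray
    mask: np.ndarray
    marker: np.ndarray
    unreached: np.ndarray
    spacing: VoxelSpacing

    @property
    def n_unreached(self) -> int:
        return int(np.count_nonzero(self.unreached))

    def at(self, voxel) -> float:
        """Distance at a (z, y, x) voxel; NaN if outside mask or unreached."""
        return float(self.values[tuple(voxel)])


def _as_bool(vol, name: str) -> np.ndarray:
    if isinstance(vol, LabeledVolume):
        return vol.require_binary()
    arr = np.asarray(vol)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be a binary volume")
    return arr.astype(bool)


def geodesic_dist(mask, marker, spacing, method: str = "fmm") -> DistanceMap:
    """Geodesic distance from ``marker`` within ``mask`` (both binary, same shape).

    Marker voxels outside the mask are projected onto marker∩mask; if the
    intersection is empty an error is raised. Mask voxels not connected to
    the marker are flagged unreached.
    """
    mask_b = _as_bool(mask, "mask")
    marker_b = _as_bool(marker, "marker")
    if mask_b.shape != marker_b.shape:
        raise ValueError(f"shape mismatch: mask {mask_b.shape} vs marker {marker_b.shape}")
    if not mask_b.any():
        raise ValueError("empty mask")
    source = mask_b & marker_b
    if not source.any():
        raise ValueError("marker is disjoint from the mask")
    spacing = VoxelSpacing.coerce(spacing)
    if method == "fmm":
        dist = _fast_marching(mask_b, source, spacing)
    elif method == "dijkstra":
        dist = _dijkstra26(mask_b, source, spacing)
    else:
        raise ValueError(f"unknown method {method!r}")
    unreached = mask_b & ~np.isfinite(dist)
    if unreached.any():
        log.warning(
            "geodesic_dist: %d mask voxel(s) unreachable from the marker",
            int(unreached.sum()),
        )
    values = np.where(mask_b & np.isfinite(dist), dist, np.nan)
    return DistanceMap(values, mask_b, marker_b, unreached, spacing)


def euclidean_dist(marker, spacing, domain=None) -> DistanceMap:
    """Exact anisotropic Euclidean distance from ``marker`` (obstacle-free).

    If ``domain`` is given, values are reported only inside it; the
    transform itself is still computed in free space.
    """
    marker_b = _as_bool(marker, "marker")
    if not marker_b.any():
        raise ValueError("empty marker")
    spacing = VoxelSpacing.coerce(spacing)
    dist = ndimage.distance_transform_edt(~marker_b, sampling=spacing.tuple)
    if domain is not None:
        dom = _as_bool(domain, "domain")
        if dom.shape != marker_b.shape:
            raise ValueError("domain shape mismatch")
    else:
        dom = np.ones_like(marker_b, dtype=bool)
    values = np.where(dom, dist, np.nan)
    unreached = np.zeros_like(dom)
    return DistanceMap(values, dom, marker_b, unreached, spacing)


# ---------------------------------------------------------------------------
# fast marching


def _fast_marching(mask: np.ndarray, source: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Second-order upwind fast marching on the masked anisotropic grid.

    Per axis the scheme uses two upwind points when both are frozen and
    monotone (Sethian's second-order stencil), falling back to first order
    otherwise. The marker's 26-neighborhood is additionally frozen at its
    exact anisotropic Euclidean distance, removing the O(1) relative error
    a gridded scheme would otherwise commit right at a point-like marker
    (the sub-diagonal chords this trusts are the same ones the
    26-connectivity voxel metric permits). Returns +inf on unreachable
    mask voxels and on non-mask voxels.
    """
    # pad by two voxels so second-order neighbor access stays in bounds
    pad = 2
    m = np.pad(mask, pad).ravel()
    shape = tuple(s + 2 * pad for s in mask.shape)
    sz = shape[1] * shape[2]
    sy = shape[2]
    offsets = (sz, sy, 1)
    h = (spacing.dz, spacing.dy, spacing.dx)
    inv_h = tuple(1.0 / hh for hh in h)

    dist = np.full(m.shape, np.inf)
    src_flat = np.flatnonzero(np.pad(source, pad).ravel())
    dist[src_flat] = 0.0

    ring = _exact_near_field(mask, source, spacing)
    edt = ndimage.distance_transform_edt(~source, sampling=spacing.tuple)
    ring_flat = np.flatnonzero(np.pad(ring, pad).ravel())
    dist[ring_flat] = np.pad(edt, pad).ravel()[ring_flat]

    # `final` marks values fixed at initialization (exact; never relaxed);
    # `frozen` additionally grows as nodes are popped and become upwind-usable
    final = np.zeros(m.shape, dtype=bool)
    final[src_flat] = True
    final[ring_flat] = True
    frozen = final.copy()
    popped = np.zeros(m.shape, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, int(i)) for i in src_flat]
    heap += [(float(dist[i]), int(i)) for i in ring_flat]
    heapq.heapify(heap)

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        d, i = pop(heap)
        if popped[i]:
            continue
        popped[i] = True
        frozen[i] = True
        for off in offsets:
            for j in (i - off, i + off):
                if not m[j] or popped[j] or final[j]:
                    continue
                # per axis: (alpha, beta) of the upwind term (alpha·t − beta)²
                terms = []
                for ax, o in enumerate(offsets):
                    best = np.inf
                    ab = None
                    for sgn in (-1, 1):
                        j1 = j + sgn * o
                        if not frozen[j1]:
                            continue
                        d1 = dist[j1]
                        if d1 >= best:
                            continue
                        best = d1
                        j2 = j + 2 * sgn * o
                        ih = inv_h[ax]
                        # second order only over smooth, strictly interior
                        # values: extrapolating across the marker (dist 0)
                        # kinks the front and underestimates
                        if frozen[j2] and m[j2] and 0.0 < dist[j2] <= d1:
                            d2 = dist[j2]
                            ab = (1.5 * ih, (2.0 * d1 - 0.5 * d2) * ih, d1)
                        else:
                            ab = (ih, d1 * ih, d1)
                    if ab is not None:
                        terms.append(ab)
                t = _solve_eikonal2(terms)
                if t < dist[j]:
                    dist[j] = t
                    push(heap, (t, j))

    dist = dist.reshape(shape)[pad:-pad, pad:-pad, pad:-pad].copy()
    dist[~mask] = np.inf
    return dist


def _solve_eikonal2(terms: list[tuple[float, float, float]]) -> float:
    """Solve Σ (α_i·t − β_i)² = 1, growing the upwind set while consistent.

    ``terms`` holds ``(α_i, β_i, a_i)`` with ``a_i`` the first-order upwind
    value used for ordering/validity; terms are included in ascending order
    of ``a_i`` as long as the solution exceeds them.
    """
    if not terms:
        return np.inf
    terms.sort(key=lambda t: t[2])
    t = np.inf
    A = B = C = 0.0
    for k, (alpha, beta, a) in enumerate(terms):
        A += alpha * alpha
        B += alpha * beta
        C += beta * beta
        disc = B * B - A * (C - 1.0)
        if disc < 0:  # over-determined: keep the previous (smaller-set) solution
            break
        cand = (B + disc**0.5) / A
        if cand < a:  # must dominate every upwind value it uses
            break
        t = cand
        if k + 1 < len(terms) and t <= terms[k + 1][2]:
            break
    return t


def _exact_near_field(
    mask: np.ndarray, source: np.ndarray, spacing: VoxelSpacing, radius_voxels: float = 5.0
) -> np.ndarray:
    """Voxels near the marker where the Euclidean distance IS the geodesic.

    The free-space distance is a lower bound on the geodesic; wherever the
    straight segment to the nearest marker voxel stays inside the mask it
    is also attained, so those voxels can be frozen at their exact value.
    Restricted to ``radius_voxels × max(spacing)`` around the marker, where
    front curvature otherwise costs the gridded scheme most of its accuracy.
    """
    edt, idx = ndimage.distance_transform_edt(
        ~source, sampling=spacing.tuple, return_indices=True
    )
    r_init = radius_voxels * max(spacing.tuple)
    cand = mask & ~source & (edt <= r_init)
    coords = np.argwhere(cand)
    if coords.size == 0:
        return cand
    targets = np.stack([idx[ax][cand] for ax in range(3)], axis=1)
    n_steps = 2 * int(radius_voxels) + 3
    ok = np.ones(len(coords), dtype=bool)
    for s in np.linspace(0.0, 1.0, n_steps)[1:-1]:
        pts = np.rint(coords + s * (targets - coords)).astype(int)
        ok &= mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    out = np.zeros_like(cand)
    sel = coords[ok]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


# ---------------------------------------------------------------------------
# Dijkstra oracle / fallback

_OFFSETS_26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
)


def mask_adjacency(mask: np.ndarray, spacing: VoxelSpacing):
    """26-connectivity sparse adjacency (physical µm edge lengths) of mask voxels.

    Returns ``(csr_matrix, flat_index_of_each_node)``.
    """
    idx = -np.ones(mask.shape, dtype=np.int64)
    flat = np.flatnonzero(mask.ravel())
    idx.ravel()[flat] = np.arange(flat.size)
    sp = np.array(spacing.tuple)
    rows, cols, wts = [], [], []
    for off in _OFFSETS_26:
        w = float(np.sqrt(((off * sp) ** 2).sum()))
        sl_a = tuple(slice(o, None) if o > 0 else slice(None, o if o < 0 else None) for o in off)
        sl_b = tuple(
            slice(None, -o) if o > 0 else slice(-o, None) if o != 0 else slice(None)
            for o in off
        )
        a = idx[sl_a].ravel()
        b = idx[sl_b].ravel()
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])
        wts.append(np.full(int(ok.sum()), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    wts = np.concatenate(wts)
    n = flat.size
    adj = sparse.coo_matrix((wts, (rows, cols)), shape=(n, n)).tocsr()
    adj = adj + adj.T
    return adj, flat


def _dijkstra26(mask: np.ndarray, source: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    adj, flat = mask_adjacency(mask, spacing)
    node_of = -np.ones(mask.size, dtype=np.int64)
    node_of[flat] = np.arange(flat.size)
    src_nodes = node_of[np.flatnonzero(source.ravel())]
    src_nodes = src_nodes[src_nodes >= 0]
    d = csgraph.dijkstra(adj, directed=False, indices=src_nodes, min_only=True)
    out = np.full(mask.size, np.inf)
    out[flat] = d
    return out.reshape(mask.shape)
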