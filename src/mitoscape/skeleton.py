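"""Skeletonization, voxel graphs, branch decomposition and graph barycenters.

A binary 3D structure is thinned to a ~1-voxel centerline (3D homotopic
thinning, Lee-style, via scikit-image), then turned into a graph with one
node per skeleton voxel and one edge per 26-adjacent voxel pair. Edge
lengths are physical: ℓ = √((Δz·dz)² + (Δy·dy)² + (Δx·dx)²) µm — anisotropy
is ignored at thinning time and honored at the graph stage. Branches are
maximal degree-2 chains between endpoints/junctions; the barycenter of a
component is the node minimizing the summed shortest-path distance to all
other nodes, used downstream as the "center" of a mitochondrial element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csgraph
from skimage.morphology import skeletonize as _sk_skeletonize

from .distance import mask_adjacency
from .volumes import LabeledVolume, VoxelSpacing

__all__ = [
    "SkeletonGraph",
    "Branch",
    "BranchDecomposition",
    "skeletonize",
    "build_graph",
    "decompose_branches",
    "barycenter",
    "graph_barycenter",
]

Voxel = tuple[int, int, int]


def central_voxel(mask: np.ndarray) -> Voxel:
    """Mask voxel nearest the component centroid (deterministic)."""
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    return tuple(int(v) for v in coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])


def _thin(grid: np.ndarray) -> np.ndarray:
    out = np.asarray(_sk_skeletonize(grid), dtype=bool)
    # homotopic thinning can annihilate small round blobs outright; restore a
    # central voxel for any input component that lost its skeleton so the
    # component count is preserved
    from scipy import ndimage

    lab, n = ndimage.label(grid, structure=np.ones((3, 3, 3), bool))
    if n:
        present = set(np.unique(lab[out]).tolist()) - {0}
        for c in range(1, n + 1):
            if c not in present:
                out[central_voxel(lab == c)] = True
    return out


def skeletonize(mask):
    """3D medial-axis thinning; output ⊆ input, per-component topology preserved."""
    if isinstance(mask, LabeledVolume):
        grid = mask.require_binary()
        if not grid.any():
            raise ValueError("empty mask")
        return LabeledVolume(_thin(grid).astype(np.uint8), mask.spacing)
    grid = np.asarray(mask).astype(bool)
    if not grid.any():
        raise ValueError("empty mask")
    return _thin(grid)


@dataclass
class SkeletonGraph:
    """Voxel-node graph of a skeleton; nodes are (z, y, x) index tuples."""

    graph: nx.Graph
    spacing: VoxelSpacing
    shape: tuple[int, int, int]
    _components: list[frozenset] = field(default=None, repr=False)  # type: ignore[assignment]

    def components(self) -> list[frozenset]:
        """Connected components, deterministically ordered by their lowest voxel."""
        if self._components is None:
            comps = [frozenset(c) for c in nx.connected_components(self.graph)]
            comps.sort(key=lambda c: min(c))
            self._components = comps
        return self._components

    def component_of(self, node: Voxel) -> int:
        for i, c in enumerate(self.components()):
            if node in c:
                return i
        raise KeyError(node)

    def degree_class(self, node: Voxel) -> str:
        d = self.graph.degree[node]
        if d == 0:
            return "isolated"
        if d == 1:
            return "endpoint"
        if d == 2:
            return "slab"
        return "junction"

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))


def build_graph(skeleton, spacing=None) -> SkeletonGraph:
    """One node per skeleton voxel, one edge per 26-adjacent pair (physical µm)."""
    if isinstance(skeleton, LabeledVolume):
        grid = skeleton.require_binary()
        spacing = skeleton.spacing if spacing is None else VoxelSpacing.coerce(spacing)
    else:
        grid = np.asarray(skeleton).astype(bool)
        if spacing is None:
            raise ValueError("spacing required for a bare array")
        spacing = VoxelSpacing.coerce(spacing)
    if not grid.any():
        raise ValueError("empty skeleton")
    adj, flat = mask_adjacency(grid, spacing)
    coords = np.column_stack(np.unravel_index(flat, grid.shape))
    nodes = [tuple(int(v) for v in c) for c in coords]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    coo = adj.tocoo()
    upper = coo.row < coo.col
    for r, c, w in zip(coo.row[upper], coo.col[upper], coo.data[upper]):
        g.add_edge(nodes[r], nodes[c], length=float(w))
    return SkeletonGraph(g, spacing, grid.shape)


@dataclass
class Branch:
    """A maximal degree-2 chain; ``nodes`` lists the chain in walk order."""

    id: int
    nodes: list
    length: float
    kind: tuple[str, str]  # class of the two terminal nodes
    is_cycle: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1 if not self.is_cycle else len(self.nodes)


@dataclass
class BranchDecomposition:
    branches: list[Branch]
    n_endpoints: int
    n_junctions: int
    n_isolated: int

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))


def decompose_branches(g: SkeletonGraph | nx.Graph) -> BranchDecomposition:
    """Partition the edge set into maximal chains between non-slab nodes.

    An isolated cycle (all nodes degree 2) becomes one branch; an isolated
    node yields no branch (it is recorded via ``n_isolated`` and treated as
    a zero-length punctum candidate downstream).
    """
    G = g.graph if isinstance(g, SkeletonGraph) else g
    deg = dict(G.degree)
    terminals = sorted(n for n, d in deg.items() if d != 2)
    visited: set[frozenset] = set()
    branches: list[Branch] = []

    def edge_key(u, v):
        return frozenset((u, v))

    def node_class(n) -> str:
        d = deg[n]
        return "isolated" if d == 0 else "endpoint" if d == 1 else "slab" if d == 2 else "junction"

    def walk(start, first):
        """Follow the chain from ``start`` through ``first`` until a non-slab node."""
        chain = [start, first]
        length = G.edges[start, first]["length"]
        visited.add(edge_key(start, first))
        prev, cur = start, first
        while deg[cur] == 2 and cur != start:
            nxt = next(n for n in G.neighbors(cur) if n != prev)
            visited.add(edge_key(cur, nxt))
            length += G.edges[cur, nxt]["length"]
            chain.append(nxt)
            prev, cur = cur, nxt
        return chain, length

    for t in terminals:
        for nb in sorted(G.neighbors(t)):
            if edge_key(t, nb) in visited:
                continue
            chain, length = walk(t, nb)
            branches.append(
                Branch(
                    id=len(branches),
                    nodes=chain,
                    length=length,
                    kind=(node_class(chain[0]), node_class(chain[-1])),
                )
            )
    # leftover edges belong to pure cycles (every node degree 2)
    for u, v in sorted(G.edges):
        if edge_key(u, v) in visited:
            continue
        chain = [u, v]
        length = G.edges[u, v]["length"]
        visited.add(edge_key(u, v))
        prev, cur = u, v
        while cur != u:
            nxt = [n for n in G.neighbors(cur) if n != prev][0]
            visited.add(edge_key(cur, nxt))
            length += G.edges[cur, nxt]["length"]
            if nxt != u:
                chain.append(nxt)
            prev, cur = cur, nxt
        branches.append(
            Branch(id=len(branches), nodes=chain, length=length, kind=("slab", "slab"), is_cycle=True)
        )
    return BranchDecomposition(
        branches=branches,
        n_endpoints=sum(1 for d in deg.values() if d == 1),
        n_junctions=sum(1 for d in deg.values() if d > 2),
        n_isolated=sum(1 for d in deg.values() if d == 0),
    )


def graph_barycenter(G: nx.Graph, nodes=None, weight: str = "length"):
    """Node minimizing Σ shortest-path distances to all others of its component.

    Ties are broken toward the lowest node in sort order (lowest (z, y, x)
    for voxel graphs). ``nodes`` restricts the search to one component.
    """
    nodelist = sorted(nodes if nodes is not None else G.nodes)
    if len(nodelist) == 1:
        return nodelist[0]
    sub = G.subgraph(nodelist)
    adj = nx.to_scipy_sparse_array(sub, nodelist=nodelist, weight=weight, format="csr")
    dmat = csgraph.dijkstra(adj, directed=False)
    if not np.isfinite(dmat).all():
        raise ValueError("barycenter requires a connected node set")
    sums = dmat.sum(axis=1)
    return nodelist[int(np.argmin(sums))]  # argmin takes the first = lowest node


def barycenter(g: SkeletonGraph, component: int):
    """Barycenter voxel of component ``component`` (see :func:`graph_barycenter`)."""
    comps = g.components()
    if not 0 <= component < len(comps):
        raise KeyError(f"unknown component id {component}")
    return graph_barycenter(g.graph, nodes=comps[component])
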