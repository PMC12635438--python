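"""Strahler ordering of whole-cell skeletons, with loop trimming and root detection.

Strahler numbers annotate distance from the extremities of a tree: the
most distal branches are order 1, a parent branch takes the maximum of its
children's orders, incremented only when at least two children attain that
maximum. The analysis requires an acyclic structure, so cycles are first
opened by a minimum spanning tree whose edge weight is the geodesic
distance-from-soma (loops are preferentially opened at their most distal
side). The root of each component is the end node with the minimum soma
distance; an explicit root mask can override this (e.g. the proximal
portion of a radial-glia endfoot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .compartments import CompartmentLabeling
from .distance import DistanceMap, euclidean_dist, geodesic_dist
from .skeleton import SkeletonGraph, build_graph, decompose_branches, skeletonize
from .volumes import LabeledVolume, VoxelSpacing

log = logging.getLogger(__name__)

__all__ = [
    "StrahlerNetwork",
    "trim_loops",
    "branch_strahler_orders",
    "strahler_analysis",
    "annotate_from_network",
]


@dataclass
class StrahlerNetwork:
    """Acyclic skeleton graph whose nodes carry order / branch_id / compartment.

    ``branch_table`` has one row per linear branch: branch_id, component,
    order, length_um and (when an annotation was supplied) compartment.
    """

    graph: nx.Graph
    branch_table: pd.DataFrame
    roots: dict[int, tuple]  # component id -> root node
    spacing: VoxelSpacing
    shape: tuple[int, int, int]

    @property
    def max_order(self) -> int:
        return int(self.branch_table["order"].max()) if len(self.branch_table) else 0


def trim_loops(g: SkeletonGraph, soma_dist: DistanceMap, reduction: str = "mean"):
    """Open cycles with a minimum spanning tree weighted by soma distance.

    Each edge is weighted by the mean (default; ``reduction="max"`` for the
    maximum) of its two nodes' distance-from-soma, so MST construction
    drops, within every cycle, the edge lying most distal from the soma.
    Returns ``(trimmed SkeletonGraph, removed edge list)``.
    """
    G = g.graph
    red = {"mean": lambda a, b: 0.5 * (a + b), "max": max}[reduction]
    sd = {}
    for n in G.nodes:
        v = soma_dist.values[n]
        if not np.isfinite(v):
            raise ValueError(f"skeleton node {n} outside the distance map's mask")
        sd[n] = float(v)
    T = nx.Graph()
    T.add_nodes_from(G.nodes(data=True))
    weighted = ((u, v, {"length": d["length"], "_w": red(sd[u], sd[v])}) for u, v, d in G.edges(data=True))
    T.add_edges_from(weighted)
    mst = nx.minimum_spanning_tree(T, weight="_w")
    removed = [e for e in G.edges if not mst.has_edge(*e)]
    for _, _, d in mst.edges(data=True):
        d.pop("_w", None)
    return SkeletonGraph(mst, g.spacing, g.shape), removed


def branch_strahler_orders(tree: nx.Graph, root) -> dict[int, int]:
    """Strahler order per branch of an acyclic node graph, rooted at ``root``.

    Branches are the maximal degree-2 chains of the tree; the returned dict
    maps branch id (as produced by :func:`~mitoscape.skeleton.decompose_branches`
    on ``tree``) to its order. Leaf branches are 1; a parent branch's order
    is the max of its children's, +1 if at least two children attain it.
    """
    decomp = decompose_branches(tree)
    if not decomp.branches:
        return {}
    if tree.degree[root] == 2:
        raise ValueError("root must be an end node or junction, not interior to a branch")
    # adjacency at branch level: terminal node -> incident branches
    incident: dict = {}
    for b in decomp.branches:
        for end in (b.nodes[0], b.nodes[-1]):
            incident.setdefault(end, []).append(b)
    orders: dict[int, int] = {}

    def other_end(b, node):
        return b.nodes[-1] if b.nodes[0] == node else b.nodes[0]

    # iterative post-order over branches from the root
    stack = [(b, root, False) for b in incident.get(root, [])]
    seen = set()
    while stack:
        b, entry, processed = stack.pop()
        far = other_end(b, entry)
        children = [c for c in incident.get(far, []) if c.id != b.id]
        if processed:
            if not children:
                orders[b.id] = 1
            else:
                ch = [orders[c.id] for c in children]
                m = max(ch)
                orders[b.id] = m + 1 if ch.count(m) >= 2 else m
        else:
            if b.id in seen:
                continue
            seen.add(b.id)
            stack.append((b, entry, True))
            for c in children:
                stack.append((c, far, False))
    # any branch unreachable from root (shouldn't happen on a tree) gets 1
    for b in decomp.branches:
        orders.setdefault(b.id, 1)
    return orders


def _root_for_component(nodes, G, weight_of):
    """End node (degree ≤ 1) minimizing the weight; tie → lowest (z, y, x)."""
    ends = sorted(n for n in nodes if G.degree[n] <= 1)
    if not ends:  # single node or residual cycle
        ends = sorted(nodes)
    return min(ends, key=lambda n: (weight_of(n), n))


def strahler_analysis(
    cell,
    soma,
    spacing,
    annotation: CompartmentLabeling | LabeledVolume | None = None,
    root=None,
) -> StrahlerNetwork:
    """Skeletonize a cell, open loops, and annotate Strahler orders per branch.

    ``annotation`` (e.g. a compartment labeling) assigns each branch to the
    compartment holding the majority of its nodes. ``root`` optionally
    gives a binary mask marking the root region (endfoot case); otherwise
    the root is the end node with minimum geodesic distance-from-soma.
    """
    cell_b = cell.require_binary() if isinstance(cell, LabeledVolume) else np.asarray(cell).astype(bool)
    soma_b = soma.require_binary() if isinstance(soma, LabeledVolume) else np.asarray(soma).astype(bool)
    spacing = VoxelSpacing.coerce(spacing)
    if not (cell_b & soma_b).any():
        raise ValueError("soma does not intersect the cell")

    skel = skeletonize(cell_b)
    g = build_graph(skel, spacing)
    soma_dist = geodesic_dist(cell_b, soma_b & cell_b, spacing)
    g, removed = trim_loops(g, soma_dist)
    if removed:
        log.info("trim_loops removed %d edge(s)", len(removed))

    if root is not None:
        root_b = root.require_binary() if isinstance(root, LabeledVolume) else np.asarray(root).astype(bool)
        root_edt = euclidean_dist(root_b, spacing).values
        weight_of = lambda n: float(root_edt[n])  # noqa: E731
    else:
        weight_of = lambda n: float(soma_dist.values[n])  # noqa: E731

    ann_grid = None
    if annotation is not None:
        ann_grid = annotation.grid if hasattr(annotation, "grid") else np.asarray(annotation)

    G = g.graph
    rows = []
    roots: dict[int, tuple] = {}
    next_branch_id = 0
    for ci, comp in enumerate(g.components()):
        sub = G.subgraph(comp)
        r = _root_for_component(comp, G, weight_of)
        roots[ci] = r
        if sub.number_of_edges() == 0:  # isolated skeleton voxel
            G.nodes[r]["order"] = 1
            G.nodes[r]["branch_id"] = -1
            if ann_grid is not None:
                G.nodes[r]["compartment"] = int(ann_grid[r])
            continue
        decomp = decompose_branches(sub)
        orders = branch_strahler_orders(sub, r)
        # paint nodes: interior nodes take their branch; shared junction nodes
        # take the root-side (higher-order) incident branch
        for b in decomp.branches:
            bid = next_branch_id + b.id
            order = orders[b.id]
            comp_label = None
            if ann_grid is not None:
                vals = [int(ann_grid[n]) for n in b.nodes]
                comp_label = int(pd.Series(vals).mode().iloc[0])
            rows.append(
                {
                    "branch_id": bid,
                    "component": ci,
                    "order": order,
                    "length_um": b.length,
                    **({"compartment": comp_label} if ann_grid is not None else {}),
                }
            )
            for n in b.nodes:
                prev = G.nodes[n].get("order")
                if prev is None or order > prev:
                    G.nodes[n]["order"] = order
                    G.nodes[n]["branch_id"] = bid
                    if ann_grid is not None:
                        G.nodes[n]["compartment"] = int(ann_grid[n])
        next_branch_id += len(decomp.branches)

    cols = ["branch_id", "component", "order", "length_um"]
    if ann_grid is not None:
        cols.append("compartment")
    table = pd.DataFrame(rows, columns=cols)
    return StrahlerNetwork(G, table, roots, spacing, cell_b.shape)


def annotate_from_network(
    cell,
    net: StrahlerNetwork,
    spacing=None,
    attribute: str = "order",
) -> LabeledVolume:
    """Paint every cell voxel with the ``attribute`` of its nearest skeleton node.

    Nearest-node assignment is anisotropic (feature transform with physical
    sampling); background stays 0. ``attribute`` is ``"order"`` (default)
    or ``"branch_id"``.
    """
    cell_b = cell.require_binary() if isinstance(cell, LabeledVolume) else np.asarray(cell).astype(bool)
    spacing = net.spacing if spacing is None else VoxelSpacing.coerce(spacing)
    nodes = list(net.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    skel = np.zeros(cell_b.shape, dtype=bool)
    vals = np.zeros(cell_b.shape, dtype=np.int64)
    offset = 1 if attribute == "branch_id" else 0  # branch ids start at 0
    for n in nodes:
        skel[n] = True
        vals[n] = int(net.graph.nodes[n].get(attribute, 0)) + offset
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        ~skel, sampling=spacing.tuple, return_indices=True
    )
    out = np.zeros(cell_b.shape, dtype=np.int64)
    out[cell_b] = vals[iz[cell_b], iy[cell_b], ix[cell_b]]
    return LabeledVolume(out, spacing)
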