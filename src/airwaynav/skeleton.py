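"""Centerline skeletonization and branch-graph / tree encoding.

The binary lumen mask is thinned to a 1-voxel-wide medial curve (26/6
connectivity-preserving thinning), the curve is condensed into a branch
graph (branching-voxel clusters and endpoint voxels become nodes, the
degree-2 chains between them become edges carrying ordered world-mm
polylines), short leaf spurs are pruned, and the graph is directed away
from the trachea entry by depth-first search to obtain the rooted airway
tree whose levels are bronchial generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage

from .segmentation import AirwayMask
from .tree import AirwayTree, TreeNode

__all__ = [
    "SkeletonVoxels",
    "skeletonize",
    "build_skeleton_graph",
    "extend_leaf_tips",
    "prune_spurs",
    "direct_from_root",
    "arc_length",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]


@dataclass
class SkeletonVoxels:
    """1-voxel-wide curve skeleton: voxel indices and 26-neighbor degrees."""

    points: np.ndarray  # (N, 3) int voxel indices
    degree: np.ndarray  # (N,) number of 26-neighbors in the skeleton
    shape: tuple[int, int, int]

    def as_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol[tuple(self.points.T)] = True
        return vol


def arc_length(polyline: np.ndarray) -> float:
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())


def skeletonize(mask: AirwayMask) -> SkeletonVoxels:
    """Thin the mask to its medial curve skeleton (topology preserving).

    Uses distance-ordered homotopic thinning with the 26/6 connectivity
    pair (see :mod:`airwaynav._thinning`).
    """
    from ._thinning import medial_curve_skeleton

    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    skel = medial_curve_skeleton(m)
    points = np.argwhere(skel)
    neigh = ndimage.correlate(skel.astype(np.uint8), _CONN26.astype(np.uint8),
                              mode="constant") - skel.astype(np.uint8)
    degree = neigh[skel]
    return SkeletonVoxels(points=points, degree=degree, shape=m.shape)


# ---------------------------------------------------------------------------
# branch graph


def _world(affine: np.ndarray, ijk) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def build_skeleton_graph(skel: SkeletonVoxels, affine: np.ndarray) -> nx.MultiGraph:
    """Condense a skeleton into a branch graph.

    Maximal 26-connected clusters of degree>=3 voxels collapse to single
    branching nodes, degree-1 (and isolated) voxels become end nodes, and
    each maximal chain of degree-2 voxels becomes an edge whose ``polyline``
    attribute is the ordered chain in world mm, capped by the two node
    positions.  Every skeleton voxel belongs to exactly one node cluster or
    one edge chain.
    """
    pts = [tuple(int(c) for c in p) for p in skel.points]
    pset = set(pts)
    if not pset:
        raise ValueError("empty skeleton")

    def nbrs(v):
        return [(v[0] + o[0], v[1] + o[1], v[2] + o[2])
                for o in _OFFSETS
                if (v[0] + o[0], v[1] + o[1], v[2] + o[2]) in pset]

    deg = {v: len(nbrs(v)) for v in pts}

    n_comp = _count_components(pset, nbrs)
    if n_comp > 1:
        raise ValueError(f"skeleton has {n_comp} connected components, expected 1")

    affine = np.asarray(affine, dtype=float)
    g = nx.MultiGraph()
    vox2node: dict[tuple, int] = {}
    next_id = 0

    # clusters of degree>=3 voxels
    branch_vox = {v for v in pts if deg[v] >= 3}
    seen = set()
    for v in sorted(branch_vox):
        if v in seen:
            continue
        cluster = _flood(v, branch_vox, nbrs)
        seen |= cluster
        cl = sorted(cluster)
        pos = _world(affine, np.mean(np.array(cl, dtype=float), axis=0))
        g.add_node(next_id, pos=pos, voxels=cl)
        for u in cl:
            vox2node[u] = next_id
        next_id += 1
    # endpoint / isolated voxels
    for v in sorted(pts):
        if deg[v] <= 1 and v not in vox2node:
            g.add_node(next_id, pos=_world(affine, v), voxels=[v])
            vox2node[v] = next_id
            next_id += 1

    # chains of degree-2 voxels
    chain_vox = {v for v in pts if deg[v] == 2}
    used = set()
    for v in sorted(chain_vox):
        if v in used:
            continue
        comp = _flood(v, chain_vox, nbrs)
        used |= comp
        ordered, cyclic = _order_chain(comp, nbrs, chain_vox)
        if cyclic:
            # pure cycle: promote its first voxel to a node, self-loop edge
            head = ordered[0]
            g.add_node(next_id, pos=_world(affine, head), voxels=[head])
            vox2node[head] = next_id
            node_id = next_id
            next_id += 1
            chain = ordered[1:]
            na = nb = node_id
        else:
            chain = ordered
            ca = _adjacent_nodes(ordered[0], nbrs, vox2node)
            cb = _adjacent_nodes(ordered[-1], nbrs, vox2node)
            if not ca or not cb:
                raise RuntimeError("chain end without an adjacent node voxel")
            # a junction-dense end voxel can touch several node clusters;
            # prefer an assignment joining two distinct nodes over a self-loop
            na, nb = min(((a, b) for a in ca for b in cb),
                         key=lambda ab: (ab[0] == ab[1], ab))
        poly = np.vstack([
            g.nodes[na]["pos"],
            _world(affine, np.array(chain, dtype=float)) if chain else np.empty((0, 3)),
            g.nodes[nb]["pos"],
        ])
        g.add_edge(na, nb, polyline=poly, n_chain=len(chain),
                   length=arc_length(poly))

    # direct node-to-node adjacency (no chain in between)
    added = set()
    for v in sorted(vox2node):
        for u in nbrs(v):
            if u in vox2node and vox2node[u] != vox2node[v]:
                key = tuple(sorted((vox2node[u], vox2node[v])))
                if key not in added:
                    added.add(key)
                    pa = g.nodes[key[0]]["pos"]
                    pb = g.nodes[key[1]]["pos"]
                    poly = np.vstack([pa, pb])
                    g.add_edge(key[0], key[1], polyline=poly, n_chain=0,
                               length=arc_length(poly))
    return g


def _count_components(pset, nbrs) -> int:
    left = set(pset)
    n = 0
    while left:
        comp = _flood(next(iter(left)), left, nbrs)
        left -= comp
        n += 1
    return n


def _flood(start, allowed, nbrs) -> set:
    comp = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in nbrs(v):
            if u in allowed and u not in comp:
                comp.add(u)
                stack.append(u)
    return comp


def _order_chain(comp: set, nbrs, chain_vox) -> tuple[list, bool]:
    """Order a degree-2 chain component; returns (ordered voxels, is_cycle)."""
    ends = [v for v in comp if sum(1 for u in nbrs(v) if u in comp) <= 1]
    cyclic = not ends
    start = min(ends) if ends else min(comp)
    ordered = [start]
    in_order = {start}
    cur = start
    while True:
        cand = [u for u in nbrs(cur) if u in comp and u not in in_order]
        if not cand:
            break
        cur = min(cand)
        ordered.append(cur)
        in_order.add(cur)
    return ordered, cyclic


def _adjacent_nodes(v, nbrs, vox2node) -> list[int]:
    return sorted({vox2node[u] for u in nbrs(v) if u in vox2node})


# ---------------------------------------------------------------------------
# tip extension


def extend_leaf_tips(graph: nx.MultiGraph, mask: np.ndarray, affine: np.ndarray,
                     max_extension_mm: float = 20.0) -> nx.MultiGraph:
    """Extend every leaf edge along its end direction to the mask boundary.

    Homotopic thinning erodes free tube ends by roughly one lumen radius, so
    terminal centerline branches systematically stop short of the true tip
    (and can then fall below the spur-pruning length).  Each degree-1 node's
    edge is marched onward in sub-voxel steps while the underlying mask stays
    foreground, and the node is moved to the recovered tip.
    """
    g = graph.copy()
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    step = 0.5 * float(spacing.min())
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)

    def edt_at(q):
        ijk = np.round(q @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= mask.shape):
            return -1.0
        return float(edt[tuple(ijk)])

    for node in list(g.nodes):
        if g.degree(node) != 1:
            continue
        (u, v, k) = next(iter(g.edges(node, keys=True)))
        d = g.edges[u, v, k]
        other = v if u == node else u
        poly = _oriented(d["polyline"], start_at=g.nodes[other]["pos"])
        direction = _end_direction(poly)
        if direction is None:
            continue
        p = poly[-1].copy()
        new_pts = []
        travelled = 0.0
        deepest = edt_at(p)
        while travelled < max_extension_mm:
            q = p + step * direction
            depth = edt_at(q)
            # stop at the medial endpoint: once the distance to the boundary
            # starts descending we are past the center of the terminal cap
            if depth <= 0.0 or depth < deepest - 1.5 * step:
                break
            deepest = max(deepest, depth)
            new_pts.append(q)
            p = q
            travelled += step
        if new_pts:
            ext = np.vstack([poly, np.asarray(new_pts)])
            g.remove_edge(u, v, k)
            g.add_edge(other, node, polyline=ext, n_chain=d["n_chain"],
                       length=arc_length(ext))
            g.nodes[node]["pos"] = ext[-1]
    return g


def _end_direction(poly: np.ndarray, lookback_mm: float = 3.0) -> np.ndarray | None:
    """Unit direction of the polyline at its last point, averaged over the
    final ``lookback_mm`` of arc length."""
    end = poly[-1]
    acc = 0.0
    for i in range(len(poly) - 1, 0, -1):
        acc += float(np.linalg.norm(poly[i] - poly[i - 1]))
        if acc >= lookback_mm or i == 1:
            v = end - poly[i - 1]
            n = np.linalg.norm(v)
            return v / n if n > 1e-9 else None
    return None


# ---------------------------------------------------------------------------
# pruning


def prune_spurs(graph: nx.MultiGraph, min_length_mm: float = 3.0,
                mask: np.ndarray | None = None,
                affine: np.ndarray | None = None,
                radius_factor: float = 1.5) -> nx.MultiGraph:
    """Iteratively remove leaf edges shorter than ``min_length_mm``.

    When the source ``mask`` (and its ``affine``) are supplied, the threshold
    at each junction additionally adapts to the local lumen radius: thinning
    a junction bulge leaves medial spurs about one radius long, so a leaf
    edge is also removed when shorter than ``radius_factor`` times the
    distance from its junction to the mask boundary.  Nodes left with
    exactly two incident edges by a removal are merged into a single
    pass-through edge.  Idempotent at its fixed point.
    """
    g = graph.copy()
    radius_at = None
    if mask is not None:
        if affine is None:
            raise ValueError("affine required with mask")
        edt = ndimage.distance_transform_edt(
            np.asarray(mask, bool),
            sampling=np.linalg.norm(np.asarray(affine, float)[:3, :3], axis=0))
        inv = np.linalg.inv(affine)

        def radius_at(pos):
            ijk = np.round(pos @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ijk = np.clip(ijk, 0, np.asarray(mask.shape) - 1)
            return float(edt[tuple(ijk)])

    while True:
        removed_near: set[int] = set()
        for node in list(g.nodes):
            if node in g and g.degree(node) == 1 and g.number_of_nodes() > 1:
                (u, v, k) = next(iter(g.edges(node, keys=True)))
                other = v if u == node else u
                thr = min_length_mm
                if radius_at is not None and other != node:
                    thr = max(thr, radius_factor * radius_at(g.nodes[other]["pos"]))
                if g.edges[u, v, k]["length"] < thr:
                    g.remove_node(node)
                    removed_near.add(other)
        if not removed_near:
            break
        for node in removed_near:
            if node in g and g.degree(node) == 2 and len(list(g.edges(node, keys=True))) == 2:
                _merge_degree2(g, node)
    return g


def _merge_degree2(g: nx.MultiGraph, node: int) -> None:
    edges = list(g.edges(node, keys=True, data=True))
    if len(edges) != 2:
        return
    (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
    a = v1 if u1 == node else u1
    b = v2 if u2 == node else u2
    if a == node or b == node:  # self-loop involved; leave as is
        return
    pos = g.nodes[node]["pos"]
    p1 = _oriented(d1["polyline"], end_at=pos)
    p2 = _oriented(d2["polyline"], start_at=pos)
    poly = np.vstack([p1, p2[1:]])
    n_chain = d1["n_chain"] + d2["n_chain"] + len(g.nodes[node].get("voxels", []))
    g.remove_node(node)
    g.add_edge(a, b, polyline=poly, n_chain=n_chain, length=arc_length(poly))


def _oriented(poly: np.ndarray, start_at=None, end_at=None) -> np.ndarray:
    if start_at is not None:
        return poly if np.linalg.norm(poly[0] - start_at) <= np.linalg.norm(poly[-1] - start_at) else poly[::-1]
    return poly if np.linalg.norm(poly[-1] - end_at) <= np.linalg.norm(poly[0] - end_at) else poly[::-1]


# ---------------------------------------------------------------------------
# directing


def direct_from_root(graph: nx.MultiGraph, trachea_seed_world,
                     diagnostics: dict | None = None) -> AirwayTree:
    """Direct the branch graph away from the trachea entry into a rooted tree.

    The root is the graph node nearest the trachea seed (ties: most superior,
    then lowest id).  Depth-first traversal (children by descending edge arc
    length) orients every edge; DFS back edges (cycles) are discarded and
    counted in ``diagnostics["discarded_edges"]``.  Pass-through nodes with a
    single child are merged so that every directed edge advances one
    bronchial level; nodes with more than two children are flagged
    ``non_binary``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    seed = np.asarray(trachea_seed_world, dtype=float)
    root = min(graph.nodes,
               key=lambda n: (np.linalg.norm(graph.nodes[n]["pos"] - seed),
                              -graph.nodes[n]["pos"][2], n))

    parent_of: dict[int, tuple[int, np.ndarray]] = {}
    visited = {root}
    used_keys: set[tuple] = set()
    discarded = 0
    stack = [root]
    while stack:
        n = stack.pop()
        edges = sorted(graph.edges(n, keys=True, data=True),
                       key=lambda e: (-e[3]["length"], e[1], e[2]))
        for (u, v, k, d) in edges:
            ekey = (min(u, v), max(u, v), k)
            m = v if u == n else u
            if m in visited or m == n:
                if ekey not in used_keys:  # back edge: breaks a cycle
                    used_keys.add(ekey)
                    discarded += 1
                continue
            used_keys.add(ekey)
            visited.add(m)
            poly = _oriented(d["polyline"], start_at=graph.nodes[n]["pos"])
            parent_of[m] = (n, poly)
            stack.append(m)
    if diagnostics is not None:
        diagnostics["discarded_edges"] = discarded
        diagnostics["root_graph_node"] = root

    children: dict[int, list[int]] = {n: [] for n in visited}
    for c, (p, _) in parent_of.items():
        children[p].append(c)

    # collapse single-child pass-through nodes (keep the root)
    nodes: list[TreeNode] = []
    edges: dict[tuple[int, int], np.ndarray] = {}
    id_map: dict[int, int] = {}
    next_id = 0

    def new_node(gnode: int, kind: str, level: int, n_children: int) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        id_map[gnode] = nid
        nodes.append(TreeNode(id=nid, point=np.asarray(graph.nodes[gnode]["pos"], float),
                              kind=kind, level=level, non_binary=n_children > 2))
        return nid

    # BFS over the collapsed tree
    root_kids = children[root]
    root_tid = new_node(root, "root", 0, len(root_kids))
    queue = [(root, root_tid, 0)]
    while queue:
        gnode, tid, level = queue.pop(0)
        for c in sorted(children[gnode]):
            poly_parts = [parent_of[c][1]]
            cur = c
            while len(children[cur]) == 1:
                nxt = children[cur][0]
                poly_parts.append(parent_of[nxt][1])
                cur = nxt
            poly = poly_parts[0]
            for part in poly_parts[1:]:
                poly = np.vstack([poly, part[1:]])
            kids = children[cur]
            kind = "leaf" if not kids else "bifurcation"
            ctid = new_node(cur, kind, level + 1, len(kids))
            edges[(tid, ctid)] = poly
            queue.append((cur, ctid, level + 1))

    return AirwayTree(nodes, edges, root_id=root_tid)
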