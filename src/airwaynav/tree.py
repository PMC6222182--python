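"""Rooted airway tree: bifurcation nodes plus per-edge 3-D centerline polylines.

The tree is stored in directed form (edges keyed parent -> child, polylines
ordered away from the root) and can be encoded as the pair of matrices used
throughout this package: a symmetric binary node-adjacency matrix together
with a matrix of 3-D segments holding the ordered skeleton points that join
each pair of adjacent nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TreeNode", "AirwayTree", "encode_adjacency", "tree_from_adjacency"]

KINDS = ("root", "bifurcation", "leaf")


@dataclass
class TreeNode:
    id: int
    point: np.ndarray  # world mm
    kind: str          # root | bifurcation | leaf
    level: int
    non_binary: bool = False

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        if self.kind not in KINDS:
            raise ValueError(f"bad node kind {self.kind!r}")


class AirwayTree:
    """Rooted tree of airway branch points with centerline polylines.

    Parameters
    ----------
    nodes : iterable of TreeNode
    edges : mapping (parent_id, child_id) -> (k, 3) polyline in world mm,
        ordered parent -> child, endpoints at the node positions.
    root_id : int
    """

    def __init__(self, nodes, edges, root_id: int):
        self.nodes: dict[int, TreeNode] = {n.id: n for n in nodes}
        self.edges: dict[tuple[int, int], np.ndarray] = {
            (int(p), int(c)): np.asarray(poly, dtype=float).reshape(-1, 3)
            for (p, c), poly in dict(edges).items()
        }
        self.root_id = int(root_id)
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        self._parent: dict[int, int] = {}
        for (p, c) in self.edges:
            self._children[p].append(c)
            self._parent[c] = p
        for i in self._children:
            self._children[i].sort()

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, i: int) -> list[int]:
        return list(self._children[i])

    def parent(self, i: int) -> int | None:
        return self._parent.get(i)

    def leaves(self) -> list[int]:
        return [i for i in self.nodes if not self._children[i]]

    def directed_edges(self) -> list[tuple[int, int]]:
        """Edges sorted lexicographically by (parent, child): the canonical
        edge order used for deterministic tie-breaking."""
        return sorted(self.edges)

    def edge_polyline(self, parent: int, child: int) -> np.ndarray:
        return self.edges[(parent, child)]

    def node_path(self, i: int) -> list[int]:
        """Node ids from the root down to node ``i``."""
        path = [i]
        while path[-1] != self.root_id:
            path.append(self._parent[path[-1]])
        return path[::-1]

    # -- validation --------------------------------------------------------
    def validate(self, endpoint_tol_mm: float = 3.0) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        if self.root_id not in self.nodes:
            raise ValueError("root id not among nodes")
        if self.nodes[self.root_id].kind != "root":
            raise ValueError("root node must have kind 'root'")
        if self.nodes[self.root_id].level != 0:
            raise ValueError("root level must be 0")
        # single root of in-degree 0, every node reachable, acyclic
        if self.root_id in self._parent:
            raise ValueError("root has a parent")
        seen = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise ValueError("cycle detected")
            seen.add(i)
            stack.extend(self._children[i])
        if seen != set(self.nodes):
            raise ValueError("nodes unreachable from root")
        for (p, c), poly in self.edges.items():
            if self.nodes[c].level != self.nodes[p].level + 1:
                raise ValueError(f"level({c}) != level({p}) + 1")
            if poly.shape[0] < 1:
                raise ValueError("empty edge polyline")
            if (np.linalg.norm(poly[0] - self.nodes[p].point) > endpoint_tol_mm
                    or np.linalg.norm(poly[-1] - self.nodes[c].point) > endpoint_tol_mm):
                raise ValueError(f"polyline endpoints far from nodes for edge {(p, c)}")
        for i, n in self.nodes.items():
            nc = len(self._children[i])
            if n.kind == "leaf" and nc:
                raise ValueError(f"leaf {i} has children")
            if n.kind == "bifurcation" and nc == 0:
                raise ValueError(f"bifurcation {i} has no children")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "root_id": self.root_id,
            "nodes": [
                {"id": n.id, "point": n.point.tolist(), "kind": n.kind,
                 "level": n.level, "non_binary": n.non_binary}
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {"parent": p, "child": c, "polyline": self.edges[(p, c)].tolist()}
                for (p, c) in self.directed_edges()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AirwayTree":
        nodes = [TreeNode(id=n["id"], point=n["point"], kind=n["kind"],
                          level=n["level"], non_binary=n.get("non_binary", False))
                 for n in d["nodes"]]
        edges = {(e["parent"], e["child"]): np.asarray(e["polyline"], dtype=float)
                 for e in d["edges"]}
        return cls(nodes, edges, d["root_id"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "AirwayTree":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- comparison --------------------------------------------------------
    def equals(self, other: "AirwayTree", tol: float = 1e-9) -> bool:
        if set(self.nodes) != set(other.nodes) or self.root_id != other.root_id:
            return False
        for i, n in self.nodes.items():
            m = other.nodes[i]
            if (n.kind, n.level, n.non_binary) != (m.kind, m.level, m.non_binary):
                return False
            if np.linalg.norm(n.point - m.point) > tol:
                return False
        if set(self.edges) != set(other.edges):
            return False
        for k, poly in self.edges.items():
            q = other.edges[k]
            if poly.shape != q.shape or np.abs(poly - q).max() > tol:
                return False
        return True

    def canonical_shape(self, with_levels: bool = True):
        """Canonical nested-tuple form for (level-tagged) isomorphism tests."""
        def rec(i: int):
            subs = tuple(sorted(rec(c) for c in self._children[i]))
            tag = self.nodes[i].level if with_levels else 0
            return (tag, subs)
        return rec(self.root_id)


# ---------------------------------------------------------------------------
# two-matrix encoding


def encode_adjacency(tree: AirwayTree) -> tuple[np.ndarray, np.ndarray]:
    """Encode a tree as (binary adjacency matrix, segment matrix).

    Rows/columns follow ascending node id order.  The adjacency matrix is
    symmetric with zero diagonal; entry (i, j) of the segment matrix is the
    polyline ordered i -> j (``None`` when non-adjacent), so its nonzero
    pattern equals the adjacency pattern.
    """
    ids = sorted(tree.nodes)
    idx = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=np.uint8)
    S = np.empty((n, n), dtype=object)
    for (p, c), poly in tree.edges.items():
        i, j = idx[p], idx[c]
        A[i, j] = A[j, i] = 1
        S[i, j] = poly
        S[j, i] = poly[::-1]
    return A, S


def tree_from_adjacency(nodes, A: np.ndarray, S: np.ndarray, root_id: int) -> AirwayTree:
    """Reconstruct an :class:`AirwayTree` from its two-matrix encoding.

    ``nodes`` supplies node metadata (ids, points, kinds, levels); edge
    directions are recovered by traversal from the root.
    """
    nodes = list(nodes)
    ids = sorted(n.id for n in nodes)
    idx = {nid: k for k, nid in enumerate(ids)}
    edges = {}
    seen = {root_id}
    stack = [root_id]
    while stack:
        p = stack.pop()
        for nid in ids:
            if nid not in seen and A[idx[p], idx[nid]]:
                edges[(p, nid)] = np.asarray(S[idx[p], idx[nid]], dtype=float)
                seen.add(nid)
                stack.append(nid)
    return AirwayTree(nodes, edges, root_id)
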