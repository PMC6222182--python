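"""Navigation-path planning: closest airway point and the root-to-lesion path.

Given a lesion point in world mm, the planner anchors it to the closest
centerline point over all edge polylines of the airway tree (deterministic
tie-break: lowest edge id in canonical edge order, then lowest point index)
and returns the unique tree path from the trachea root to that anchor, the
final segment truncated at the anchor point.

Each path segment owns its distal junction: a segment runs from the
bifurcation it leaves (its first point) to the bifurcation point at its own
level ``d`` (its last point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tree import AirwayTree

__all__ = ["AnchorPoint", "PathSegment", "NavigationPath",
           "closest_airway_point", "root_path", "plan_path"]


@dataclass
class AnchorPoint:
    """Closest centerline point to the lesion."""

    edge: tuple[int, int]   # (parent id, child id)
    point_index: int        # index into that edge's polyline
    point: np.ndarray       # world mm
    gap_mm: float           # Euclidean distance lesion -> anchor

    def __post_init__(self) -> None:
        self.edge = (int(self.edge[0]), int(self.edge[1]))
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        if self.gap_mm < 0:
            raise ValueError("gap_mm must be >= 0")


@dataclass
class PathSegment:
    """One path segment S_d: ordered centerline points between consecutive
    path nodes, at bronchial level ``level`` (the level of its distal node)."""

    proximal: int
    distal: int
    points: np.ndarray
    level: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


@dataclass
class NavigationPath:
    """Ordered segments S_1..S_n from the trachea root to the lesion anchor."""

    segments: list[PathSegment]
    anchor: AnchorPoint
    lesion: np.ndarray

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=float).reshape(3)

    @property
    def n(self) -> int:
        return len(self.segments)

    def to_dict(self) -> dict:
        return {
            "lesion": self.lesion.tolist(),
            "anchor": {"edge": list(self.anchor.edge),
                       "point_index": self.anchor.point_index,
                       "point": self.anchor.point.tolist(),
                       "gap_mm": self.anchor.gap_mm},
            "segments": [{"proximal": s.proximal, "distal": s.distal,
                          "level": s.level, "points": s.points.tolist()}
                         for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NavigationPath":
        anchor = AnchorPoint(edge=tuple(d["anchor"]["edge"]),
                             point_index=d["anchor"]["point_index"],
                             point=d["anchor"]["point"],
                             gap_mm=d["anchor"]["gap_mm"])
        segs = [PathSegment(s["proximal"], s["distal"], s["points"], s["level"])
                for s in d["segments"]]
        return cls(segments=segs, anchor=anchor, lesion=d["lesion"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "NavigationPath":
        return cls.from_dict(json.loads(Path(path).read_text()))


def closest_airway_point(tree: AirwayTree, lesion) -> AnchorPoint:
    """Global minimizer of the lesion distance over all polyline points.

    Ties are broken deterministically: the edge earliest in canonical
    (parent, child) order wins, then the lowest point index.
    """
    lesion = np.asarray(lesion, dtype=float).reshape(3)
    if not tree.edges:
        raise ValueError("tree has no edges")
    best = None  # (dist, edge, idx, point)
    for edge in tree.directed_edges():
        poly = tree.edges[edge]
        d = np.linalg.norm(poly - lesion, axis=1)
        i = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
        if best is None or d[i] < best[0]:
            best = (float(d[i]), edge, i, poly[i])
    return AnchorPoint(edge=best[1], point_index=best[2], point=best[3],
                       gap_mm=best[0])


def root_path(tree: AirwayTree, anchor: AnchorPoint) -> NavigationPath:
    """Unique tree path from the root to the anchor, truncated mid-edge.

    The per-segment level is the level of the segment's distal node; levels
    increase by exactly 1 along the path.
    """
    if anchor.edge not in tree.edges:
        raise ValueError(f"anchor edge {anchor.edge} not in tree")
    u, v = anchor.edge
    node_seq = tree.node_path(u)
    segments: list[PathSegment] = []
    for a, b in zip(node_seq[:-1], node_seq[1:]):
        segments.append(PathSegment(proximal=a, distal=b,
                                    points=tree.edges[(a, b)],
                                    level=tree.nodes[b].level))
    if anchor.point_index > 0:
        poly = tree.edges[(u, v)][: anchor.point_index + 1]
        segments.append(PathSegment(proximal=u, distal=v, points=poly,
                                    level=tree.nodes[v].level))
    elif not segments:
        # degenerate: the anchor is the root itself
        segments.append(PathSegment(proximal=u, distal=v,
                                    points=tree.edges[(u, v)][:1],
                                    level=tree.nodes[v].level))
    # root_path has no lesion of its own; default to the anchor point
    # (plan_path overwrites it with the true lesion)
    return NavigationPath(segments=segments, anchor=anchor, lesion=anchor.point)


def plan_path(tree: AirwayTree, lesion) -> NavigationPath:
    """Convenience wrapper: anchor the lesion, then build the root path."""
    anchor = closest_airway_point(tree, lesion)
    path = root_path(tree, anchor)
    path.lesion = np.asarray(lesion, dtype=float).reshape(3)
    return path
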