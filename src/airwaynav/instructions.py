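"""Quadrant-based navigation instructions via virtual-camera projection.

At every bifurcation along a navigation path a virtual camera is placed a
few millimetres proximal on the path, looking at the bifurcation point.  The
centerline points of each child segment are perspective-projected onto the
image plane; the image is split into four quadrants centred at the projected
bifurcation point (I = up-right, II = up-left, III = down-left,
IV = down-right), each child is assigned the quadrant holding most of its
projected points, and the pair of quadrant labels is simplified to a single
command by dropping the word the two children share: children in I/II vs
III/IV give "go up"/"go down", children in I/IV vs II/III give
"go right"/"go left".  Two children in the same quadrant are separated along
the axis on which their mean projected points differ most.  The ordered
per-bifurcation instructions form the exported roadmap.

Bifurcations closer together than ``close_mm`` are flagged
(``close_levels``): seen from one camera their lumens superimpose ("three
lumens" in one view), a known source of confusion; with ``merge_close`` the
two steps collapse into a single instruction that names the full quadrant of
the on-path grandchild as seen from the first camera.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .planner import NavigationPath
from .tree import AirwayTree
from .volume import ANTERIOR, SUPERIOR

__all__ = [
    "CameraPose",
    "ProjectedSegment",
    "Instruction",
    "Roadmap",
    "SegmentNotVisibleError",
    "bifurcation_camera",
    "project_segment",
    "assign_quadrant",
    "label_pair",
    "encode_instructions",
    "export_roadmap",
    "roadmap_from_json",
    "QUADRANT_NAMES",
]

QUADRANTS = ("I", "II", "III", "IV")
QUADRANT_NAMES = {"I": "up-right", "II": "up-left",
                  "III": "down-left", "IV": "down-right"}
INSTRUCTION_TEXTS = ("go up", "go down", "go left", "go right",
                     "go up-right", "go up-left", "go down-left", "go down-right")


class SegmentNotVisibleError(RuntimeError):
    pass


@dataclass
class CameraPose:
    """Pinhole camera: position, orthonormal (view, up) pair, field of view."""

    position: np.ndarray
    view_dir: np.ndarray
    up: np.ndarray
    fov_deg: float
    principal_point: np.ndarray  # 2-D projection of the bifurcation point

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.view_dir = np.asarray(self.view_dir, dtype=float).reshape(3)
        self.up = np.asarray(self.up, dtype=float).reshape(3)
        self.principal_point = np.asarray(self.principal_point, dtype=float).reshape(2)
        if not (0.0 < self.fov_deg < 180.0):
            raise ValueError("fov must be in (0, 180) degrees")
        if abs(np.dot(self.view_dir, self.up)) > 1e-6:
            raise ValueError("view_dir and up must be orthogonal")

    @property
    def right(self) -> np.ndarray:
        """Image x axis; (right, up, view) is right-handed."""
        return np.cross(self.up, self.view_dir)

    def to_dict(self) -> dict:
        return {"position": self.position.tolist(),
                "view_dir": self.view_dir.tolist(),
                "up": self.up.tolist(), "fov_deg": self.fov_deg,
                "principal_point": self.principal_point.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraPose":
        return cls(d["position"], d["view_dir"], d["up"], d["fov_deg"],
                   d["principal_point"])


@dataclass
class ProjectedSegment:
    """A child segment projected into the camera image.

    ``points2d`` are normalized image coordinates (x right, y up) relative to
    the principal point; ``quadrant`` is the majority quadrant of the
    in-frustum points (ties go to the quadrant of the most distal projected
    point, i.e. the direction the operator actually steers toward).
    """

    child_id: int
    points2d: np.ndarray
    quadrant: str
    quadrant_counts: dict[str, int]
    mean_angle_deg: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.points2d = np.asarray(self.points2d, dtype=float).reshape(-1, 2)

    @property
    def mean_point(self) -> np.ndarray:
        return self.points2d.mean(axis=0)

    def to_dict(self) -> dict:
        return {"child_id": self.child_id, "points2d": self.points2d.tolist(),
                "quadrant": self.quadrant, "quadrant_counts": self.quadrant_counts,
                "mean_angle_deg": self.mean_angle_deg, "n_dropped": self.n_dropped}

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectedSegment":
        return cls(d["child_id"], d["points2d"], d["quadrant"],
                   dict(d["quadrant_counts"]), d["mean_angle_deg"], d["n_dropped"])


@dataclass
class Instruction:
    """One per-bifurcation instruction of the roadmap."""

    level: int
    node_id: int
    onpath_child: int
    labels: dict[int, str]  # child id -> full quadrant name
    text: str
    non_binary: bool = False
    close_levels: bool = False
    merged: bool = False

    def __post_init__(self) -> None:
        if self.text not in INSTRUCTION_TEXTS:
            raise ValueError(f"invalid instruction text {self.text!r}")

    def to_dict(self) -> dict:
        return {"level": self.level, "node_id": self.node_id,
                "onpath_child": self.onpath_child,
                "labels": {str(k): v for k, v in self.labels.items()},
                "text": self.text,
                "flags": {"non_binary": self.non_binary,
                          "close_levels": self.close_levels,
                          "merged": self.merged}}

    @classmethod
    def from_dict(cls, d: dict) -> "Instruction":
        return cls(level=d["level"], node_id=d["node_id"],
                   onpath_child=d["onpath_child"],
                   labels={int(k): v for k, v in d["labels"].items()},
                   text=d["text"], non_binary=d["flags"]["non_binary"],
                   close_levels=d["flags"]["close_levels"],
                   merged=d["flags"]["merged"])


@dataclass
class Roadmap:
    """Ordered instructions plus the projection geometry behind each one."""

    instructions: list[Instruction]
    projections: list[dict]  # per instruction: camera + projected segments
    lesion: np.ndarray
    anchor_gap_mm: float

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=float).reshape(3)

    def to_dict(self) -> dict:
        return {
            "instructions": [i.to_dict() for i in self.instructions],
            "projections": [
                {"node_id": p["node_id"],
                 "camera": p["camera"].to_dict(),
                 "segments": [s.to_dict() for s in p["segments"]]}
                for p in self.projections
            ],
            "lesion": self.lesion.tolist(),
            "anchor_gap_mm": self.anchor_gap_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Roadmap":
        return cls(
            instructions=[Instruction.from_dict(i) for i in d["instructions"]],
            projections=[
                {"node_id": p["node_id"],
                 "camera": CameraPose.from_dict(p["camera"]),
                 "segments": [ProjectedSegment.from_dict(s) for s in p["segments"]]}
                for p in d["projections"]
            ],
            lesion=d["lesion"],
            anchor_gap_mm=d["anchor_gap_mm"],
        )


# ---------------------------------------------------------------------------
# camera


def _walk_back(points: np.ndarray, setback_mm: float) -> np.ndarray:
    """Point ``setback_mm`` proximal to the polyline's last point along it,
    clamped to the first point."""
    acc = 0.0
    for i in range(len(points) - 1, 0, -1):
        step = float(np.linalg.norm(points[i] - points[i - 1]))
        if acc + step >= setback_mm and step > 0:
            f = (setback_mm - acc) / step
            return points[i] + f * (points[i - 1] - points[i])
        acc += step
    return points[0].copy()


def bifurcation_camera(path: NavigationPath, d: int, setback_mm: float = 5.0,
                       fov_deg: float = 120.0) -> CameraPose:
    """Virtual camera at the level-``d`` bifurcation of the path.

    The camera sits ``setback_mm`` proximal to the bifurcation point along
    segment S_d (clamped to the segment start) and views the bifurcation.
    "Up" is the patient-superior axis orthogonalized against the viewing
    direction, falling back to patient-anterior when the view is within ~8
    degrees of vertical.
    """
    by_level = {s.level: s for s in path.segments}
    if d not in by_level or d >= path.segments[-1].level:
        raise ValueError(f"level {d} has no on-path bifurcation")
    seg = by_level[d]
    bif = seg.points[-1]
    pos = _walk_back(seg.points, setback_mm)
    view = bif - pos
    nv = np.linalg.norm(view)
    if nv < 1e-9:
        raise ValueError("degenerate segment: camera coincides with bifurcation")
    view = view / nv
    ref = SUPERIOR if abs(np.dot(view, SUPERIOR)) <= 0.99 else ANTERIOR
    up = ref - np.dot(ref, view) * view
    up = up / np.linalg.norm(up)
    return CameraPose(position=pos, view_dir=view, up=up, fov_deg=fov_deg,
                      principal_point=np.zeros(2))


# ---------------------------------------------------------------------------
# projection and quadrants


def project_segment(cam: CameraPose, polyline, child_id: int = -1) -> ProjectedSegment:
    """Perspective-project a child polyline into the camera image.

    Points behind the camera (cz <= 0) or outside the field-of-view cone are
    dropped (and counted); projecting every point away raises
    :class:`SegmentNotVisibleError`.
    """
    pts = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty polyline")
    rel = pts - cam.position
    cx = rel @ cam.right
    cy = rel @ cam.up
    cz = rel @ cam.view_dir
    half = np.deg2rad(cam.fov_deg / 2.0)
    keep = (cz > 0) & (np.hypot(cx, cy) <= np.tan(half) * cz)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise SegmentNotVisibleError(
            f"segment {child_id}: no point projects inside the view frustum")
    p2d = np.stack([cx[keep] / cz[keep], cy[keep] / cz[keep]], axis=1)
    p2d = p2d - cam.principal_point
    counts = _quadrant_counts(p2d)
    # most distal in-frustum point (polylines are ordered proximal -> distal)
    distal_q = _point_quadrant(p2d[-1])
    quadrant = _majority(counts, distal_q)
    mean = p2d.mean(axis=0)
    mean_angle = float(np.degrees(np.arctan2(mean[1], mean[0])))
    return ProjectedSegment(child_id=child_id, points2d=p2d, quadrant=quadrant,
                            quadrant_counts=counts, mean_angle_deg=mean_angle,
                            n_dropped=n_dropped)


def _point_quadrant(p) -> str:
    x, y = p
    if x >= 0:
        return "I" if y >= 0 else "IV"
    return "II" if y >= 0 else "III"


def _quadrant_counts(p2d: np.ndarray) -> dict[str, int]:
    x, y = p2d[:, 0], p2d[:, 1]
    return {"I": int(((x >= 0) & (y >= 0)).sum()),
            "II": int(((x < 0) & (y >= 0)).sum()),
            "III": int(((x < 0) & (y < 0)).sum()),
            "IV": int(((x >= 0) & (y < 0)).sum())}


def _majority(counts: dict[str, int], tie_break: str) -> str:
    best = max(counts.values())
    winners = [q for q in QUADRANTS if counts[q] == best]
    if len(winners) == 1:
        return winners[0]
    return tie_break if tie_break in winners else winners[0]


def assign_quadrant(proj: ProjectedSegment) -> str:
    """Majority quadrant of a projected segment (ties: most distal point)."""
    if len(proj.points2d) == 0:
        raise SegmentNotVisibleError("segment has no in-frustum points")
    return _majority(proj.quadrant_counts, _point_quadrant(proj.points2d[-1]))


# ---------------------------------------------------------------------------
# labelling


def _is_up(q: str) -> bool:
    return q in ("I", "II")


def _is_right(q: str) -> bool:
    return q in ("I", "IV")


def label_pair(onpath: ProjectedSegment, sibling: ProjectedSegment) -> tuple[str, str]:
    """Simplified command pair for two sibling segments.

    Drops the quadrant word the two share: different vertical halves give
    "go up"/"go down" (this rule also takes precedence for diagonal pairs),
    same vertical but different horizontal halves give "go right"/"go left".
    Children in the same quadrant are split along the axis of larger
    separation between their mean projected points.
    """
    q1, q2 = onpath.quadrant, sibling.quadrant
    if _is_up(q1) != _is_up(q2):
        return (("go up", "go down") if _is_up(q1) else ("go down", "go up"))
    if _is_right(q1) != _is_right(q2):
        return (("go right", "go left") if _is_right(q1) else ("go left", "go right"))
    # same quadrant: order by angular position via the mean projected points
    m1, m2 = onpath.mean_point, sibling.mean_point
    dx, dy = abs(m1[0] - m2[0]), abs(m1[1] - m2[1])
    if dx > dy:
        return (("go right", "go left") if m1[0] >= m2[0] else ("go left", "go right"))
    return (("go up", "go down") if m1[1] >= m2[1] else ("go down", "go up"))


# ---------------------------------------------------------------------------
# roadmap


def encode_instructions(path: NavigationPath, tree: AirwayTree,
                        setback_mm: float = 5.0, fov_deg: float = 120.0,
                        close_mm: float = 6.0,
                        merge_close: bool = False) -> Roadmap:
    """Encode a navigation path as an ordered per-bifurcation roadmap.

    One instruction per internal path bifurcation (count = n - 1 without
    merging), ordered proximal to distal and enumerated by bronchial level.
    """
    n = path.n
    instructions: list[Instruction] = []
    projections: list[dict] = []
    d = 1
    while d <= n - 1:
        seg = path.segments[d - 1]
        bif_id = seg.distal
        bif_point = seg.points[-1]
        children = tree.children(bif_id)
        if len(children) < 2:
            raise ValueError(f"path node {bif_id} at level {d} is not a bifurcation")
        onpath_child = path.segments[d].distal
        try:
            cam = bifurcation_camera(path, d, setback_mm, fov_deg)
            projs = {
                c: project_segment(cam, tree.edge_polyline(bif_id, c)[1:], child_id=c)
                for c in children
            }
        except SegmentNotVisibleError as exc:
            raise SegmentNotVisibleError(f"bifurcation {bif_id}: {exc}") from exc

        next_is_bif = d + 1 <= n - 1
        close = False
        if next_is_bif:
            next_bif = path.segments[d].points[-1]
            close = float(np.linalg.norm(next_bif - bif_point)) < close_mm

        labels = {c: QUADRANT_NAMES[projs[c].quadrant] for c in children}
        non_binary = len(children) > 2

        if close and merge_close:
            # unify the two near-coincident levels into one instruction:
            # steer by the on-path grandchild's full quadrant as seen from
            # this camera (the view in which all three lumens appear)
            grand_bif = path.segments[d].distal
            grandchild = path.segments[d + 1].distal
            gproj = project_segment(
                cam, tree.edge_polyline(grand_bif, grandchild)[1:], child_id=grandchild)
            for gc in tree.children(grand_bif):
                p = project_segment(cam, tree.edge_polyline(grand_bif, gc)[1:], child_id=gc)
                labels[gc] = QUADRANT_NAMES[p.quadrant]
                projs[gc] = p
            text = "go " + QUADRANT_NAMES[gproj.quadrant]
            instructions.append(Instruction(
                level=d, node_id=bif_id, onpath_child=grandchild, labels=labels,
                text=text, non_binary=non_binary, close_levels=True, merged=True))
            projections.append({"node_id": bif_id, "camera": cam,
                                "segments": [projs[c] for c in sorted(projs)]})
            d += 2
            continue

        if non_binary:
            text = "go " + QUADRANT_NAMES[projs[onpath_child].quadrant]
        else:
            sibling = next(c for c in children if c != onpath_child)
            text, _ = label_pair(projs[onpath_child], projs[sibling])
        instructions.append(Instruction(
            level=d, node_id=bif_id, onpath_child=onpath_child, labels=labels,
            text=text, non_binary=non_binary, close_levels=close))
        projections.append({"node_id": bif_id, "camera": cam,
                            "segments": [projs[c] for c in sorted(projs)]})
        d += 1

    return Roadmap(instructions=instructions, projections=projections,
                   lesion=path.lesion, anchor_gap_mm=path.anchor.gap_mm)


# ---------------------------------------------------------------------------
# export


def export_roadmap(rm: Roadmap, out_dir, formats=("json", "txt", "png"),
                   allow_empty: bool = False) -> list[Path]:
    """Write the roadmap as JSON, numbered plain text, and a schematic PNG
    mosaic (one panel per bifurcation: projected child points, quadrant
    cross, arrow toward the chosen direction)."""
    if not rm.instructions and not allow_empty:
        raise ValueError("empty roadmap (pass allow_empty=True to export anyway)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    formats = set(formats)
    if "json" in formats:
        p = out_dir / "roadmap.json"
        p.write_text(json.dumps(rm.to_dict(), indent=1))
        written.append(p)
    if "txt" in formats:
        p = out_dir / "roadmap.txt"
        lines = [f"{i + 1}. (level {ins.level}) {ins.text}"
                 for i, ins in enumerate(rm.instructions)]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(p)
    if "png" in formats and rm.instructions:
        written.append(_render_mosaic(rm, out_dir / "roadmap.png"))
    return written


def _render_mosaic(rm: Roadmap, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(rm.instructions)
    ncols = min(4, k)
    nrows = (k + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows),
                             squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    for i, (ins, proj) in enumerate(zip(rm.instructions, rm.projections)):
        ax = axes.flat[i]
        ax.axis("on")
        for seg in proj["segments"]:
            marker = "o" if seg.child_id == ins.onpath_child else "."
            ax.plot(seg.points2d[:, 0], seg.points2d[:, 1], marker, ms=3,
                    label=f"child {seg.child_id} ({seg.quadrant})")
        ax.axhline(0.0, color="0.6", ls=":")
        ax.axvline(0.0, color="0.6", ls=":")
        chosen = next(s for s in proj["segments"] if s.child_id == ins.onpath_child)
        m = chosen.mean_point
        ax.annotate("", xy=m, xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:red"))
        ax.set_title(f"{i + 1}. level {ins.level}: {ins.text}", fontsize=9)
        ax.set_aspect("equal")
        ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def roadmap_from_json(path) -> Roadmap:
    return Roadmap.from_dict(json.loads(Path(path).read_text()))
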