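"""Synthetic branching-airway CT phantoms with exact ground truth.

A phantom is a recursive binary tree of straight tubular branches: a dark
lumen (air, ~ -1000 HU) wrapped in a brighter wall, embedded in lung
parenchyma background, with optional Gaussian noise.  Branch directions are
obtained by rotating the parent direction by +/- the branching angle in a
plane that alternates between two split axes level by level — emulating the
roughly alternating coronal/sagittal branching planes of real airways.

Every phantom carries its exact ground truth: the analytic centerline tree
(:func:`truth_tree`) and the exact lumen mask (:func:`true_lumen_mask`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .tree import AirwayTree, TreeNode
from .volume import CTVolume

__all__ = [
    "Branch",
    "PhantomTree",
    "generate_phantom_spec",
    "rasterize_phantom",
    "true_lumen_mask",
    "truth_tree",
    "fit_spacing",
]


@dataclass
class Branch:
    parent: int | None
    start: np.ndarray      # world mm
    direction: np.ndarray  # unit vector
    length: float          # mm
    radius: float          # lumen radius, mm
    level: int

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("branch direction must be unit-norm")

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length * self.direction


@dataclass
class PhantomTree:
    """Generative specification of a synthetic airway tree."""

    branches: list[Branch]
    lumen_hu: float = -1000.0
    wall_hu: float = -100.0
    wall_thickness_mm: float = 1.5
    background_hu: float = -850.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branches[0].parent is not None:
            raise ValueError("root branch must have parent None")
        for b in self.branches:
            if b.parent is not None and b.radius > self.branches[b.parent].radius + 1e-9:
                raise ValueError("child radius exceeds parent radius")

    def children_of(self, i: int) -> list[int]:
        return [k for k, b in enumerate(self.branches) if b.parent == i]


def _rotate_in_plane(u: np.ndarray, axis_hint: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate unit vector ``u`` by ``angle_deg`` toward ``axis_hint`` within
    the plane spanned by both."""
    b = axis_hint - np.dot(axis_hint, u) * u
    nb = np.linalg.norm(b)
    if nb < 1e-9:  # hint parallel to direction; pick any perpendicular
        b = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(b) < 1e-9:
            b = np.cross(u, [0.0, 1.0, 0.0])
        nb = np.linalg.norm(b)
    b = b / nb
    t = np.deg2rad(angle_deg)
    v = np.cos(t) * u + np.sin(t) * b
    return v / np.linalg.norm(v)


def generate_phantom_spec(
    levels: int,
    branch_angle_deg: float = 35.0,
    length_ratio: float = 0.75,
    radius_ratio: float = 0.79,
    jitter_sd: float = 0.0,
    seed: int = 0,
    trachea_length_mm: float = 40.0,
    trachea_radius_mm: float = 8.0,
    root_start=(0.0, 0.0, 0.0),
    root_direction=(0.0, 0.0, -1.0),
    split_axes=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
    close_bifurcation_mm: float | None = None,
    noise_sd_hu: float = 0.0,
    **hu_kwargs,
) -> PhantomTree:
    """Generate a binary branching-tube specification.

    ``levels`` counts branch generations (trachea = generation 0), giving
    ``2**levels - 1`` branches.  Children rotate the parent direction by
    +/- ``branch_angle_deg`` (plus Gaussian jitter of ``jitter_sd`` degrees)
    in a plane that alternates between the two ``split_axes``.

    ``close_bifurcation_mm``, when set, shortens the first child of the
    trachea to that length so its distal bifurcation lies within the given
    distance of its parent bifurcation (the "three lumens in one view"
    condition near-coincident levels produce).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if not (0.0 < radius_ratio <= 1.0):
        raise ValueError("radius_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    axes = [np.asarray(a, dtype=float) for a in split_axes]
    root = Branch(None, np.asarray(root_start, float),
                  np.asarray(root_direction, float) / np.linalg.norm(root_direction),
                  trachea_length_mm, trachea_radius_mm, 0)
    branches = [root]
    frontier = [0]
    for level in range(1, levels):
        new_frontier = []
        for pi in frontier:
            parent = branches[pi]
            axis = axes[parent.level % len(axes)]
            # nominal cascade, so a deliberately shortened branch does not
            # propagate its length to descendants
            length = trachea_length_mm * length_ratio ** level
            radius = parent.radius * radius_ratio
            for sign in (+1.0, -1.0):
                angle = sign * branch_angle_deg + rng.normal(0.0, jitter_sd)
                direction = _rotate_in_plane(parent.direction, axis, angle)
                blen = length
                if (close_bifurcation_mm is not None and parent.parent is None
                        and sign > 0):
                    blen = close_bifurcation_mm
                branches.append(Branch(pi, parent.end, direction, blen, radius, level))
                new_frontier.append(len(branches) - 1)
        frontier = new_frontier
    return PhantomTree(branches=branches, seed=seed, noise_sd_hu=noise_sd_hu, **hu_kwargs)


# ---------------------------------------------------------------------------
# rasterization


def _bounds(spec: PhantomTree, margin_mm: float) -> tuple[np.ndarray, np.ndarray]:
    pts = np.concatenate([[b.start, b.end] for b in spec.branches])
    pad = max(b.radius for b in spec.branches) + spec.wall_thickness_mm + margin_mm
    return pts.min(axis=0) - pad, pts.max(axis=0) + pad


def fit_spacing(spec: PhantomTree, shape=(128, 128, 128), margin_mm: float = 4.0) -> np.ndarray:
    """Isotropic spacing that fits the phantom in a grid of the given shape."""
    lo, hi = _bounds(spec, margin_mm)
    shape = np.asarray(shape)
    s = float(np.max((hi - lo) / (shape - 1)))
    return np.full(3, s)


def _paint(spec: PhantomTree, shape, spacing, affine, radius_pad, min_radius_mm=0.0):
    """Boolean mask of voxels within (radius + radius_pad) of any branch axis."""
    out = np.zeros(shape, dtype=bool)
    inv_lin = np.linalg.inv(affine[:3, :3])
    origin = affine[:3, 3]
    shape = np.asarray(shape)
    for b in spec.branches:
        if b.radius < min_radius_mm:
            continue
        r = b.radius + radius_pad
        lo_w = np.minimum(b.start, b.end) - r
        hi_w = np.maximum(b.start, b.end) + r
        lo = np.floor((lo_w - origin) @ inv_lin.T).astype(int)
        hi = np.ceil((hi_w - origin) @ inv_lin.T).astype(int)
        lo = np.clip(lo, 0, shape - 1)
        hi = np.clip(hi, 0, shape - 1)
        if np.any(hi < lo):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d] + 1) for d in range(3)],
                                 indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        pts = ijk @ affine[:3, :3].T + origin
        # point-to-segment (capsule) distance
        d = pts - b.start
        t = np.clip(np.tensordot(d, b.direction, axes=([-1], [0])), 0.0, b.length)
        closest = b.start + t[..., None] * b.direction
        dist = np.linalg.norm(pts - closest, axis=-1)
        sub = out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub |= dist <= r
    return out


def _grid_affine(spec: PhantomTree, shape, spacing) -> np.ndarray:
    """Grid placement: centred laterally, superior extent at the grid top
    (as in a chest scan, where the trachea reaches the first slices)."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    lo, hi = _bounds(spec, 0.0)
    center = (lo + hi) / 2.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = center - spacing * (shape - 1) / 2.0
    affine[2, 3] = hi[2] - spacing[2] * (shape[2] - 1)  # top-align z
    return affine


def rasterize_phantom(spec: PhantomTree, shape=(128, 128, 128), spacing=None) -> CTVolume:
    """Rasterize a phantom specification into a CT volume in HU.

    Voxels within the lumen radius of a branch axis get the lumen HU, a
    shell of the wall thickness gets the wall HU, everything else the
    background HU; Gaussian noise (sd ``spec.noise_sd_hu``) is added last.
    The grid is centred on the tree's bounding box.
    """
    shape = tuple(int(s) for s in shape)
    if spacing is None:
        spacing = fit_spacing(spec, shape)
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    affine = _grid_affine(spec, shape, spacing)

    lo, hi = _bounds(spec, 0.0)
    extent = np.asarray(shape) * spacing
    if np.any(hi - lo > extent):
        warnings.warn("phantom does not fit in the grid; branches truncated")
    thin = [i for i, b in enumerate(spec.branches) if b.radius < spacing.min()]
    if thin:
        warnings.warn(f"{len(thin)} branch(es) thinner than one voxel; truncated")
    min_r = spacing.min()

    lumen = _paint(spec, shape, spacing, affine, 0.0, min_radius_mm=min_r)
    wall = _paint(spec, shape, spacing, affine, spec.wall_thickness_mm, min_radius_mm=min_r)
    vol = np.full(shape, spec.background_hu, dtype=np.float32)
    vol[wall & ~lumen] = spec.wall_hu
    vol[lumen] = spec.lumen_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)
    return CTVolume(voxels=vol, affine=affine)


def true_lumen_mask(spec: PhantomTree, vol: CTVolume, min_radius_mm: float = 0.0) -> np.ndarray:
    """Exact lumen mask of the phantom on the grid of ``vol``.

    ``min_radius_mm`` restricts the mask to branches at least that thick
    (e.g. for scoring only branches of radius >= 2 voxels).
    """
    return _paint(spec, vol.shape, vol.spacing, vol.affine, 0.0,
                  min_radius_mm=max(min_radius_mm, vol.spacing.min()))


# ---------------------------------------------------------------------------
# ground truth tree


def truth_tree(spec: PhantomTree, samples_per_mm: float = 2.0) -> AirwayTree:
    """Analytic ground-truth centerline tree of a phantom.

    Nodes sit at branch endpoints (root at the trachea entry); each edge's
    polyline samples the straight branch axis at ``samples_per_mm``.
    """
    nodes = [TreeNode(id=0, point=spec.branches[0].start, kind="root", level=0)]
    edges: dict[tuple[int, int], np.ndarray] = {}
    end_node_of: dict[int, int] = {}  # branch index -> node id at its end
    next_id = 1
    for bi, b in enumerate(spec.branches):
        kind = "leaf" if not spec.children_of(bi) else "bifurcation"
        nid = next_id
        next_id += 1
        level = b.level + 1
        nodes.append(TreeNode(id=nid, point=b.end, kind=kind, level=level))
        end_node_of[bi] = nid
        parent_node = 0 if b.parent is None else end_node_of[b.parent]
        n = max(2, int(np.ceil(b.length * samples_per_mm)) + 1)
        t = np.linspace(0.0, b.length, n)
        poly = b.start + t[:, None] * b.direction
        edges[(parent_node, nid)] = poly
    return AirwayTree(nodes, edges, root_id=0)
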