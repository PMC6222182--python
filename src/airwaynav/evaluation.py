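"""Evaluation experiments on synthetic phantoms.

Shared by the test suite and the acceptance script: topology-recovery runs
(phantom -> segment -> skeleton -> tree, compared with ground truth),
segmentation Dice runs, and the camera-aligned constructed geometry whose
per-bifurcation instructions are known analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phantom as ph
from .instructions import encode_instructions
from .planner import plan_path
from .segmentation import dice, segment_airways
from .skeleton import (build_skeleton_graph, direct_from_root, extend_leaf_tips,
                       prune_spurs, skeletonize)
from .tree import AirwayTree
from .volume import world_from_voxel

__all__ = [
    "TopologyResult",
    "run_topology_case",
    "run_dice_case",
    "camera_aligned_spec",
    "expected_instructions",
]


@dataclass
class TopologyResult:
    seed: int
    levels: int
    isomorphic: bool
    centerline_rms_vox: float
    dice: float
    n_leaves: int
    n_true_leaves: int


def _extract_tree(vol, mask, spur_mm: float = 3.0) -> AirwayTree:
    skel = skeletonize(mask)
    graph = build_skeleton_graph(skel, mask.affine)
    graph = extend_leaf_tips(graph, mask.mask, mask.affine)
    graph = prune_spurs(graph, spur_mm, mask=mask.mask, affine=mask.affine)
    tree = direct_from_root(graph, world_from_voxel(vol, mask.seed))
    tree.validate(endpoint_tol_mm=float(np.linalg.norm(vol.spacing)) * 2)
    return tree


def _centerline_rms_vox(tree: AirwayTree, truth: AirwayTree, spacing_mm: float) -> float:
    """RMS distance (in voxels) from extracted centerline points to the
    nearest ground-truth axis sample."""
    from scipy.spatial import cKDTree

    true_pts = np.concatenate([truth.edges[e] for e in truth.directed_edges()])
    kd = cKDTree(true_pts)
    ext_pts = np.concatenate([tree.edges[e] for e in tree.directed_edges()])
    d, _ = kd.query(ext_pts)
    return float(np.sqrt(np.mean(d ** 2)) / spacing_mm)


def run_topology_case(seed: int, levels: int, shape=(128, 128, 128),
                      noise_sd_hu: float = 0.0, jitter_sd: float = 3.0) -> TopologyResult:
    """One phantom -> pipeline -> ground-truth comparison run."""
    spec = ph.generate_phantom_spec(levels=levels, seed=seed, jitter_sd=jitter_sd,
                                    noise_sd_hu=noise_sd_hu)
    vol = ph.rasterize_phantom(spec, shape=shape)
    mask = segment_airways(vol)
    tree = _extract_tree(vol, mask)
    truth = ph.truth_tree(spec, samples_per_mm=4.0)
    iso = tree.canonical_shape() == truth.canonical_shape()
    rms = _centerline_rms_vox(tree, truth, float(vol.spacing.min()))
    d = dice(mask.mask, ph.true_lumen_mask(spec, vol))
    return TopologyResult(seed=seed, levels=levels, isomorphic=iso,
                          centerline_rms_vox=rms, dice=d,
                          n_leaves=len(tree.leaves()),
                          n_true_leaves=len(truth.leaves()))


def run_dice_case(seed: int = 0, levels: int = 3, shape=(96, 96, 96),
                  noise_sd_hu: float = 0.0) -> float:
    """Dice of the segmentation against the true lumen restricted to
    branches at least two voxels in radius."""
    spec = ph.generate_phantom_spec(levels=levels, seed=seed, jitter_sd=3.0,
                                    noise_sd_hu=noise_sd_hu)
    vol = ph.rasterize_phantom(spec, shape=shape)
    mask = segment_airways(vol)
    truth_mask = ph.true_lumen_mask(spec, vol, min_radius_mm=2 * float(vol.spacing.min()))
    return dice(mask.mask & _near(truth_mask), truth_mask)


def _near(mask: np.ndarray, it: int = 2) -> np.ndarray:
    from scipy import ndimage
    return ndimage.binary_dilation(mask, np.ones((3, 3, 3), bool), iterations=it)


# ---------------------------------------------------------------------------
# camera-aligned constructed geometry


def camera_aligned_spec(levels: int = 5, branch_angle_deg: float = 30.0,
                        half_tilt_deg: float = 8.0) -> tuple[ph.PhantomTree, dict[int, str]]:
    """Binary tree whose branch planes alternate between the camera's
    horizontal and vertical image axes.

    At each bifurcation the two children deviate by the branching angle along
    the image-right axis (even generations, expected words "go right" /
    "go left") or the image-up axis (odd generations, "go up" / "go down") of
    the virtual camera that will view that bifurcation, with a small common
    tilt (``half_tilt_deg``) into the expected half-plane so each child lies
    strictly inside one quadrant.  Returns the spec plus the analytically
    expected instruction word for entering each branch.
    """
    sup = np.array([0.0, 0.0, 1.0])
    root_dir = np.array([0.0, 1.0, 0.0])
    theta = np.deg2rad(branch_angle_deg)
    phi = np.deg2rad(half_tilt_deg)
    branches = [ph.Branch(None, np.zeros(3), root_dir, 40.0, 8.0, 0)]
    expected: dict[int, str] = {}
    frontier = [0]
    for level in range(1, levels):
        nxt = []
        for pi in frontier:
            parent = branches[pi]
            u = parent.direction
            up = sup - np.dot(sup, u) * u
            up = up / np.linalg.norm(up)
            right = np.cross(up, u)  # camera right for view_dir = u
            horizontal = (parent.level % 2 == 0)
            if horizontal:
                devs = [(np.cos(phi) * right + np.sin(phi) * up, "go right"),
                        (-np.cos(phi) * right + np.sin(phi) * up, "go left")]
            else:
                devs = [(np.cos(phi) * up + np.sin(phi) * right, "go up"),
                        (-np.cos(phi) * up + np.sin(phi) * right, "go down")]
            for b, word in devs:
                direction = np.cos(theta) * u + np.sin(theta) * b
                direction = direction / np.linalg.norm(direction)
                branches.append(ph.Branch(pi, parent.end, direction,
                                          parent.length * 0.75,
                                          parent.radius * 0.79, level))
                expected[len(branches) - 1] = word
                nxt.append(len(branches) - 1)
        frontier = nxt
    return ph.PhantomTree(branches=branches), expected


def expected_instructions(truth: AirwayTree, path, expected: dict[int, str]) -> list[str]:
    """Analytic instruction words along a planned path (camera-aligned spec).

    Node ids in a :func:`airwaynav.phantom.truth_tree` follow branch order
    (node id = branch index + 1), so the expected word at each bifurcation is
    the word of the branch the path enters next.
    """
    return [expected[path.segments[d].distal - 1] for d in range(1, path.n)]
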