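"""Thinning, branch-graph condensation, pruning, DFS directing, encoding."""

import numpy as np
import networkx as nx
import pytest

import airwaynav as an
from airwaynav.skeleton import SkeletonVoxels, arc_length
from airwaynav.tree import encode_adjacency, tree_from_adjacency


def _skel_from_voxels(voxels, shape):
    """Build SkeletonVoxels from explicit voxel tuples."""
    vol = np.zeros(shape, dtype=bool)
    for v in voxels:
        vol[v] = True
    pts = np.argwhere(vol)
    pset = set(map(tuple, pts))
    deg = np.array([sum(((p[0] + dx, p[1] + dy, p[2] + dz) in pset)
                        for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                        for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0))
                    for p in map(tuple, pts)])
    return SkeletonVoxels(points=pts, degree=deg, shape=shape)


def _y_skeleton():
    """Y shape: a stem plus two diverging arms, in voxel space."""
    vox = [(15, 15, z) for z in range(20)]                    # stem
    vox += [(15 + i, 15 + i, 20 + i) for i in range(1, 12)]   # arm 1
    vox += [(15 - i, 15 + i, 20 + i) for i in range(1, 12)]   # arm 2
    vox.append((15, 15, 20))                                  # branching voxel
    return _skel_from_voxels(vox, (40, 40, 40))


class TestSkeletonize:
    def test_straight_tube_rms_within_one_voxel(self, straight_tube_volume):
        spec, vol = straight_tube_volume
        lum = an.true_lumen_mask(spec, vol)
        seed = tuple(np.argwhere(lum)[0])
        skel = an.skeletonize(an.AirwayMask(mask=lum, seed=seed, affine=vol.affine))
        b = spec.branches[0]
        w = an.world_from_voxel(vol, skel.points)
        t = (w - b.start) @ b.direction
        d = np.linalg.norm(w - (b.start + t[:, None] * b.direction), axis=1)
        assert np.sqrt(np.mean(d ** 2)) <= vol.spacing.max()

    def test_single_voxel_mask(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        skel = an.skeletonize(an.AirwayMask(mask=m, seed=(2, 2, 2), affine=np.eye(4)))
        assert np.array_equal(skel.points, [[2, 2, 2]])

    def test_y_mask_has_one_branching_voxel(self):
        # thick Y phantom: skeleton should contain exactly one junction
        spec = an.generate_phantom_spec(levels=2, trachea_length_mm=30.0,
                                        trachea_radius_mm=3.0, jitter_sd=0.0)
        vol = an.rasterize_phantom(spec, shape=(96, 96, 96), spacing=(0.7, 0.7, 0.7))
        lum = an.true_lumen_mask(spec, vol)
        seed = tuple(np.argwhere(lum)[0])
        skel = an.skeletonize(an.AirwayMask(mask=lum, seed=seed, affine=vol.affine))
        g = an.prune_spurs(an.build_skeleton_graph(skel, vol.affine), 3.0)
        assert sum(1 for n in g.nodes if g.degree(n) >= 3) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            an.AirwayMask(mask=np.zeros((3, 3, 3), bool), seed=(0, 0, 0),
                          affine=np.eye(4))


class TestBranchGraph:
    def test_straight_chain(self):
        skel = _skel_from_voxels([(2, 2, z) for z in range(50)], (5, 5, 60))
        g = an.build_skeleton_graph(skel, np.eye(4))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        poly = list(g.edges(data=True))[0][2]["polyline"]
        assert len(poly) == 50  # chain plus the two end-node caps

    def test_y_graph(self):
        g = an.build_skeleton_graph(_y_skeleton(), np.eye(4))
        degs = sorted(dict(g.degree).values())
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 3
        assert degs == [1, 1, 1, 3]

    def test_voxel_partition_conservation(self, tree3, segmented3):
        _, vol, mask = segmented3
        skel = an.skeletonize(mask)
        g = an.build_skeleton_graph(skel, mask.affine)
        n_cluster = sum(len(g.nodes[n]["voxels"]) for n in g.nodes)
        n_chain = sum(d["n_chain"] for _, _, d in g.edges(data=True))
        assert n_cluster + n_chain == len(skel.points)

    def test_disconnected_rejected(self):
        skel = _skel_from_voxels([(1, 1, 1), (8, 8, 8)], (10, 10, 10))
        with pytest.raises(ValueError, match="components"):
            an.build_skeleton_graph(skel, np.eye(4))


class TestExtendLeafTips:
    def test_recovers_eroded_tube_end(self, straight_tube_volume):
        # thinning stops about one radius short of the tip; extension must
        # recover it without overshooting past the cap centre
        spec, vol = straight_tube_volume
        lum = an.true_lumen_mask(spec, vol)
        seed = tuple(np.argwhere(lum)[0])
        skel = an.skeletonize(an.AirwayMask(mask=lum, seed=seed, affine=vol.affine))
        g = an.build_skeleton_graph(skel, vol.affine)
        ge = an.extend_leaf_tips(g, lum, vol.affine)
        b = spec.branches[0]
        ends = np.array([ge.nodes[n]["pos"] for n in ge.nodes if ge.degree(n) == 1])
        d_start = min(np.linalg.norm(e - b.start) for e in ends)
        d_end = min(np.linalg.norm(e - b.end) for e in ends)
        assert d_start <= 2.5 * vol.spacing.max()
        assert d_end <= 2.5 * vol.spacing.max()

    def test_does_not_extend_internal_edges(self, straight_tube_volume):
        spec, vol = straight_tube_volume
        lum = an.true_lumen_mask(spec, vol)
        seed = tuple(np.argwhere(lum)[0])
        skel = an.skeletonize(an.AirwayMask(mask=lum, seed=seed, affine=vol.affine))
        g = an.build_skeleton_graph(skel, vol.affine)
        ge = an.extend_leaf_tips(g, lum, vol.affine)
        assert ge.number_of_nodes() == g.number_of_nodes()
        assert ge.number_of_edges() == g.number_of_edges()


class TestPruneSpurs:
    def _graph_with_spur(self):
        g = nx.MultiGraph()
        for nid, pos in enumerate([(0, 0, 0), (0, 0, 10), (0, 0, 22),
                                   (0, 2, 12)]):
            g.add_node(nid, pos=np.array(pos, float), voxels=[])
        def add(a, b):
            poly = np.array([g.nodes[a]["pos"], g.nodes[b]["pos"]])
            g.add_edge(a, b, polyline=poly, n_chain=0, length=arc_length(poly))
        add(0, 1); add(1, 2); add(1, 3)  # node 3 is a 2.8 mm spur off node 1
        return g

    def test_spur_removed_and_node_merged(self):
        g = an.prune_spurs(self._graph_with_spur(), min_length_mm=5.0)
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        poly = list(g.edges(data=True))[0][2]["polyline"]
        assert arc_length(poly) == pytest.approx(22.0)

    def test_min_length_zero_is_identity(self):
        g0 = self._graph_with_spur()
        g = an.prune_spurs(g0, min_length_mm=0.0)
        assert g.number_of_nodes() == g0.number_of_nodes()
        assert g.number_of_edges() == g0.number_of_edges()

    def test_idempotent(self):
        once = an.prune_spurs(self._graph_with_spur(), 5.0)
        twice = an.prune_spurs(once, 5.0)
        assert nx.utils.graphs_equal(once, twice) or (
            once.number_of_nodes() == twice.number_of_nodes()
            and once.number_of_edges() == twice.number_of_edges())


class TestDirectFromRoot:
    def test_y_levels(self):
        g = an.build_skeleton_graph(_y_skeleton(), np.eye(4))
        tree = an.direct_from_root(g, (15.0, 15.0, -1.0))
        tree.validate()
        levels = sorted(n.level for n in tree.nodes.values())
        assert levels == [0, 1, 2, 2]
        assert [n.kind for n in tree.nodes.values()].count("leaf") == 2

    def test_cycle_broken_and_recorded(self):
        g = nx.MultiGraph()
        pos = {0: (0, 0, 0), 1: (0, 0, 10), 2: (5, 0, 15), 3: (-5, 0, 15)}
        for n, p in pos.items():
            g.add_node(n, pos=np.array(p, float), voxels=[])
        for a, b in [(0, 1), (1, 2), (1, 3), (2, 3)]:  # 1-2-3 cycle
            poly = np.array([g.nodes[a]["pos"], g.nodes[b]["pos"]])
            g.add_edge(a, b, polyline=poly, n_chain=0, length=arc_length(poly))
        diag = {}
        tree = an.direct_from_root(g, (0, 0, -1), diagnostics=diag)
        tree.validate()
        assert diag["discarded_edges"] == 1

    def test_phantom_isomorphic_to_truth(self, tree3):
        tree, truth = tree3
        tree.validate()
        assert tree.canonical_shape() == truth.canonical_shape()
        assert len(tree.leaves()) == len(truth.leaves())

    def test_level_increments(self, tree3):
        tree, _ = tree3
        for (p, c) in tree.edges:
            assert tree.nodes[c].level == tree.nodes[p].level + 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            an.direct_from_root(nx.MultiGraph(), (0, 0, 0))


class TestEncodeAdjacency:
    def test_path_tree_pattern(self):
        nodes = [an.TreeNode(0, (0, 0, 0), "root", 0),
                 an.TreeNode(1, (0, 0, 5), "bifurcation", 1),
                 an.TreeNode(2, (0, 0, 9), "leaf", 2)]
        edges = {(0, 1): np.array([[0, 0, 0], [0, 0, 5.0]]),
                 (1, 2): np.array([[0, 0, 5.0], [0, 0, 9.0]])}
        tree = an.AirwayTree(nodes, edges, 0)
        A, S = encode_adjacency(tree)
        assert np.triu(A, 1).sum() == 2
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        # nonzero pattern of the segment matrix equals the adjacency pattern
        filled = np.array([[S[i, j] is not None for j in range(3)] for i in range(3)])
        assert np.array_equal(filled, A.astype(bool))

    def test_round_trip_identity(self, tree3):
        tree, _ = tree3
        A, S = encode_adjacency(tree)
        back = tree_from_adjacency(tree.nodes.values(), A, S, tree.root_id)
        assert tree.equals(back)
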