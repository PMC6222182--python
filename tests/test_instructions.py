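"""Virtual camera, projection, quadrant voting, labelling, roadmap export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import airwaynav as an
from airwaynav.evaluation import camera_aligned_spec, expected_instructions
from airwaynav.instructions import (SegmentNotVisibleError, _point_quadrant,
                                    _quadrant_counts, _majority)
from airwaynav.planner import NavigationPath, PathSegment, AnchorPoint


def _vertical_path():
    """Two-segment path: straight inferior-directed trachea then a child."""
    s1 = PathSegment(0, 1, np.array([[0, 0, z] for z in range(0, -21, -1)],
                                    dtype=float), 1)
    s2 = PathSegment(1, 2, np.array([[0, 0, -20], [4, 0, -24.0]]), 2)
    anchor = AnchorPoint(edge=(1, 2), point_index=1, point=(4, 0, -24.0), gap_mm=0.0)
    return NavigationPath(segments=[s1, s2], anchor=anchor, lesion=(4, 0, -24.0))


class TestCamera:
    def test_vertical_view_falls_back_to_anterior_up(self):
        cam = an.bifurcation_camera(_vertical_path(), d=1, setback_mm=5.0)
        assert np.allclose(cam.view_dir, (0, 0, -1))
        assert np.allclose(cam.up, (0, -1, 0))  # anterior in LPS
        assert np.allclose(cam.position, (0, 0, -15))

    def test_setback_clamped_to_segment_start(self):
        cam = an.bifurcation_camera(_vertical_path(), d=1, setback_mm=500.0)
        assert np.allclose(cam.position, (0, 0, 0))

    def test_orthogonality_on_random_paths(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = rng.normal(size=3)
            b = a + rng.normal(size=3) * 5
            seg1 = PathSegment(0, 1, np.linspace(a, b, 12), 1)
            seg2 = PathSegment(1, 2, np.stack([b, b + rng.normal(size=3)]), 2)
            path = NavigationPath(segments=[seg1, seg2],
                                  anchor=AnchorPoint((1, 2), 1, seg2.points[-1], 0.0),
                                  lesion=b)
            cam = an.bifurcation_camera(path, 1)
            assert abs(np.dot(cam.view_dir, cam.up)) < 1e-9

    def test_leaf_level_rejected(self):
        with pytest.raises(ValueError):
            an.bifurcation_camera(_vertical_path(), d=2)


class TestProjection:
    def _cam(self):
        return an.CameraPose(position=(0, 0, 0), view_dir=(0, 0, -1),
                             up=(0, -1, 0), fov_deg=120.0, principal_point=(0, 0))

    def test_axis_point_projects_to_origin(self):
        p = an.project_segment(self._cam(), [[0, 0, -10.0]])
        assert np.allclose(p.points2d, [[0, 0]])

    def test_pinhole_arithmetic(self):
        cam = self._cam()
        # camera coords (1, 1, 1): right = cross(up, view) = (-1, 0, 0)
        world = (cam.position + cam.right + cam.up + cam.view_dir)
        p = an.project_segment(cam, [world])
        assert np.allclose(p.points2d, [[1.0, 1.0]])

    def test_distance_scaling_preserves_angles(self):
        rng = np.random.default_rng(2)
        cam = self._cam()
        pts = rng.normal(size=(30, 3)) * [5, 5, 2] + [0, 0, -20]
        p1 = an.project_segment(cam, pts)
        p2 = an.project_segment(cam, cam.position + 2 * (pts - cam.position))
        a1 = np.arctan2(p1.points2d[:, 1], p1.points2d[:, 0])
        a2 = np.arctan2(p2.points2d[:, 1], p2.points2d[:, 0])
        assert np.allclose(a1, a2)

    def test_points_behind_camera_dropped(self):
        p = an.project_segment(self._cam(), [[0, 0, 5.0], [0, 0, -5.0]])
        assert p.n_dropped == 1
        with pytest.raises(SegmentNotVisibleError):
            an.project_segment(self._cam(), [[0, 0, 5.0]])


class TestQuadrants:
    def test_majority_five_to_two(self):
        # five points in I, two in IV: majority wins
        pts = [[0.3, 0.4]] * 5 + [[0.3, -0.4]] * 2
        counts = _quadrant_counts(np.array(pts))
        assert counts == {"I": 5, "II": 0, "III": 0, "IV": 2}
        assert _majority(counts, tie_break="IV") == "I"

    def test_all_points_same_quadrant(self):
        pts = np.array([[0.3, 0.4]] * 4)
        assert _majority(_quadrant_counts(pts), "III") == "I"

    def test_tie_break_uses_most_distal_point(self):
        cam = an.CameraPose((0, 0, 0), (0, 0, -1), (0, -1, 0), 120.0, (0, 0))
        # 1 point in I, 1 point in IV; distal (last) point decides
        world_I = cam.position + (0.3 * cam.right + 0.4 * cam.up + cam.view_dir)
        world_IV = cam.position + (0.3 * cam.right - 0.4 * cam.up + cam.view_dir)
        p = an.project_segment(cam, [world_I, world_IV])
        assert p.quadrant == "IV"
        p = an.project_segment(cam, [world_IV, world_I])
        assert p.quadrant == "I"

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_vectorized_counts_match_per_point_loop(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(1, 60), 2))
        counts = _quadrant_counts(pts)
        loop = {"I": 0, "II": 0, "III": 0, "IV": 0}
        for p in pts:
            loop[_point_quadrant(p)] += 1
        assert counts == loop
        assert sum(counts.values()) == len(pts)


def _proj(child_id, pts):
    pts = np.asarray(pts, float)
    counts = _quadrant_counts(pts)
    return an.ProjectedSegment(child_id=child_id, points2d=pts,
                               quadrant=_majority(counts, _point_quadrant(pts[-1])),
                               quadrant_counts=counts, mean_angle_deg=0.0)


class TestLabelPair:
    def test_vertical_split_drops_common_word(self):
        onpath = _proj(1, [[0.5, 0.5]])   # I  (up-right)
        sib = _proj(2, [[0.5, -0.5]])     # IV (down-right): drop "right"
        assert an.label_pair(onpath, sib) == ("go up", "go down")

    def test_horizontal_split_drops_common_word(self):
        onpath = _proj(1, [[-0.5, 0.5]])  # II (up-left)
        sib = _proj(2, [[0.5, 0.5]])      # I  (up-right): drop "up"
        assert an.label_pair(onpath, sib) == ("go left", "go right")

    def test_diagonal_pair_uses_vertical_rule(self):
        onpath = _proj(1, [[0.5, 0.5]])   # I
        sib = _proj(2, [[-0.5, -0.5]])    # III
        assert an.label_pair(onpath, sib) == ("go up", "go down")

    def test_same_quadrant_split_along_larger_separation(self):
        # both in I; means (0.5, 0.1) vs (0.2, 0.6): larger gap vertically
        onpath = _proj(1, [[0.5, 0.1]])
        sib = _proj(2, [[0.2, 0.6]])
        assert an.label_pair(onpath, sib) == ("go down", "go up")
        # larger gap horizontally
        onpath = _proj(1, [[0.7, 0.1]])
        sib = _proj(2, [[0.1, 0.2]])
        assert an.label_pair(onpath, sib) == ("go right", "go left")


class TestEncode:
    def test_single_segment_path_has_no_instructions(self):
        spec = an.generate_phantom_spec(levels=2, jitter_sd=0.0)
        truth = an.truth_tree(spec)
        edge = (0, truth.children(0)[0])
        mid = truth.edges[edge][len(truth.edges[edge]) // 2]
        path = an.plan_path(truth, mid)
        rm = an.encode_instructions(path, truth)
        assert rm.instructions == []

    def test_instruction_count_is_segments_minus_one(self):
        spec, _ = camera_aligned_spec(levels=5)
        truth = an.truth_tree(spec)
        for leaf in truth.leaves()[:4]:
            path = an.plan_path(truth, truth.nodes[leaf].point)
            rm = an.encode_instructions(path, truth)
            assert len(rm.instructions) == path.n - 1

    def test_alternating_families_on_aligned_phantom(self):
        spec, expected = camera_aligned_spec(levels=4)
        truth = an.truth_tree(spec)
        for leaf in truth.leaves():
            path = an.plan_path(truth, truth.nodes[leaf].point)
            rm = an.encode_instructions(path, truth)
            words = [i.text for i in rm.instructions]
            assert words == expected_instructions(truth, path, expected)
            families = ["h" if w in ("go left", "go right") else "v" for w in words]
            assert families == ["h", "v", "h"]

    def test_close_bifurcation_flag_and_merge(self):
        spec = an.generate_phantom_spec(levels=4, jitter_sd=0.0,
                                        close_bifurcation_mm=4.0)
        truth = an.truth_tree(spec)
        leaf = [l for l in truth.leaves() if 2 in truth.node_path(l)][0]
        path = an.plan_path(truth, truth.nodes[leaf].point)
        rm = an.encode_instructions(path, truth, close_mm=6.0)
        assert [i.close_levels for i in rm.instructions] == [True, False, False]
        merged = an.encode_instructions(path, truth, close_mm=6.0, merge_close=True)
        assert len(merged.instructions) == len(rm.instructions) - 1
        assert merged.instructions[0].merged

    def test_deterministic(self):
        spec, _ = camera_aligned_spec(levels=4)
        truth = an.truth_tree(spec)
        path = an.plan_path(truth, truth.nodes[truth.leaves()[2]].point)
        a = an.encode_instructions(path, truth).to_dict()
        b = an.encode_instructions(path, truth).to_dict()
        assert a == b


class TestEquivariance:
    def _random_bifurcation(self, seed):
        """Random camera plus two child polylines in front of it."""
        rng = np.random.default_rng(seed)
        view = rng.normal(size=3)
        view /= np.linalg.norm(view)
        ref = np.array([0, 0, 1.0]) if abs(view[2]) <= 0.99 else np.array([0, -1.0, 0])
        up = ref - np.dot(ref, view) * view
        up /= np.linalg.norm(up)
        cam = an.CameraPose(rng.normal(size=3) * 10, view, up, 120.0, (0, 0))
        bif = cam.position + 6.0 * view
        children = []
        for _ in range(2):
            direction = view + 0.7 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            t = np.linspace(0.5, 12.0, 15)
            children.append(bif + t[:, None] * direction)
        return cam, children

    def _pair_words(self, cam, children):
        p1 = an.project_segment(cam, children[0], 1)
        p2 = an.project_segment(cam, children[1], 2)
        return an.label_pair(p1, p2)

    def test_mirror_swaps_left_right(self):
        swap = {"go left": "go right", "go right": "go left"}
        for seed in range(30):
            cam, children = self._random_bifurcation(seed)
            r = cam.right
            mirrored = [c - 2 * ((c - cam.position) @ r)[:, None] * r
                        for c in children]
            w = self._pair_words(cam, children)
            m = self._pair_words(cam, mirrored)
            assert m == tuple(swap.get(x, x) for x in w)

    def test_camera_roll_180_maps_to_diagonal(self):
        opposite = {"go up": "go down", "go down": "go up",
                    "go left": "go right", "go right": "go left"}
        for seed in range(30):
            cam, children = self._random_bifurcation(seed)
            rolled = an.CameraPose(cam.position, cam.view_dir, -cam.up,
                                   cam.fov_deg, cam.principal_point)
            w = self._pair_words(cam, children)
            r = self._pair_words(rolled, children)
            assert r == tuple(opposite[x] for x in w)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 100.0))
    def test_quadrant_invariant_under_positive_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 2))
        a = _majority(_quadrant_counts(pts), _point_quadrant(pts[-1]))
        b = _majority(_quadrant_counts(pts * scale), _point_quadrant(pts[-1] * scale))
        assert a == b


class TestExport:
    def _roadmap(self):
        spec, _ = camera_aligned_spec(levels=4)
        truth = an.truth_tree(spec)
        path = an.plan_path(truth, truth.nodes[truth.leaves()[0]].point)
        return an.encode_instructions(path, truth)

    def test_txt_has_numbered_lines(self, tmp_path):
        rm = self._roadmap()
        an.export_roadmap(rm, tmp_path, formats=("txt",))
        lines = (tmp_path / "roadmap.txt").read_text().splitlines()
        assert len(lines) == 3
        assert all(l.startswith(f"{i + 1}.") for i, l in enumerate(lines))

    def test_json_round_trip(self, tmp_path):
        rm = self._roadmap()
        an.export_roadmap(rm, tmp_path, formats=("json",))
        back = an.roadmap_from_json(tmp_path / "roadmap.json")
        assert back.to_dict() == rm.to_dict()

    def test_png_flag_off_writes_no_images(self, tmp_path):
        an.export_roadmap(self._roadmap(), tmp_path, formats=("json", "txt"))
        assert not list(tmp_path.glob("*.png"))

    def test_png_mosaic_written(self, tmp_path):
        an.export_roadmap(self._roadmap(), tmp_path, formats=("png",))
        assert (tmp_path / "roadmap.png").exists()

    def test_empty_roadmap_needs_flag(self, tmp_path):
        rm = an.Roadmap(instructions=[], projections=[], lesion=(0, 0, 0),
                        anchor_gap_mm=0.0)
        with pytest.raises(ValueError):
            an.export_roadmap(rm, tmp_path)
        an.export_roadmap(rm, tmp_path, allow_empty=True)
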