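"""Node ranks, densities, branch-end clustering, branching-angle frames."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinemesh.graph import BranchRecord, NodeRecord, SkeletonGraph
from spinemesh.spatial import boundary_distance_field
from spinemesh.topology import (
    AngleTriple,
    branch_end_clustering_test,
    branching_angles_rank3,
    node_density,
    node_rank_distribution,
    standardize_rank3_frame,
)
from spinemesh.volume import LABEL_CYTOSOL, LABEL_EXTRACELLULAR, LabelMask


def star_graph(directions, origin=(50.0, 50.0, 50.0), length=20.0):
    """Rank-n node at the origin with straight branches along given unit
    directions."""
    g = SkeletonGraph()
    origin = np.asarray(origin, float)
    g.nodes[0] = NodeRecord(0, origin)
    for i, d in enumerate(directions, start=1):
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        g.nodes[i] = NodeRecord(i, origin + length * d)
        poly = origin + np.linspace(0, length, 9)[:, None] * d
        b = BranchRecord(i - 1, 0, i, poly)
        b.finalize()
        g.branches[i - 1] = b
    g.recompute_ranks()
    return g


class TestRankDistribution:
    def test_single_y_junction_is_pure_rank3(self):
        g = star_graph([(0, 0, 1), (0, 1, 0), (0, -1, -1)])
        df = node_rank_distribution(g)
        row = df[df.domain == "all"].iloc[0]
        assert row.rank3_fraction == 1.0
        assert row.n_ends == 3

    def test_crossing_chains_are_rank4(self):
        g = star_graph([(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0)])
        row = node_rank_distribution(g)[lambda d: d.domain == "all"].iloc[0]
        assert row.rank4_fraction == 1.0

    def test_crosslinks_raise_rank4_fraction(self, small_phantom, crosslinked_phantom):
        _, _, net0 = small_phantom
        _, _, net1 = crosslinked_phantom
        def r4(net):
            junc = [n for n in net.nodes.values() if n.rank >= 3]
            return sum(1 for n in junc if n.rank == 4) / len(junc)
        assert r4(net1) > r4(net0)


class TestNodeDensity:
    def test_unit_conversion(self):
        # 100 junctions in 10^6 nm^3 of cytosol = 10^5 per um^3
        side = int(round((1e6) ** (1 / 3) / 2.0))  # 50 voxels at 2 nm
        labels = np.full((side, side, side), LABEL_CYTOSOL, dtype=np.uint8)
        mask = LabelMask(labels, voxel_pitch=2.0)
        g = SkeletonGraph()
        rng = np.random.default_rng(0)
        for i in range(100):
            g.nodes[i] = NodeRecord(i, rng.uniform(0, 100, 3), rank=3)
        dens = node_density(g, mask)["all"]
        assert dens == pytest.approx(1e5, rel=1e-6)

    def test_empty_graph(self):
        labels = np.full((10, 10, 10), LABEL_CYTOSOL, dtype=np.uint8)
        assert node_density(SkeletonGraph(), LabelMask(labels))["all"] == 0.0


class TestBranchEndClustering:
    def _slab_field(self):
        labels = np.full((30, 40, 40), LABEL_CYTOSOL, dtype=np.uint8)
        labels[:2] = LABEL_EXTRACELLULAR
        mask = LabelMask(labels, voxel_pitch=2.0)
        return mask, boundary_distance_field(mask)

    def _graph_with_ends(self, positions):
        g = SkeletonGraph()
        far = np.array([50.0, 40.0, 40.0])
        for i, p in enumerate(positions):
            a, b = 2 * i, 2 * i + 1
            g.nodes[a] = NodeRecord(a, np.asarray(p, float))
            g.nodes[b] = NodeRecord(b, far + i)
            br = BranchRecord(i, a, b, np.linspace(p, far + i, 5))
            br.finalize()
            g.branches[i] = br
        g.recompute_ranks()
        return g

    def test_two_ends_observed_mean_is_separation(self):
        mask, f = self._slab_field()
        g = self._graph_with_ends([[6.0, 20, 20], [6.0, 20, 32]])
        obs, rand, p = branch_end_clustering_test(g, f, shell=10.0, seed=0, n_rand=20)
        assert obs == pytest.approx(12.0, abs=1e-6)

    def test_tight_pairs_detected_as_clustered(self):
        mask, f = self._slab_field()
        rng = np.random.default_rng(1)
        pos = []
        for _ in range(12):
            base = rng.uniform([5.0, 8, 8], [7.0, 72, 72])
            pos += [base, base + [0, 0, 4.0]]
        g = self._graph_with_ends(pos)
        obs, rand, p = branch_end_clustering_test(g, f, shell=10.0, seed=2, n_rand=60)
        assert obs < rand
        assert p < 0.05

    def test_null_calibration(self):
        """Ends placed by the uniform null itself reject at ~alpha."""
        mask, f = self._slab_field()
        shell_idx = np.argwhere((f.dt < 10.0) & mask.cytosol())
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 50
        for _ in range(reps):
            pick = rng.choice(len(shell_idx), size=15, replace=False)
            pts = (shell_idx[pick] + rng.uniform(0, 1, (15, 3))) * 2.0
            g = self._graph_with_ends(pts)
            _, _, p = branch_end_clustering_test(
                g, f, shell=10.0, seed=int(rng.integers(2**31)), n_rand=40
            )
            rejections += p < 0.05
        assert rejections / reps <= 0.16  # 5% nominal + MC slack

    def test_too_few_ends_returns_none(self):
        mask, f = self._slab_field()
        g = self._graph_with_ends([[6.0, 20, 20]])
        assert branch_end_clustering_test(g, f, shell=10.0) is None


class TestBranchingAngles:
    def test_orthogonal_axes(self):
        g = star_graph([(0, 0, 1), (0, 1, 0), (1, 0, 0)])
        (t,) = branching_angles_rank3(g)
        assert np.allclose(t.angles, [90, 90, 90], atol=1e-9)
        assert t.angle_sum == pytest.approx(270.0)

    def test_planar_70_110_180(self):
        a70 = np.radians(70.0)
        g = star_graph(
            [(0, 0, 1), (0, 0, -1), (0, np.sin(a70), np.cos(a70))]
        )
        (t,) = branching_angles_rank3(g)
        assert np.allclose(t.angles, [70, 110, 180], atol=1e-6)
        assert t.angle_sum == pytest.approx(360.0, abs=1e-6)

    def test_symmetric_120s(self):
        dirs = [
            (0, np.sin(a), np.cos(a))
            for a in np.radians([0.0, 120.0, 240.0])
        ]
        (t,) = branching_angles_rank3(star_graph(dirs))
        assert np.allclose(t.angles, [120, 120, 120], atol=1e-9)

    def test_angle_sum_bounded_for_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            dirs = rng.standard_normal((3, 3))
            (t,) = branching_angles_rank3(star_graph(dirs))
            assert t.angle_sum <= 360.0 + 1e-6

    def test_rotation_invariance_exact(self):
        rng = np.random.default_rng(5)
        dirs = rng.standard_normal((3, 3))
        (t0,) = branching_angles_rank3(star_graph(dirs))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        (t1,) = branching_angles_rank3(star_graph(dirs @ q.T))
        assert np.allclose(t0.angles, t1.angles, atol=1e-8)


def _triple_from_dirs(dirs):
    dirs = np.asarray(dirs, float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    angs = sorted(
        float(np.degrees(np.arccos(np.clip(np.dot(dirs[i], dirs[j]), -1, 1))))
        for i, j in ((0, 1), (0, 2), (1, 2))
    )
    return AngleTriple(0, tuple(angs), sum(angs), dirs)


class TestStandardizedFrame:
    def test_standard_frame_fixed_point(self):
        a70 = np.radians(70.0)
        dirs = np.array(
            [[0, 0, -1.0], [0, 0, 1.0], [0, np.sin(a70), np.cos(a70)]]
        )
        out = standardize_rank3_frame(_triple_from_dirs(dirs))
        assert np.allclose(out[0], [-1, 0, 0], atol=1e-9)
        assert out[1][2] == pytest.approx(0.0, abs=1e-9)
        assert out[1][1] > 0
        assert out[2][2] >= -1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dirs = rng.standard_normal((3, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        t0 = _triple_from_dirs(dirs)
        try:
            base = standardize_rank3_frame(t0)
        except ValueError:
            return  # degenerate draw
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))  # proper-ish orthogonal, det +-1
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        rot = standardize_rank3_frame(_triple_from_dirs(dirs @ q.T))
        assert np.allclose(base, rot, atol=1e-6)

    def test_mirror_maps_to_same_frame(self):
        rng = np.random.default_rng(9)
        dirs = rng.standard_normal((3, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        base = standardize_rank3_frame(_triple_from_dirs(dirs))
        mirrored = dirs.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        out = standardize_rank3_frame(_triple_from_dirs(mirrored))
        assert np.allclose(base, out, atol=1e-8)

    def test_angles_preserved(self):
        rng = np.random.default_rng(10)
        dirs = rng.standard_normal((3, 3))
        t = _triple_from_dirs(dirs)
        out = standardize_rank3_frame(t)
        angs = sorted(
            float(np.degrees(np.arccos(np.clip(np.dot(out[i], out[j]), -1, 1))))
            for i, j in ((0, 1), (0, 2), (1, 2))
        )
        assert np.allclose(angs, t.angles, atol=1e-9)

    def test_collinear_rejected(self):
        dirs = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            standardize_rank3_frame(_triple_from_dirs(dirs))
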