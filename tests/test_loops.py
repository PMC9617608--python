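"""Elementary loops, loop-plane PCA, pore estimate, MST pruning."""

import itertools

import networkx as nx
import numpy as np
import pytest

from spinemesh.graph import BranchRecord, NodeRecord, SkeletonGraph
from spinemesh.loops import (
    ElementaryLoop,
    elementary_loops,
    loop_planarity_pca,
    merge_rank2_nodes,
    minimum_spanning_tree_prune,
    pore_diameter_estimate,
    prune_stats,
)


def graph_from_edges(edges, positions=None):
    """Build a SkeletonGraph from (a, b, length) triples."""
    g = SkeletonGraph()
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    rng = np.random.default_rng(0)
    for n in nodes:
        pos = (
            np.asarray(positions[n], float)
            if positions is not None
            else rng.uniform(0, 100, 3)
        )
        g.nodes[n] = NodeRecord(n, pos)
    for i, (a, b, L) in enumerate(edges):
        pa, pb = g.nodes[a].position, g.nodes[b].position
        poly = np.vstack([pa, pb]) if a != b else np.vstack([pa, pa + 1.0, pa])
        br = BranchRecord(i, a, b, poly)
        br.finalize()
        br.arc_length = float(L)  # prescribe the metric length
        br.euclidean_span = float(np.linalg.norm(pb - pa))
        g.branches[i] = br
    g.recompute_ranks()
    return g


def brute_force_min_cycles(g: SkeletonGraph):
    """Oracle: for every branch, the minimal-circumference cycle through
    it, found by exhaustive simple-cycle enumeration."""
    mg = nx.MultiGraph()
    for bid, b in g.branches.items():
        mg.add_edge(b.node_a, b.node_b, key=bid, length=b.arc_length)
    cycles = []
    for cyc in nx.simple_cycles(mg):
        # nx returns node lists; recover all edge-key combinations
        edges = list(zip(cyc, cyc[1:] + cyc[:1]))
        key_options = []
        for a, b in edges:
            key_options.append(list(mg[a][b].keys()))
        for combo in itertools.product(*key_options):
            if len(set(combo)) != len(combo):
                continue
            length = sum(g.branches[k].arc_length for k in combo)
            cycles.append((frozenset(combo), length))
    # per-branch minima (shortest cycle containing each branch)
    best: dict[int, tuple[set, float]] = {}
    for key, length in cycles:
        for bid in key:
            if bid not in best or length < best[bid][1] - 1e-9:
                best[bid] = ({key}, length)
            elif abs(length - best[bid][1]) <= 1e-9:
                best[bid][0].add(key)
    # per (node, incident-edge-pair) minima: the elementary-loop set is
    # the union of the shortest cycles through every such pair
    pair_best: dict[tuple, tuple[set, float]] = {}
    for key, length in cycles:
        incidence: dict[int, list[int]] = {}
        for bid in key:
            b = g.branches[bid]
            incidence.setdefault(b.node_a, []).append(bid)
            if b.node_b != b.node_a:
                incidence.setdefault(b.node_b, []).append(bid)
        for node, bids in incidence.items():
            pk = (node, frozenset(bids))
            if pk not in pair_best or length < pair_best[pk][1] - 1e-9:
                pair_best[pk] = ({key}, length)
            elif abs(length - pair_best[pk][1]) <= 1e-9:
                pair_best[pk][0].add(key)
    union = set()
    for keys, _ in pair_best.values():
        union |= keys
    return union, best


class TestElementaryLoops:
    def test_triangle(self):
        g = graph_from_edges([(0, 1, 10), (1, 2, 20), (0, 2, 30)])
        loops = elementary_loops(g)
        assert len(loops) == 1
        assert loops[0].circumference == pytest.approx(60.0)
        assert loops[0].node_count == 3

    def test_tree_has_no_loops(self):
        g = graph_from_edges([(0, 1, 5), (1, 2, 7), (1, 3, 9)])
        assert elementary_loops(g) == []

    def test_cube_graph_faces(self):
        corners = list(itertools.product((0, 1), repeat=3))
        idx = {c: i for i, c in enumerate(corners)}
        edges = []
        for c in corners:
            for ax in range(3):
                d = list(c)
                d[ax] ^= 1
                d = tuple(d)
                if idx[c] < idx[d]:
                    edges.append((idx[c], idx[d], 1.0))
        pos = {i: np.array(c, float) * 10 for c, i in idx.items()}
        g = graph_from_edges(edges, positions=pos)
        loops = elementary_loops(g)
        assert len(loops) == 6  # the six faces
        assert all(l.node_count == 4 for l in loops)
        assert all(l.circumference == pytest.approx(4.0) for l in loops)
        oracle, _ = brute_force_min_cycles(g)
        assert {l.branch_ids for l in loops} == oracle

    def test_parallel_edges_form_two_branch_loop(self):
        g = graph_from_edges([(0, 1, 10), (0, 1, 14), (1, 2, 5)])
        loops = elementary_loops(g)
        assert len(loops) == 1
        assert loops[0].circumference == pytest.approx(24.0)
        assert loops[0].node_count == 2

    def test_self_loop(self):
        g = graph_from_edges([(0, 0, 9), (0, 1, 5)])
        loops = elementary_loops(g)
        assert len(loops) == 1
        assert loops[0].node_count == 1
        assert loops[0].circumference == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        """Per-branch minimal circumference equals exhaustive enumeration
        on small random graphs (<= 12 edges)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        possible = list(itertools.combinations(range(n), 2))
        rng.shuffle(possible)
        m = int(rng.integers(n, min(len(possible), 12) + 1))
        edges = [
            (a, b, float(rng.uniform(1, 30))) for a, b in possible[:m]
        ]
        g = graph_from_edges(edges)
        loops = elementary_loops(g)
        _, best = brute_force_min_cycles(g)
        found_min: dict[int, float] = {}
        for l in loops:
            for bid in l.branch_ids:
                found_min[bid] = min(
                    found_min.get(bid, np.inf), l.circumference
                )
        for bid, (_, length) in best.items():
            assert found_min[bid] == pytest.approx(length)
        # no branch with a cycle is missed, none invented, and every loop
        # is one of the tied minimal cycles of the oracle
        assert set(found_min) == set(best)
        oracle_union, _ = brute_force_min_cycles(g)
        assert {l.branch_ids for l in loops} <= oracle_union

    def test_dedup_independent_of_node_order(self):
        edges = [(0, 1, 3), (1, 2, 4), (2, 0, 5), (2, 3, 6), (3, 0, 7)]
        g = graph_from_edges(edges)
        base = {l.branch_ids for l in elementary_loops(g)}
        # relabel nodes in reverse order; branch ids unchanged
        relabel = {0: 3, 1: 2, 2: 1, 3: 0}
        g2 = graph_from_edges(
            [(relabel[a], relabel[b], L) for a, b, L in edges]
        )
        assert base == {l.branch_ids for l in elementary_loops(g2)}


class TestLoopPlanarity:
    def _loop_of_points(self, pts):
        g = SkeletonGraph()
        for i, p in enumerate(pts):
            g.nodes[i] = NodeRecord(i, np.asarray(p, float))
        loop = ElementaryLoop(tuple(range(len(pts))), frozenset(), 1.0, len(pts))
        return g, loop

    def test_planar_square(self):
        g, loop = self._loop_of_points(
            [[0, 0, 0], [0, 0, 10], [0, 10, 10], [0, 10, 0]]
        )
        loop_planarity_pca(loop, g)
        assert loop.pca_variances[2] == pytest.approx(0.0, abs=1e-9)
        assert loop.planarity == pytest.approx(1.0)

    def test_circle_is_round(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        g, loop = self._loop_of_points(
            np.stack([np.zeros_like(t), 10 * np.sin(t), 10 * np.cos(t)], axis=1)
        )
        loop_planarity_pca(loop, g)
        assert loop.elongation == pytest.approx(1.0, abs=1e-6)

    def test_two_to_one_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        g, loop = self._loop_of_points(
            np.stack([np.zeros_like(t), 10 * np.sin(t), 20 * np.cos(t)], axis=1)
        )
        loop_planarity_pca(loop, g)
        assert loop.elongation == pytest.approx(2.0, rel=0.05)

    def test_collinear_rejected(self):
        g, loop = self._loop_of_points([[0, 0, 0], [0, 0, 5], [0, 0, 10]])
        with pytest.raises(ValueError):
            loop_planarity_pca(loop, g)


class TestPoreDiameter:
    def test_reference_case(self):
        # typical loop length 120 nm, elongation 1.47, filament 8 nm
        assert pore_diameter_estimate(120.0, 1.47, 8.0) == pytest.approx(18.0, abs=0.5)

    def test_circle_inversion(self):
        for d in (5.0, 20.0, 80.0):
            assert pore_diameter_estimate(np.pi * d, 1.0, 1e-12) == pytest.approx(d)

    def test_direct_arithmetic(self):
        assert pore_diameter_estimate(100.0, 1.0, 8.0) == pytest.approx(
            100 / np.pi - 8, abs=0.01
        )

    def test_closed_mesh_clips_to_zero(self):
        assert pore_diameter_estimate(10.0, 1.5, 8.0) == 0.0


class TestMST:
    def test_triangle_drops_shortest_branch(self):
        g = graph_from_edges([(0, 1, 10), (1, 2, 20), (0, 2, 30)])
        pruned = minimum_spanning_tree_prune(g)
        kept = {b.arc_length for b in pruned.branches.values()}
        assert kept == {20, 30}

    def test_tree_input_identity(self):
        g = graph_from_edges([(0, 1, 5), (1, 2, 7), (1, 3, 9)])
        pruned = minimum_spanning_tree_prune(g)
        assert set(pruned.branches) == set(g.branches)

    def test_nodes_equal_branches_plus_one_per_component(self, crosslinked_phantom):
        _, _, net = crosslinked_phantom
        pruned = minimum_spanning_tree_prune(net)
        mg = pruned.to_networkx()
        for comp in nx.connected_components(mg):
            sub = mg.subgraph(comp)
            assert sub.number_of_nodes() == sub.number_of_edges() + 1
        assert elementary_loops(pruned) == []

    def test_minimal_inverse_length_weight_vs_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(6):
            n = int(rng.integers(4, 6))
            possible = list(itertools.combinations(range(n), 2))
            rng.shuffle(possible)
            m = int(rng.integers(n, min(len(possible), 8) + 1))
            edges = [(a, b, float(rng.uniform(1, 30))) for a, b in possible[:m]]
            g = graph_from_edges(edges)
            mg = nx.MultiGraph()
            for bid, b in g.branches.items():
                mg.add_edge(b.node_a, b.node_b, key=bid)
            if not nx.is_connected(mg):
                continue
            pruned = minimum_spanning_tree_prune(g)
            got = sum(1.0 / g.branches[i].arc_length for i in pruned.branches)
            best = np.inf
            ids = list(g.branches)
            for combo in itertools.combinations(ids, len(g.nodes) - 1):
                t = nx.MultiGraph()
                t.add_nodes_from(g.nodes)
                for i in combo:
                    t.add_edge(g.branches[i].node_a, g.branches[i].node_b)
                if nx.is_connected(t) and t.number_of_edges() == len(g.nodes) - 1:
                    best = min(
                        best, sum(1.0 / g.branches[i].arc_length for i in combo)
                    )
            assert got == pytest.approx(best)


class TestMergeRank2:
    def test_path_concatenation(self):
        g = graph_from_edges(
            [(0, 1, 5), (1, 2, 7)],
            positions={0: [0, 0, 0], 1: [0, 0, 5], 2: [0, 0, 12]},
        )
        out = merge_rank2_nodes(g)
        assert len(out.nodes) == 2 and len(out.branches) == 1
        (b,) = out.branches.values()
        assert b.arc_length == pytest.approx(12.0)

    def test_graph_without_rank2_is_unchanged(self):
        # triangle with a pendant at each corner: every corner is rank 3
        g = graph_from_edges(
            [(0, 1, 10), (1, 2, 20), (0, 2, 30), (0, 3, 4), (1, 4, 4), (2, 5, 4)]
        )
        out = merge_rank2_nodes(g)
        assert len(out.nodes) == 6 and len(out.branches) == 6

    def test_pure_cycle_collapses_to_self_loop(self):
        # all-rank-2 cycle resolves to a single self-loop carrier
        g = graph_from_edges([(0, 1, 10), (1, 2, 20), (0, 2, 30)])
        out = merge_rank2_nodes(g)
        assert len(out.nodes) == 1 and len(out.branches) == 1
        (b,) = out.branches.values()
        assert b.node_a == b.node_b

    def test_long_chain_sums_lengths(self):
        pts = {i: [0, 0, 4.0 * i] for i in range(7)}
        edges = [(i, i + 1, 4.0) for i in range(6)]
        g = graph_from_edges(edges, positions=pts)
        out = merge_rank2_nodes(g)
        assert len(out.branches) == 1
        (b,) = out.branches.values()
        assert b.arc_length == pytest.approx(sum(L for *_, L in edges))
        # polyline traverses all original nodes in order
        assert b.polyline[0][2] == 0.0 and b.polyline[-1][2] == 24.0


class TestPruneStats:
    def test_identical_graphs_zero_reduction(self):
        g = graph_from_edges([(0, 1, 5), (1, 2, 7), (1, 3, 9)])
        st = prune_stats(g, g)
        assert st["branch_reduction_percent"] == 0.0
        assert st["node_reduction_percent"] == 0.0

    def test_triangle_mst_reduction(self):
        # MST drops one of three branches; merging the resulting rank-2
        # node joins the remaining two, so the merged graph has 1 branch
        g = graph_from_edges([(0, 1, 10), (1, 2, 20), (0, 2, 30)])
        pruned = minimum_spanning_tree_prune(g)
        st = prune_stats(g, pruned)
        assert st["branch_count_after"] == 1
        assert st["branch_reduction_percent"] == pytest.approx(200 / 3)
        # the merged branch length is the geometric length of the two
        # concatenated polylines
        expected = sum(
            np.linalg.norm(b.polyline[-1] - b.polyline[0])
            for b in pruned.branches.values()
        )
        assert st["mean_branch_length_after_nm"] == pytest.approx(expected)

    def test_merging_increases_mean_length(self, crosslinked_phantom):
        _, _, net = crosslinked_phantom
        pruned = minimum_spanning_tree_prune(net)
        st = prune_stats(net, pruned)
        if st["node_reduction_percent"] > 0:
            assert (
                st["mean_branch_length_after_nm"]
                > st["mean_branch_length_before_nm"]
            )
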