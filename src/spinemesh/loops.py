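"""Elementary loops, loop-plane geometry, pore estimate and MST pruning.

An *elementary loop* is the shortest cycle (weighted by branch length)
through a given branch.  Loops are found by deleting each node in turn,
running Dijkstra between every pair of its neighbours on the remaining
graph, and adding back the two branches incident to the deleted node;
the resulting cycles are deduplicated by their branch-id set.

The *minimum spanning tree* pruning removes loops while preferentially
discarding short branches (putative cross-links): the MST is computed per
connected component under edge weight 1/length, then rank-2 nodes left by
the pruning are merged so that their two branches concatenate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import BranchRecord, SkeletonGraph
from .volume import LabelMask


@dataclass
class ElementaryLoop:
    node_ids: tuple[int, ...]
    branch_ids: frozenset[int]
    circumference: float  # nm
    node_count: int
    pca_variances: tuple[float, float, float] | None = None
    planarity: float | None = None
    elongation: float | None = None  # epsilon = primary/secondary axis length


def _min_edge_graph(g: SkeletonGraph, skip_node: int | None = None) -> nx.Graph:
    """Simple graph keeping, per node pair, the minimum-length branch."""
    h = nx.Graph()
    for b in g.branches.values():
        if b.node_a == b.node_b:
            continue
        if skip_node is not None and skip_node in (b.node_a, b.node_b):
            continue
        if h.has_edge(b.node_a, b.node_b):
            if b.arc_length < h[b.node_a][b.node_b]["length"]:
                h[b.node_a][b.node_b].update(length=b.arc_length, branch=b.id)
        else:
            h.add_edge(b.node_a, b.node_b, length=b.arc_length, branch=b.id)
    return h


def elementary_loops(g: SkeletonGraph) -> list[ElementaryLoop]:
    """All deduplicated elementary loops of the graph (empty for trees)."""
    loops: dict[frozenset[int], ElementaryLoop] = {}

    incident: dict[int, list[BranchRecord]] = {}
    for b in g.branches.values():
        incident.setdefault(b.node_a, []).append(b)
        if b.node_b != b.node_a:
            incident.setdefault(b.node_b, []).append(b)

    for v in sorted(g.nodes):
        branches = sorted(incident.get(v, []), key=lambda b: b.id)
        # self-loops are elementary loops of a single node
        for b in branches:
            if b.node_a == b.node_b:
                key = frozenset([b.id])
                if key not in loops:
                    loops[key] = ElementaryLoop(
                        (v,), key, b.arc_length, node_count=1
                    )
        h = _min_edge_graph(g, skip_node=v)
        plain = [b for b in branches if b.node_a != b.node_b]
        for i in range(len(plain)):
            for j in range(i + 1, len(plain)):
                e1, e2 = plain[i], plain[j]
                a = e1.node_b if e1.node_a == v else e1.node_a
                c = e2.node_b if e2.node_a == v else e2.node_a
                if a == c:
                    # parallel branches: two-branch loop
                    key = frozenset([e1.id, e2.id])
                    circ = e1.arc_length + e2.arc_length
                    if key not in loops or circ < loops[key].circumference:
                        loops[key] = ElementaryLoop(
                            (v, a), key, circ, node_count=2
                        )
                    continue
                if a not in h or c not in h:
                    continue
                try:
                    length, path = nx.single_source_dijkstra(
                        h, a, c, weight="length"
                    )
                except nx.NetworkXNoPath:
                    continue
                bids = [e1.id, e2.id] + [
                    h[p][q]["branch"] for p, q in zip(path[:-1], path[1:])
                ]
                key = frozenset(bids)
                circ = e1.arc_length + e2.arc_length + length
                if key not in loops or circ < loops[key].circumference:
                    loops[key] = ElementaryLoop(
                        tuple([v, *path]), key, circ, node_count=1 + len(path)
                    )
    out = sorted(loops.values(), key=lambda l: sorted(l.branch_ids))
    return out


def loop_planarity_pca(
    loop: ElementaryLoop, g: SkeletonGraph
) -> ElementaryLoop:
    """PCA of the loop's node positions: fills ``pca_variances``,
    ``planarity`` (variance in the best-fit plane) and ``elongation``
    (primary/secondary axis length ratio, i.e. SD ratio)."""
    pos = np.array([g.nodes[n].position for n in loop.node_ids], dtype=float)
    if len(pos) < 3:
        raise ValueError("planarity needs at least three nodes")
    centred = pos - pos.mean(axis=0)
    cov = centred.T @ centred / len(pos)
    vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if vals[1] <= 1e-12 or total <= 0:
        raise ValueError("collinear loop nodes: elongation undefined")
    loop.pca_variances = tuple(float(v) for v in vals)
    loop.planarity = float((vals[0] + vals[1]) / total)
    loop.elongation = float(np.sqrt(vals[0] / vals[1]))
    return loop


def loop_statistics(g: SkeletonGraph) -> dict:
    """Summary of the elementary-loop population: mean circumference and
    node count, mean elongation, mean in-plane variance fraction."""
    loops = elementary_loops(g)
    out = dict(n_loops=len(loops))
    if not loops:
        return out
    out["mean_circumference_nm"] = float(
        np.mean([l.circumference for l in loops])
    )
    out["sd_circumference_nm"] = float(np.std([l.circumference for l in loops]))
    out["mean_node_count"] = float(np.mean([l.node_count for l in loops]))
    elong, planar = [], []
    for l in loops:
        if l.node_count >= 3:
            try:
                loop_planarity_pca(l, g)
            except ValueError:
                continue
            elong.append(l.elongation)
            planar.append(l.planarity)
    if elong:
        out["mean_elongation"] = float(np.mean(elong))
        out["mean_planarity"] = float(np.mean(planar))
    return out


def pore_diameter_estimate(
    mean_loop_length: float, epsilon: float, filament_diameter: float
) -> float:
    """Short-axis pore diameter implied by the typical elementary loop:
    loop length / (pi * epsilon) minus the filament width; clipped at 0
    (closed mesh)."""
    if min(mean_loop_length, epsilon, filament_diameter + 1) <= 0:
        raise ValueError("inputs must be positive")
    return max(mean_loop_length / (np.pi * epsilon) - filament_diameter, 0.0)


def minimum_spanning_tree_prune(g: SkeletonGraph) -> SkeletonGraph:
    """Per-component minimum spanning tree under edge weight 1/length.

    Short branches carry large weight and are preferentially dropped; the
    result is acyclic with |nodes| = |branches| + 1 per component.
    """
    mg = nx.MultiGraph()
    mg.add_nodes_from(g.nodes)
    for b in g.branches.values():
        if b.node_a == b.node_b:
            continue  # self-loops can never be tree edges
        w = 1.0 / b.arc_length if b.arc_length > 0 else np.inf
        mg.add_edge(b.node_a, b.node_b, key=b.id, weight=w)
    keep = set()
    for comp in nx.connected_components(mg):
        sub = mg.subgraph(comp)
        for a, b_, key in nx.minimum_spanning_edges(
            sub, weight="weight", keys=True, data=False
        ):
            keep.add(key)
    pruned = SkeletonGraph(voxel_pitch=g.voxel_pitch)
    pruned.nodes = {i: n for i, n in g.copy().nodes.items()}
    pruned.branches = {
        i: b for i, b in g.copy().branches.items() if i in keep
    }
    pruned.recompute_ranks()
    return pruned


def merge_rank2_nodes(g: SkeletonGraph) -> SkeletonGraph:
    """Remove every rank-2 node by concatenating its two branches
    (polylines joined, arc lengths summed); repeats until none remain.

    A rank-2 node whose two incidences belong to the same branch (a
    detached cycle) is left as the carrier of a self-loop.
    """
    out = g.copy()
    merge_rank2_inplace(out)
    return out


def merge_rank2_inplace(out: SkeletonGraph) -> None:
    """In-place version of :func:`merge_rank2_nodes`."""
    changed = True
    while changed:
        changed = False
        incident: dict[int, list[int]] = {}
        for bid, b in out.branches.items():
            incident.setdefault(b.node_a, []).append(bid)
            if b.node_b != b.node_a:
                incident.setdefault(b.node_b, []).append(bid)
        for nid, n in list(out.nodes.items()):
            if n.rank != 2:
                continue
            bids = incident.get(nid, [])
            if len(bids) != 2 or bids[0] == bids[1]:
                continue  # self-loop carrier: keep
            b1, b2 = out.branches[bids[0]], out.branches[bids[1]]
            p1 = b1.polyline if b1.node_b == nid else b1.polyline[::-1]
            p2 = b2.polyline if b2.node_a == nid else b2.polyline[::-1]
            na = b1.node_a if b1.node_b == nid else b1.node_b
            nb = b2.node_b if b2.node_a == nid else b2.node_a
            merged = BranchRecord(
                id=b1.id,
                node_a=na,
                node_b=nb,
                polyline=np.vstack([p1, p2[1:]]),
                excluded=b1.excluded or b2.excluded,
                domain=b1.domain,
            )
            merged.finalize()
            del out.branches[b2.id]
            out.branches[b1.id] = merged
            del out.nodes[nid]
            out.recompute_ranks()
            changed = True
            break
    out.recompute_ranks()


def prune_stats(
    original: SkeletonGraph,
    pruned: SkeletonGraph,
    mask: LabelMask | None = None,
    sigma_vol: float = 4.0,
) -> dict:
    """Before/after comparison of the MST pruning: branch and node
    reduction percentages, mean branch lengths, rank-1 fractions, and
    (with a mask) reconstructed volume fractions."""
    merged = merge_rank2_nodes(pruned)

    def mean_len(gr: SkeletonGraph) -> float:
        lens = [b.arc_length for b in gr.branches.values()]
        return float(np.mean(lens)) if lens else float("nan")

    def rank1_fraction(gr: SkeletonGraph) -> float:
        n = len(gr.nodes)
        return sum(1 for x in gr.nodes.values() if x.rank == 1) / n if n else float("nan")

    nb0, nb1 = original.branch_count(), merged.branch_count()
    nn0, nn1 = original.node_count(), merged.node_count()
    out = dict(
        branch_count_before=nb0,
        branch_count_after=nb1,
        branch_reduction_percent=100.0 * (nb0 - nb1) / nb0 if nb0 else 0.0,
        node_count_before=nn0,
        node_count_after=nn1,
        node_reduction_percent=100.0 * (nn0 - nn1) / nn0 if nn0 else 0.0,
        mean_branch_length_before_nm=mean_len(original),
        mean_branch_length_after_nm=mean_len(merged),
        rank1_fraction_before=rank1_fraction(original),
        rank1_fraction_after=rank1_fraction(merged),
    )
    if mask is not None:
        from .spatial import cytoskeleton_volume_fraction

        out["volume_fraction_before"] = cytoskeleton_volume_fraction(
            original, mask, sigma_vol
        )["all"]
        out["volume_fraction_after"] = cytoskeleton_volume_fraction(
            merged, mask, sigma_vol
        )["all"]
    return out
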