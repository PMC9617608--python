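"""Skeleton-to-graph conversion and branch geometry.

Skeleton voxels are classified by their number of foreground neighbours:
more than two makes a junction voxel, exactly two a branch voxel, one a
branch end.  Mutually adjacent junction voxels are merged into a single
node placed at their centre of mass.  Maximal chains of branch voxels
become branches whose polylines are smoothed once with the sliding kernel
(1, 2, 3, 2, 1)/9, pinned to the adjacent node positions.

The resulting :class:`SkeletonGraph` is an undirected multigraph: parallel
branches between the same node pair and self-loops occur in dense meshes
and are kept (and counted separately by the reporting layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage

from .skeletonize import SkeletonVoxels, _STRUCT26, _OFFSETS
from .volume import LabelMask, DOMAIN_NONE

_SMOOTH_WEIGHTS = np.array([1.0, 2.0, 3.0, 2.0, 1.0])


@dataclass
class NodeRecord:
    id: int
    position: np.ndarray  # nm
    rank: int = 0
    domain: int = DOMAIN_NONE
    boundary_flag: bool = False


@dataclass
class BranchRecord:
    id: int
    node_a: int
    node_b: int
    polyline: np.ndarray  # (N, 3) nm
    arc_length: float = 0.0
    euclidean_span: float = 0.0
    tortuosity: float | None = None
    com: np.ndarray | None = None
    domain: int = DOMAIN_NONE
    excluded: bool = False  # touches the analysis bounding box (artificial cut)

    def finalize(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.arc_length = branch_length(self.polyline)
        self.euclidean_span = float(
            np.linalg.norm(self.polyline[-1] - self.polyline[0])
        )
        self.tortuosity = (
            self.arc_length / self.euclidean_span
            if self.euclidean_span > 1e-12
            else None
        )
        self.com = self.polyline.mean(axis=0)


@dataclass
class SkeletonGraph:
    """Attributed undirected multigraph of junction nodes and branches."""

    nodes: dict[int, NodeRecord] = field(default_factory=dict)
    branches: dict[int, BranchRecord] = field(default_factory=dict)
    voxel_pitch: float = 2.0

    def recompute_ranks(self) -> None:
        for n in self.nodes.values():
            n.rank = 0
        for b in self.branches.values():
            self.nodes[b.node_a].rank += 1
            self.nodes[b.node_b].rank += 1

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for nid, n in self.nodes.items():
            g.add_node(nid, position=n.position, rank=n.rank, domain=n.domain,
                       boundary=n.boundary_flag)
        for bid, b in self.branches.items():
            g.add_edge(b.node_a, b.node_b, key=bid, length=b.arc_length,
                       weight=b.arc_length, excluded=b.excluded)
        return g

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(
            nodes={i: replace(n, position=n.position.copy())
                   for i, n in self.nodes.items()},
            branches={
                i: replace(b, polyline=b.polyline.copy(),
                           com=None if b.com is None else b.com.copy())
                for i, b in self.branches.items()
            },
            voxel_pitch=self.voxel_pitch,
        )

    # --- convenience -----------------------------------------------------
    def branch_count(self) -> int:
        return len(self.branches)

    def node_count(self) -> int:
        return len(self.nodes)

    def junction_nodes(self, min_rank: int = 3):
        return [n for n in self.nodes.values() if n.rank >= min_rank]

    def included_branches(self):
        return [b for b in self.branches.values() if not b.excluded]

    def rank1_nodes(self):
        return [n for n in self.nodes.values() if n.rank == 1]


def branch_length(polyline: np.ndarray) -> float:
    """Arc length of a polyline: sum of segment Euclidean lengths (nm)."""
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("polyline needs at least two points")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def branch_tortuosity(branch: BranchRecord) -> float:
    """Arc length divided by the Euclidean span of the branch end points."""
    if branch.euclidean_span <= 1e-12:
        raise ValueError("tortuosity undefined for zero-span (closed) branch")
    return branch.arc_length / branch.euclidean_span


def smooth_branch_curve(
    voxel_chain: np.ndarray, node_a: np.ndarray, node_b: np.ndarray
) -> np.ndarray:
    """Smooth a branch voxel chain with the sliding (1,2,3,2,1)/9 kernel.

    The first and last points of the returned polyline are the fixed node
    positions; each interior point is replaced by the weighted average of
    the five surrounding points, with the kernel truncated and
    renormalized where it overhangs the ends of the point list.
    """
    chain = np.atleast_2d(np.asarray(voxel_chain, dtype=float))
    pts = np.vstack([np.asarray(node_a, float), chain, np.asarray(node_b, float)])
    n = len(pts)
    out = pts.copy()
    for i in range(1, n - 1):
        lo = max(i - 2, 0)
        hi = min(i + 2, n - 1)
        w = _SMOOTH_WEIGHTS[lo - i + 2 : hi - i + 3]
        out[i] = (pts[lo : hi + 1] * w[:, None]).sum(axis=0) / w.sum()
    return out


def _order_chain(voxels: list[tuple[int, int, int]]) -> tuple[list, bool]:
    """Order a degree<=2 voxel component into a path or cycle.

    Returns (ordered voxel list, is_cycle).
    """
    vset = set(voxels)
    nbrs = {
        v: [
            (v[0] + dz, v[1] + dy, v[2] + dx)
            for dz, dy, dx in _OFFSETS
            if (v[0] + dz, v[1] + dy, v[2] + dx) in vset
        ]
        for v in voxels
    }
    endpoints = sorted(v for v in voxels if len(nbrs[v]) <= 1)
    if endpoints:
        start = endpoints[0]
        is_cycle = False
    else:
        start = min(voxels)
        is_cycle = True
    order = [start]
    prev = None
    cur = start
    while True:
        nxt = [n for n in nbrs[cur] if n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        order.append(cur)
        if len(order) == len(voxels) and not is_cycle:
            break
        if len(order) > len(voxels):  # safety
            break
    return order, is_cycle


def build_graph(s: SkeletonVoxels, mask: LabelMask | None = None) -> SkeletonGraph:
    """Convert a voxel skeleton into an attributed multigraph.

    Junction voxels (> 2 neighbours) are clustered by 26-adjacency into
    single nodes at their centre of mass; maximal chains of degree-2
    voxels become branches; chain ends become rank-1 nodes.  Isolated
    voxels are dropped.  Branches whose voxels touch the bounding-box
    faces are flagged ``excluded`` (artificial cuts at sub-volume
    interfaces) but kept for connectivity.
    """
    if s.count() == 0:
        raise ValueError("empty skeleton")
    pitch = s.voxel_pitch
    origin = s.origin
    counts = s.neighbor_counts()
    skel = s.mask
    nz, ny, nx_ = skel.shape

    def phys(vox) -> np.ndarray:
        return origin + (np.asarray(vox, dtype=float) + 0.5) * pitch

    def on_boundary(vox) -> bool:
        z, y, x = vox
        return (
            z in (0, nz - 1) or y in (0, ny - 1) or x in (0, nx_ - 1)
        )

    junction = skel & (counts > 2)
    chainmask = skel & (counts <= 2) & (counts > 0)

    g = SkeletonGraph(voxel_pitch=pitch)
    next_node = 0
    next_branch = 0

    # junction clusters -> nodes
    jlabels, njc = ndimage.label(junction, structure=_STRUCT26)
    cluster_node: dict[int, int] = {}
    for lab in range(1, njc + 1):
        vox = np.argwhere(jlabels == lab)
        pos = origin + (vox.astype(float) + 0.5).mean(axis=0) * pitch
        nrec = NodeRecord(next_node, pos, boundary_flag=bool(
            np.any([on_boundary(tuple(v)) for v in vox])
        ))
        g.nodes[next_node] = nrec
        cluster_node[lab] = next_node
        next_node += 1

    end_nodes: dict[tuple[int, int, int], int] = {}

    def node_for_end(vox) -> int:
        nonlocal next_node
        v = tuple(int(c) for c in vox)
        if v not in end_nodes:
            g.nodes[next_node] = NodeRecord(
                next_node, phys(v), boundary_flag=on_boundary(v)
            )
            end_nodes[v] = next_node
            next_node += 1
        return end_nodes[v]

    def adjacent_clusters(vox) -> list[int]:
        z, y, x = vox
        labs = []
        for dz, dy, dx in _OFFSETS:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx_ and junction[zz, yy, xx]:
                lab = int(jlabels[zz, yy, xx])
                if lab not in labs:
                    labs.append(lab)
        return labs

    def add_branch(na, nb, chain_pts, touches_boundary, closed=False):
        nonlocal next_branch
        pa, pb = g.nodes[na].position, g.nodes[nb].position
        poly = smooth_branch_curve(chain_pts, pa, pb) if len(chain_pts) else (
            np.vstack([pa, pb])
        )
        br = BranchRecord(next_branch, na, nb, poly, excluded=touches_boundary)
        br.finalize()
        g.branches[next_branch] = br
        next_branch += 1

    # chain components -> branches
    clabels, ncc = ndimage.label(chainmask, structure=_STRUCT26)
    comp_voxels: dict[int, list] = {}
    for v in np.argwhere(clabels > 0):
        comp_voxels.setdefault(int(clabels[tuple(v)]), []).append(tuple(int(c) for c in v))

    for lab, voxels in sorted(comp_voxels.items()):
        order, is_cycle = _order_chain(voxels)
        touches = any(on_boundary(v) for v in order)
        pts = np.array([phys(v) for v in order])
        if is_cycle:
            # isolated closed filament: one carrier node, self-loop branch
            na = node_for_end(order[0])
            chain_pts = pts[1:]
            add_branch(na, na, chain_pts, touches, closed=True)
            continue
        first, last = order[0], order[-1]
        if len(order) == 1:
            labs = adjacent_clusters(first)
            if len(labs) >= 2:
                add_branch(cluster_node[labs[0]], cluster_node[labs[1]],
                           pts, touches)
            elif len(labs) == 1 and counts[first] == 2:
                # both neighbours in the same cluster: self-loop through voxel
                add_branch(cluster_node[labs[0]], cluster_node[labs[0]],
                           pts, touches)
            elif len(labs) == 1:
                add_branch(cluster_node[labs[0]], node_for_end(first),
                           np.empty((0, 3)), touches)
            # len(labs) == 0: isolated voxel, dropped
            continue
        labs_a = adjacent_clusters(first)
        labs_b = adjacent_clusters(last)
        na = cluster_node[labs_a[0]] if labs_a else node_for_end(first)
        nb = cluster_node[labs_b[0]] if labs_b else node_for_end(last)
        interior = pts
        if not labs_a:
            interior = interior[1:]  # first voxel is the end node itself
        if not labs_b:
            interior = interior[:-1]
        add_branch(na, nb, interior, touches)

    g.recompute_ranks()

    if mask is not None:
        assign_domains(g, mask)
    return g


def assign_domains(g: SkeletonGraph, mask: LabelMask) -> None:
    """Assign head/neck domains from the label mask at each branch centre
    of mass (and node position)."""
    if mask.domains is None:
        return
    shape = mask.shape

    def domain_at(pos: np.ndarray) -> int:
        idx = np.floor((pos - mask.origin) / mask.voxel_pitch).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        return int(mask.domains[tuple(idx)])

    for b in g.branches.values():
        b.domain = domain_at(b.com)
    for n in g.nodes.values():
        n.domain = domain_at(n.position)
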