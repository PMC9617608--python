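"""Node-rank statistics, densities, branch-end clustering and rank-3
branching-angle geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .graph import SkeletonGraph
from .spatial import DistanceField
from .volume import DOMAIN_NAMES, NM3_PER_UM3, LabelMask


def node_rank_distribution(g: SkeletonGraph) -> pd.DataFrame:
    """Counts and fractions of node ranks 3, 4, 5 and >=6, per domain and
    overall; rank-1 branch ends are reported separately."""
    if not g.nodes:
        raise ValueError("empty graph")
    rows = []
    domains = sorted({n.domain for n in g.nodes.values()})
    for dom in ["all", *domains]:
        nodes = [
            n
            for n in g.nodes.values()
            if dom == "all" or n.domain == dom
        ]
        junc = [n for n in nodes if n.rank >= 3]
        total = len(junc)
        counts = {
            "rank3": sum(1 for n in junc if n.rank == 3),
            "rank4": sum(1 for n in junc if n.rank == 4),
            "rank5": sum(1 for n in junc if n.rank == 5),
            "rank6plus": sum(1 for n in junc if n.rank >= 6),
        }
        row = dict(
            domain=DOMAIN_NAMES.get(dom, dom) if dom != "all" else "all",
            n_junctions=total,
            n_ends=sum(1 for n in nodes if n.rank == 1),
        )
        for key, c in counts.items():
            row[f"{key}_count"] = c
            row[f"{key}_fraction"] = c / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def node_density(g: SkeletonGraph, mask: LabelMask) -> dict[str, float]:
    """Density of junction nodes (rank >= 3) per μm³ of accessible
    cytosol, keyed by domain name plus ``"all"``."""
    out: dict[str, float] = {}
    vol_all = mask.cytosol_volume_um3()
    junc = g.junction_nodes()
    out["all"] = len(junc) / vol_all if vol_all > 0 else 0.0
    for tag in mask.domain_tags_present():
        dom = mask.domain_of(tag)
        vol = np.count_nonzero(dom) * mask.voxel_pitch**3 / NM3_PER_UM3
        n = sum(1 for nd in junc if nd.domain == tag)
        out[DOMAIN_NAMES[tag]] = n / vol if vol > 0 else 0.0
    return out


def branch_end_clustering_test(
    g: SkeletonGraph,
    dfield: DistanceField,
    shell: float = 10.0,
    seed: int = 0,
    n_rand: int = 100,
):
    """Nearest-neighbour clustering test for branch ends near the membrane.

    Observed: nearest-neighbour distances among rank-1 nodes lying within
    ``shell`` nm of the boundary.  Reference: the same number of points
    placed uniformly at random in the shell voxel set, ``n_rand`` times.
    Returns (observed mean, random mean, two-sided Mann-Whitney p) or
    ``None`` if fewer than two ends lie in the shell.
    """
    ends = np.array(
        [n.position for n in g.rank1_nodes()], dtype=float
    ).reshape(-1, 3)
    if len(ends) == 0:
        return None
    d = dfield.dt_at(ends)
    sel = d < shell
    pts = ends[sel]
    if len(pts) < 2:
        return None
    obs = _nn_distances(pts)

    shell_mask = (dfield.dt < shell) & (
        dfield.cytosol if dfield.cytosol is not None else np.isfinite(dfield.dt)
    )
    shell_idx = np.argwhere(shell_mask)
    if len(shell_idx) == 0:
        return None
    rng = np.random.default_rng(seed)
    pooled = []
    distinct = len(shell_idx) >= len(pts)
    for _ in range(n_rand):
        if distinct:
            pick = rng.choice(len(shell_idx), size=len(pts), replace=False)
        else:
            pick = rng.integers(0, len(shell_idx), size=len(pts))
        jitter = rng.uniform(0.0, 1.0, size=(len(pts), 3))
        rpts = dfield.origin + (shell_idx[pick] + jitter) * dfield.voxel_pitch
        pooled.append(_nn_distances(rpts))
    pooled = np.concatenate(pooled)
    stat = stats.mannwhitneyu(obs, pooled, alternative="two-sided")
    return float(obs.mean()), float(pooled.mean()), float(stat.pvalue)


def _nn_distances(points: np.ndarray) -> np.ndarray:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return d[:, 1]


@dataclass
class AngleTriple:
    """Sorted pairwise branching angles at a rank-3 node."""

    node_id: int
    angles: tuple[float, float, float]  # sorted ascending, degrees
    angle_sum: float
    tangents: np.ndarray  # (3, 3) unit vectors, pre-standardization order
    frame: np.ndarray | None = None  # standardized unit vectors


def _branch_tangent(branch, node_id: int) -> np.ndarray | None:
    """Tangent at a node: first principal direction of the first three
    polyline points starting at the node, oriented into the branch."""
    p = np.asarray(branch.polyline, dtype=float)
    if branch.node_a == node_id:
        pts = p[:3]
    else:
        pts = p[::-1][:3]
    if len(pts) < 2:
        return None
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    v = vt[0]
    direction = pts[-1] - pts[0]
    if np.dot(v, direction) < 0:
        v = -v
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else None


def branching_angles_rank3(g: SkeletonGraph) -> list[AngleTriple]:
    """Sorted pairwise angle triples at every rank-3 node."""
    triples = []
    incident: dict[int, list] = {}
    for b in g.branches.values():
        incident.setdefault(b.node_a, []).append(b)
        if b.node_b != b.node_a:
            incident.setdefault(b.node_b, []).append(b)
    for n in g.nodes.values():
        if n.rank != 3:
            continue
        branches = incident.get(n.id, [])
        tangents = []
        for b in sorted(branches, key=lambda b: b.id):
            t = _branch_tangent(b, n.id)
            if t is not None:
                tangents.append(t)
            if b.node_a == b.node_b:  # self-loop contributes both ends
                t2 = _branch_tangent_reverse(b)
                if t2 is not None:
                    tangents.append(t2)
        if len(tangents) != 3:
            continue
        t = np.array(tangents)
        angs = sorted(
            _pair_angle(t[i], t[j]) for i, j in ((0, 1), (0, 2), (1, 2))
        )
        triples.append(
            AngleTriple(
                node_id=n.id,
                angles=tuple(angs),
                angle_sum=float(sum(angs)),
                tangents=t,
            )
        )
    return triples


def _branch_tangent_reverse(branch) -> np.ndarray | None:
    p = np.asarray(branch.polyline, dtype=float)[::-1][:3]
    if len(p) < 2:
        return None
    centred = p - p.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v = vt[0]
    if np.dot(v, p[-1] - p[0]) < 0:
        v = -v
    return v / np.linalg.norm(v)


def _pair_angle(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def standardize_rank3_frame(t: AngleTriple) -> np.ndarray:
    """Rotate (and if needed reflect) a tangent triple into the canonical
    frame: the vector with the largest summed angle to the other two maps
    to (-1, 0, 0); the vector making the intermediate angle with it spans
    the azimuthal z=0 plane with positive y; the third vector has
    non-negative elevation.  Pairwise angles are preserved exactly.
    """
    v = np.asarray(t.tangents, dtype=float)
    if v.shape != (3, 3):
        raise ValueError("need exactly three tangents")
    ang = np.array(
        [
            [_pair_angle(v[i], v[j]) if i != j else 0.0 for j in range(3)]
            for i in range(3)
        ]
    )
    sums = ang.sum(axis=1)
    first = int(np.argmax(sums))
    others = [i for i in range(3) if i != first]
    # azimuthal plane partner: the vector forming the globally
    # intermediate pairwise angle with `first`; if the intermediate angle
    # is between the two other vectors the larger-angle partner is used
    pairs = sorted(
        ((0, 1), (0, 2), (1, 2)), key=lambda ij: (ang[ij[0], ij[1]], ij)
    )
    inter = pairs[1]
    if first in inter:
        second = inter[0] if inter[1] == first else inter[1]
    else:
        second = max(others, key=lambda i: (ang[first, i], -i))
    third = [i for i in others if i != second][0]

    e1 = -v[first]  # will map to +x after negation, i.e. v[first] -> (-1,0,0)
    perp = v[second] - np.dot(v[second], e1) * e1
    n = np.linalg.norm(perp)
    if n < 1e-10:
        raise ValueError("degenerate (collinear) tangents")
    e2 = perp / n
    e3 = np.cross(e1, e2)
    rot = np.vstack([e1, e2, e3])  # maps e1->x, e2->y, e3->z
    out = v @ rot.T
    if out[third, 2] < 0:
        out[:, 2] = -out[:, 2]
    # order rows as (first, second, third) in the standardized frame
    return out[[first, second, third]]
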