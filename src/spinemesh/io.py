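"""Volume, mask and graph input/output.

Volumes and masks are exchanged as MRC2014 (via SimpleITK's MRC reader,
which carries the voxel pitch in the header) or as multi-page TIFF stacks
(via tifffile; the pitch must then come from the analysis configuration).
Graphs are persisted as GraphML plus a pair of CSV tables (nodes.csv /
branches.csv) that round-trip every attribute including the branch
polylines.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .graph import BranchRecord, NodeRecord, SkeletonGraph
from .volume import DOMAIN_NAMES, LabelMask, VolumeGrid

_DOMAIN_BY_NAME = {v: k for k, v in DOMAIN_NAMES.items()}


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".rec", ".map"):
        return "mrc"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer volume format from {path.name}")


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_pitch: float | None = None,
    polarity: str = "absorption",
) -> VolumeGrid:
    """Read a 3D volume from MRC or a TIFF stack.

    The voxel pitch is taken from the MRC header when present, otherwise
    from ``voxel_pitch`` (default 2.0 nm).  ``polarity="luminance"``
    negates intensities on load so that downstream binarization always
    operates on absorption polarity (filaments bright).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    if fmt == "mrc":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).astype(np.float32)
        spacing = img.GetSpacing()
        if max(spacing) - min(spacing) > 1e-6:
            warnings.warn(
                f"anisotropic voxel pitch {spacing} in {path.name}; "
                "using the mean"
            )
        pitch = float(np.mean(spacing)) if spacing[0] > 0 else None
    elif fmt == "tiff":
        data = tifffile.imread(str(path)).astype(np.float32)
        if data.ndim == 2:
            data = data[None]
        pitch = None
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if voxel_pitch is not None:
        pitch = voxel_pitch
    if pitch is None or pitch <= 0:
        pitch = 2.0
    if polarity == "luminance":
        data = -data
    elif polarity != "absorption":
        raise ValueError("polarity must be 'absorption' or 'luminance'")
    return VolumeGrid(data, voxel_pitch=pitch)


def write_volume(volume: VolumeGrid, path: str | Path, format: str | None = None) -> None:
    """Write a volume as MRC (with pitch in the header) or TIFF stack."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "mrc":
        img = sitk.GetImageFromArray(np.asarray(volume.data, dtype=np.float32))
        img.SetSpacing((volume.voxel_pitch,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        tifffile.imwrite(str(path), np.asarray(volume.data, dtype=np.float32))


def read_mask(
    path: str | Path, format: str | None = None, voxel_pitch: float | None = None
) -> LabelMask:
    """Read an integer label mask; a companion ``<stem>.domains<suffix>``
    file, when present, provides the head/neck domain tags."""
    path = Path(path)
    vg = read_volume(path, format=format, voxel_pitch=voxel_pitch)
    labels = np.rint(vg.data).astype(np.uint8)
    domains = None
    dom_path = path.with_name(path.stem + ".domains" + path.suffix)
    if dom_path.exists():
        domains = np.rint(read_volume(dom_path, format=format).data).astype(np.uint8)
    return LabelMask(labels, voxel_pitch=vg.voxel_pitch, domains=domains)


def write_mask(mask: LabelMask, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "mrc":
        img = sitk.GetImageFromArray(mask.labels.astype(np.uint8))
        img.SetSpacing((mask.voxel_pitch,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        tifffile.imwrite(str(path), mask.labels.astype(np.uint8))
    if mask.domains is not None:
        dom_path = path.with_name(path.stem + ".domains" + path.suffix)
        if fmt == "mrc":
            img = sitk.GetImageFromArray(mask.domains.astype(np.uint8))
            img.SetSpacing((mask.voxel_pitch,) * 3)
            sitk.WriteImage(img, str(dom_path))
        else:
            tifffile.imwrite(str(dom_path), mask.domains.astype(np.uint8))


# ---------------------------------------------------------------------------
# graph IO
# ---------------------------------------------------------------------------


def _polyline_to_str(p: np.ndarray) -> str:
    # repr gives the shortest exactly round-trippable decimal form
    return ";".join(",".join(repr(float(c)) for c in pt) for pt in p)


def _polyline_from_str(s: str) -> np.ndarray:
    return np.array([[float(c) for c in pt.split(",")] for pt in s.split(";")])


def export_graph(g: SkeletonGraph, path: str | Path, format: str = "csv-tables") -> None:
    """Persist a graph as GraphML or as nodes.csv / branches.csv tables.

    For ``csv-tables`` the path is a directory; re-import reproduces the
    graph up to ordering.
    """
    path = Path(path)
    if format == "graphml":
        import networkx as nx

        mg = nx.MultiGraph(voxel_pitch=g.voxel_pitch)
        for nid, n in g.nodes.items():
            mg.add_node(
                nid, x=float(n.position[2]), y=float(n.position[1]),
                z=float(n.position[0]), rank=n.rank,
                domain=DOMAIN_NAMES.get(n.domain, str(n.domain)),
                boundary=bool(n.boundary_flag),
            )
        for bid, b in g.branches.items():
            mg.add_edge(
                b.node_a, b.node_b, key=bid,
                length_nm=b.arc_length,
                tortuosity=float("nan") if b.tortuosity is None else b.tortuosity,
                excluded=bool(b.excluded),
                polyline=_polyline_to_str(b.polyline),
            )
        nx.write_graphml(mg, str(path))
        return
    if format != "csv-tables":
        raise ValueError("format must be 'graphml' or 'csv-tables'")
    path.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [
            dict(
                id=nid,
                x=n.position[2], y=n.position[1], z=n.position[0],
                rank=n.rank,
                domain=DOMAIN_NAMES.get(n.domain, str(n.domain)),
                boundary=bool(n.boundary_flag),
            )
            for nid, n in sorted(g.nodes.items())
        ],
        columns=["id", "x", "y", "z", "rank", "domain", "boundary"],
    )
    branches = pd.DataFrame(
        [
            dict(
                id=bid,
                node_a=b.node_a, node_b=b.node_b,
                length_nm=b.arc_length,
                tortuosity=float("nan") if b.tortuosity is None else b.tortuosity,
                excluded=bool(b.excluded),
                polyline=_polyline_to_str(b.polyline),
            )
            for bid, b in sorted(g.branches.items())
        ],
        columns=["id", "node_a", "node_b", "length_nm", "tortuosity",
                 "excluded", "polyline"],
    )
    nodes.to_csv(path / "nodes.csv", index=False)
    branches.to_csv(path / "branches.csv", index=False)


def import_graph(path: str | Path, format: str = "csv-tables") -> SkeletonGraph:
    """Inverse of :func:`export_graph`."""
    path = Path(path)
    g = SkeletonGraph()
    if format == "graphml":
        import networkx as nx

        mg = nx.read_graphml(str(path), force_multigraph=True)
        g.voxel_pitch = float(mg.graph.get("voxel_pitch", 2.0))
        for nid, d in mg.nodes(data=True):
            nid = int(nid)
            g.nodes[nid] = NodeRecord(
                nid,
                np.array([d["z"], d["y"], d["x"]], dtype=float),
                rank=int(d.get("rank", 0)),
                domain=_DOMAIN_BY_NAME.get(d.get("domain", "none"), 0),
                boundary_flag=bool(d.get("boundary", False)),
            )
        for a, b_, key, d in mg.edges(keys=True, data=True):
            bid = int(key)
            br = BranchRecord(
                bid, int(a), int(b_),
                polyline=_polyline_from_str(d["polyline"]),
                excluded=bool(d.get("excluded", False)),
            )
            br.finalize()
            g.branches[bid] = br
        g.recompute_ranks()
        return g
    nodes = pd.read_csv(path / "nodes.csv")
    branches = pd.read_csv(path / "branches.csv")
    for row in nodes.itertuples():
        g.nodes[int(row.id)] = NodeRecord(
            int(row.id),
            np.array([row.z, row.y, row.x], dtype=float),
            rank=int(row.rank),
            domain=_DOMAIN_BY_NAME.get(row.domain, 0),
            boundary_flag=bool(row.boundary),
        )
    for row in branches.itertuples():
        br = BranchRecord(
            int(row.id), int(row.node_a), int(row.node_b),
            polyline=_polyline_from_str(row.polyline),
            excluded=bool(row.excluded),
        )
        br.finalize()
        g.branches[int(row.id)] = br
    g.recompute_ranks()
    return g
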