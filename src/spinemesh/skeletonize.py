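"""Topology-preserving skeletonization of the binarized filament volume.

The binarized foreground is reduced to a one-voxel-wide skeleton by visiting
voxels in ascending Euclidean-distance-transform order and deleting a voxel
only if the deletion

* preserves local topology (the voxel is a *simple point* under
  26-connectivity for foreground / 6-connectivity for background),
* does not erase a branch end (voxels with at most one foreground
  neighbour are kept), and
* does not detach a connected component from the analysis-volume boundary
  (filaments exiting the imaged volume keep at least one anchor voxel on
  the bounding-box faces).

Ties in the distance transform are broken by lexicographic (z, y, x) scan
order so the result is deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeGrid
from .segmentation import BinarizedVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# The 26 neighbour offsets in fixed order; bit i of a neighbourhood
# configuration refers to _OFFSETS[i].
_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
_OFFSET_INDEX = {off: i for i, off in enumerate(_OFFSETS)}

# 26-adjacency between neighbour cells (for foreground components).
_ADJ26 = [
    [
        j
        for j, q in enumerate(_OFFSETS)
        if j != i and max(abs(q[0] - p[0]), abs(q[1] - p[1]), abs(q[2] - p[2])) <= 1
    ]
    for i, p in enumerate(_OFFSETS)
]

# N18: neighbour cells sharing a face or edge with the centre.
_N18 = [i for i, p in enumerate(_OFFSETS) if sum(c != 0 for c in p) <= 2]
_IS_N18 = [sum(c != 0 for c in p) <= 2 for p in _OFFSETS]
# 6-adjacency between N18 cells (for background components).
_ADJ6 = [
    [
        j
        for j, q in enumerate(_OFFSETS)
        if j != i
        and _IS_N18[j]
        and sum(abs(q[a] - p[a]) for a in range(3)) == 1
    ]
    if _IS_N18[i]
    else []
    for i, p in enumerate(_OFFSETS)
]
# The six face neighbours (seeds of the background component containing P).
_FACES = [i for i, p in enumerate(_OFFSETS) if sum(c != 0 for c in p) == 1]


def _is_simple_config(config: int) -> bool:
    """Simple-point test on a 26-bit neighbourhood configuration.

    A voxel is simple iff its foreground neighbours form exactly one
    26-connected component and the background cells of N18 form exactly one
    6-connected component touching a face neighbour.
    """
    fg = [(config >> i) & 1 for i in range(26)]
    # foreground: exactly one 26-component, and at least one fg neighbour
    seen = [False] * 26
    ncomp = 0
    for i in range(26):
        if fg[i] and not seen[i]:
            ncomp += 1
            if ncomp > 1:
                return False
            stack = [i]
            seen[i] = True
            while stack:
                v = stack.pop()
                for w in _ADJ26[v]:
                    if fg[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
    if ncomp != 1:
        return False
    # background: exactly one 6-component of N18 background cells adjacent
    # to the centre (i.e. containing a face neighbour)
    seen_bg = [False] * 26
    ncomp_bg = 0
    for s in _FACES:
        if not fg[s] and not seen_bg[s]:
            ncomp_bg += 1
            if ncomp_bg > 1:
                return False
            stack = [s]
            seen_bg[s] = True
            while stack:
                v = stack.pop()
                for w in _ADJ6[v]:
                    if not fg[w] and not seen_bg[w]:
                        seen_bg[w] = True
                        stack.append(w)
    return ncomp_bg == 1


_SIMPLE_CACHE: dict[int, bool] = {}


@dataclass
class SkeletonVoxels:
    """One-voxel-wide skeleton as a boolean volume plus bookkeeping."""

    mask: np.ndarray  # boolean, same shape as the binarized source
    voxel_pitch: float = 2.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    anchored: set = field(default_factory=set)  # voxels on bounding-box faces

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.mask.shape

    def coords(self) -> np.ndarray:
        return np.argwhere(self.mask)

    def count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def neighbor_counts(self) -> np.ndarray:
        """Number of foreground 26-neighbours for every voxel."""
        conv = ndimage.convolve(
            self.mask.astype(np.uint8), _STRUCT26.astype(np.uint8), mode="constant"
        )
        return (conv - self.mask.astype(np.uint8)).astype(np.int32)


def distance_transform_binary(b: BinarizedVolume) -> VolumeGrid:
    """Euclidean distance (nm) from each foreground voxel to the nearest
    background voxel centre; background voxels carry 0."""
    if not b.foreground.any():
        raise ValueError("empty foreground: nothing to transform")
    dt = ndimage.distance_transform_edt(b.foreground) * b.voxel_pitch
    return VolumeGrid(dt, voxel_pitch=b.voxel_pitch, origin=b.origin)


def _boundary_anchor_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        m[tuple(sl)] = True
        sl[ax] = shape[ax] - 1
        m[tuple(sl)] = True
    return m


def topological_thinning(b: BinarizedVolume, dt: VolumeGrid) -> SkeletonVoxels:
    """Thin the foreground to its topological skeleton.

    Voxels are deleted in ascending ``dt`` order subject to the
    simple-point, branch-end and boundary-anchor rules described in the
    module docstring.  Deletion of a simple point never splits or merges
    components, so component membership is fixed once at the start and the
    anchor rule reduces to "never delete the last bounding-box anchor of a
    component".
    """
    fg = np.asarray(b.foreground, dtype=bool).copy()
    if fg.shape != dt.data.shape:
        raise ValueError("distance transform shape mismatch")
    nz, ny, nx = fg.shape

    labels, _ = ndimage.label(fg, structure=_STRUCT26)
    anchor_mask = _boundary_anchor_mask(fg.shape) & fg
    anchor_counts = np.bincount(
        labels[anchor_mask].ravel(), minlength=labels.max() + 1
    )

    dtv = dt.data
    heap: list[tuple[float, int, int, int]] = [
        (float(dtv[z, y, x]), z, y, x) for z, y, x in np.argwhere(fg)
    ]
    heapq.heapify(heap)

    offsets = _OFFSETS
    cache = _SIMPLE_CACHE
    anchored_final: set = set()

    def neighborhood_config(z: int, y: int, x: int) -> tuple[int, int]:
        config = 0
        nnb = 0
        for i, (dz, dy, dx) in enumerate(offsets):
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and fg[zz, yy, xx]:
                config |= 1 << i
                nnb += 1
        return config, nnb

    while heap:
        d, z, y, x = heapq.heappop(heap)
        if not fg[z, y, x]:
            continue
        config, nnb = neighborhood_config(z, y, x)
        if nnb <= 1:  # branch end (or isolated voxel): keep
            continue
        simple = cache.get(config)
        if simple is None:
            simple = _is_simple_config(config)
            cache[config] = simple
        if not simple:
            continue
        lab = labels[z, y, x]
        is_anchor = z in (0, nz - 1) or y in (0, ny - 1) or x in (0, nx - 1)
        if is_anchor:
            if anchor_counts[lab] <= 1:
                continue  # sole boundary attachment of its component
            anchor_counts[lab] -= 1
        fg[z, y, x] = False
        # neighbours may have become removable; re-examine them
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and fg[zz, yy, xx]:
                heapq.heappush(heap, (float(dtv[zz, yy, xx]), zz, yy, xx))

    skel = SkeletonVoxels(fg, voxel_pitch=b.voxel_pitch, origin=b.origin)
    for z, y, x in np.argwhere(fg & _boundary_anchor_mask(fg.shape)):
        anchored_final.add((int(z), int(y), int(x)))
    skel.anchored = anchored_final
    return skel


def skeletonize_binary(b: BinarizedVolume, stub_min: float = 4.0) -> SkeletonVoxels:
    """Convenience wrapper: distance transform, thinning, stub pruning."""
    dt = distance_transform_binary(b)
    skel = topological_thinning(b, dt)
    return prune_stubs(skel, stub_min)


def prune_stubs(s: SkeletonVoxels, min_length: float) -> SkeletonVoxels:
    """Remove terminal chains shorter than ``min_length`` (nm) hanging off
    junctions.

    The stub length is measured along the chain's own voxels (end-voxel
    centre to the last chain voxel before the junction); the junction voxel
    itself is retained.  Whole connected components whose spatial extent is
    below ``min_length`` (noise speckle) are removed as well; larger
    isolated chains are never touched.  Applied once.
    """
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    if min_length == 0:
        return s
    mask = s.mask.copy()
    counts = s.neighbor_counts()
    pitch = s.voxel_pitch
    nz, ny, nx = mask.shape

    def neighbors(z, y, x):
        out = []
        for dz, dy, dx in _OFFSETS:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
                out.append((zz, yy, xx))
        return out

    def n_components(voxels: list) -> int:
        vset = set(voxels)
        seen: set = set()
        ncomp = 0
        for v in voxels:
            if v in seen:
                continue
            ncomp += 1
            stack = [v]
            seen.add(v)
            while stack:
                p = stack.pop()
                for q in vset:
                    if q not in seen and max(
                        abs(q[0] - p[0]), abs(q[1] - p[1]), abs(q[2] - p[2])
                    ) <= 1:
                        seen.add(q)
                        stack.append(q)
        return ncomp

    ends = [tuple(int(c) for c in v) for v in np.argwhere(mask & (counts == 1))]
    to_remove: list[list[tuple[int, int, int]]] = []
    for end in ends:
        # walk from the branch end toward the rest of the skeleton; the
        # stub terminates where it attaches to structure that stays
        # connected without it (single neighbour component), or at a
        # genuine junction voxel (which is retained)
        chain = [end]
        chainset = {end}
        attached = False
        while True:
            cur = chain[-1]
            rest = [n for n in neighbors(*cur) if n not in chainset]
            if not rest:
                break  # isolated chain: never a stub
            if len(rest) == 1:
                chain.append(rest[0])
                chainset.add(rest[0])
                continue
            attached = True
            if n_components(rest) > 1:
                chain.pop()  # cur is a real junction voxel: keep it
            break
        if not attached or not chain:
            continue
        arc = sum(
            float(np.linalg.norm(np.subtract(a, c))) * pitch
            for a, c in zip(chain[:-1], chain[1:])
        )
        if arc < min_length:
            to_remove.append(chain)
    for chain in to_remove:
        for v in chain:
            mask[v] = False
    # remove sub-threshold isolated structures (noise speckle)
    labels, ncomp = ndimage.label(mask, structure=_STRUCT26)
    if ncomp:
        objs = ndimage.find_objects(labels)
        for lab, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            extent = max(s_.stop - s_.start for s_ in sl) * pitch
            if extent < min_length:
                mask[labels == lab] = False
    out = SkeletonVoxels(mask, voxel_pitch=pitch, origin=s.origin)
    out.anchored = {v for v in s.anchored if mask[v]}
    return out


# ---------------------------------------------------------------------------
# Topology oracles (used to verify topology preservation)
# ---------------------------------------------------------------------------


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of the union of closed voxel cubes.

    Counts vertices, edges, faces and cubes of the cubical complex covered
    by the foreground.  This convention corresponds to 26-connectivity for
    the foreground and 6-connectivity for the background, matching the
    thinning rules.
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1)

    def cover(axes: tuple[int, ...]) -> int:
        # a cell of the complex spanned along `axes` is present if any of
        # its incident voxels is foreground
        acc = padded
        for ax in axes:
            acc = acc[tuple(slice(None) if a != ax else slice(0, -1) for a in range(3))] | acc[
                tuple(slice(None) if a != ax else slice(1, None) for a in range(3))
            ]
        return int(np.count_nonzero(acc))

    n_cubes = cover(())
    n_faces = sum(cover((ax,)) for ax in range(3))
    n_edges = sum(cover((a, b)) for a, b in ((0, 1), (0, 2), (1, 2)))
    n_verts = cover((0, 1, 2))
    return n_verts - n_edges + n_faces - n_cubes


def betti_numbers(mask: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2) of a voxel set under the (26, 6) connectivity pair.

    b0 from 26-connected labelling, b2 from enclosed background cavities
    (6-connected background components not touching the border), and b1
    from the Euler characteristic chi = b0 - b1 + b2.
    """
    m = np.asarray(mask, dtype=bool)
    _, b0 = ndimage.label(m, structure=_STRUCT26)
    bg_labels, nbg = ndimage.label(~m)  # 6-connectivity default
    border = np.zeros_like(m)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    touching = set(np.unique(bg_labels[border & ~m]))
    b2 = nbg - len(touching - {0})
    chi = euler_characteristic(m)
    b1 = b0 + b2 - chi
    return b0, b1, b2
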