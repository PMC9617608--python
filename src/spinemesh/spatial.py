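"""Distance-to-membrane fields and membrane-relative statistics.

The reference frame for all spatial analyses is the Euclidean distance
transform of the cytosol with respect to the spine boundary; membrane,
PSD, ER and other organelle interfaces all count as boundary.  Its
gradient points from the membrane toward the interior and is the
reference direction for branch orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .graph import SkeletonGraph
from .volume import (
    DOMAIN_HEAD,
    DOMAIN_NECK,
    DOMAIN_NONE,
    DOMAIN_NAMES,
    NM3_PER_UM3,
    LabelMask,
)


@dataclass
class DistanceField:
    """Distance-to-boundary field over the cytosol plus its gradient.

    ``dt`` is the distance (nm) of each cytosol voxel centre to the
    boundary; voxels face-adjacent to the boundary carry 0 (one voxel
    pitch is subtracted from the centre-to-centre transform so the field
    vanishes at the membrane).  ``grad`` holds the normalized gradient
    (z, y, x components), zero where undefined.  ``dt_norm`` rescales dt
    to [0, 1] by the per-domain maximum.
    """

    dt: np.ndarray
    grad: np.ndarray  # (3, nz, ny, nx) unit vectors
    dt_norm: np.ndarray
    voxel_pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cytosol: np.ndarray | None = None

    def dt_at(self, positions: np.ndarray) -> np.ndarray:
        """Distance values at physical positions (nearest voxel)."""
        idx = self._indices(positions)
        return self.dt[tuple(idx.T)]

    def dt_norm_at(self, positions: np.ndarray) -> np.ndarray:
        idx = self._indices(positions)
        return self.dt_norm[tuple(idx.T)]

    def grad_at(self, positions: np.ndarray) -> np.ndarray:
        """Unit gradient vectors at physical positions (trilinear)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        coords = (pos - self.origin) / self.voxel_pitch - 0.5
        coords = coords.T
        g = np.stack(
            [
                ndimage.map_coordinates(self.grad[c], coords, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
        norms = np.linalg.norm(g, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(norms > 1e-8, g / norms, 0.0)
        return g

    def _indices(self, positions: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        idx = np.floor((pos - self.origin) / self.voxel_pitch).astype(int)
        return np.clip(idx, 0, np.asarray(self.dt.shape) - 1)


def boundary_distance_field(mask: LabelMask) -> DistanceField:
    """Distance transform of the cytosol with respect to the spine
    boundary (membrane, ER, PSD, mitochondria and extracellular space all
    count as boundary), with normalized central-difference gradient and a
    per-domain normalized copy."""
    cyt = mask.cytosol()
    if not cyt.any():
        raise ValueError("mask contains no cytosol voxels")
    edt = ndimage.distance_transform_edt(cyt)
    dt = np.maximum(edt - 1.0, 0.0) * mask.voxel_pitch

    grad = np.stack(np.gradient(dt, mask.voxel_pitch))
    norms = np.linalg.norm(grad, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grad = np.where(norms > 1e-8, grad / norms, 0.0)
    grad[:, ~cyt] = 0.0

    dt_norm = np.zeros_like(dt)
    for tag in mask.domain_tags_present():
        dom = mask.domain_of(tag)
        if dom.any():
            mx = dt[dom].max()
            if mx > 0:
                dt_norm[dom] = dt[dom] / mx
    return DistanceField(
        dt=dt,
        grad=grad,
        dt_norm=dt_norm,
        voxel_pitch=mask.voxel_pitch,
        origin=mask.origin,
        cytosol=cyt,
    )


def rasterize_graph(g: SkeletonGraph, shape, voxel_pitch: float, origin) -> np.ndarray:
    """Rasterize branch polylines into a boolean volume (densely sampled
    at half-voxel steps)."""
    vol = np.zeros(shape, dtype=bool)
    origin = np.asarray(origin, dtype=float)
    step = voxel_pitch / 2.0
    for b in g.branches.values():
        p = b.polyline
        seg = np.diff(p, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        for i, L in enumerate(lens):
            n = max(int(np.ceil(L / step)), 1)
            ts = np.linspace(0.0, 1.0, n + 1)
            pts = p[i] + ts[:, None] * seg[i]
            idx = np.floor((pts - origin) / voxel_pitch).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            vol[tuple(idx[ok].T)] = True
    return vol


def cytoskeleton_volume_fraction(
    g: SkeletonGraph, mask: LabelMask, sigma_vol: float = 4.0
) -> dict[str, float]:
    """Fraction of cytosol occupied by the reconstructed cytoskeleton.

    The skeleton is rasterized, convolved with a 3D Gaussian of SD
    ``sigma_vol`` (nm) and thresholded at exp(-1/2) of the peak response
    of an infinite straight line, which reconstructs tubes of radius
    ``sigma_vol`` (8 nm diameter filaments for the default 4 nm).
    Returns fractions keyed by domain name plus ``"all"``.
    """
    if not sigma_vol > 0:
        raise ValueError("sigma_vol must be positive")
    pitch = mask.voxel_pitch
    cyt = mask.cytosol()
    out: dict[str, float] = {}
    if not g.branches:
        out["all"] = 0.0
        for tag in mask.domain_tags_present():
            out[DOMAIN_NAMES[tag]] = 0.0
        return out
    raster = rasterize_graph(g, mask.shape, pitch, mask.origin)
    smoothed = ndimage.gaussian_filter(raster.astype(float), sigma_vol / pitch)
    # peak response of a unit line at voxel sampling: pitch^2 / (2 pi sigma^2)
    level = np.exp(-0.5) * pitch**2 / (2.0 * np.pi * sigma_vol**2)
    tubes = smoothed > level
    ncyt = np.count_nonzero(cyt)
    out["all"] = float(np.count_nonzero(tubes & cyt) / ncyt) if ncyt else 0.0
    for tag in mask.domain_tags_present():
        dom = mask.domain_of(tag)
        nd = np.count_nonzero(dom)
        out[DOMAIN_NAMES[tag]] = (
            float(np.count_nonzero(tubes & dom) / nd) if nd else 0.0
        )
    return out


def branch_orientation(branch, dfield: DistanceField) -> float:
    """Mean angle (degrees, folded to [0, 90]) between the branch and the
    distance-transform gradient, averaged over the interior polyline
    points.  Points where the gradient is undefined are skipped."""
    p = np.asarray(branch.polyline, dtype=float)
    if len(p) < 3:
        tangents = (p[-1] - p[0])[None, :]
        ref_pts = p[:1] * 0.5 + p[-1:] * 0.5
    else:
        tangents = p[2:] - p[:-2]
        ref_pts = p[1:-1]
    norms = np.linalg.norm(tangents, axis=1)
    ok = norms > 1e-9
    if not ok.any():
        return float("nan")
    tangents = tangents[ok] / norms[ok, None]
    grads = dfield.grad_at(ref_pts[ok])
    gnorm = np.linalg.norm(grads, axis=1)
    ok2 = gnorm > 1e-8
    if not ok2.any():
        return float("nan")
    cosang = np.abs(np.sum(tangents[ok2] * grads[ok2], axis=1)).clip(0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def profile_vs_distance(
    positions: np.ndarray,
    values: np.ndarray | None,
    dfield: DistanceField,
    bin_width: float = 3.0,
    normalized: bool = False,
    mask: LabelMask | None = None,
) -> pd.DataFrame:
    """Bin values (or point counts) by distance to the nearest membrane.

    Each item is placed by the dt (or dt_norm) value at its reference
    position.  With ``values`` given, per-bin mean, SD, SEM and count are
    returned.  With ``values=None`` the result is a density profile:
    counts divided by the cytosol volume (μm³) of each dt shell
    (requires ``mask``).  Empty bins are absent from the result.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise ValueError("need at least one position")
    d = dfield.dt_norm_at(positions) if normalized else dfield.dt_at(positions)
    bins = np.floor(d / bin_width).astype(int)
    rows = []
    if values is not None:
        values = np.asarray(values, dtype=float)
        for b in np.unique(bins):
            sel = bins == b
            v = values[sel]
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append(
                dict(
                    bin_low=b * bin_width,
                    bin_high=(b + 1) * bin_width,
                    mean=v.mean(),
                    sd=v.std(ddof=1) if v.size > 1 else 0.0,
                    sem=(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
                    count=int(v.size),
                )
            )
    else:
        if mask is None:
            raise ValueError("density profiles require the label mask")
        field_vals = dfield.dt_norm if normalized else dfield.dt
        cyt = mask.cytosol()
        shell_bins = np.floor(field_vals[cyt] / bin_width).astype(int)
        shell_counts = np.bincount(shell_bins)
        voxvol_um3 = mask.voxel_pitch**3 / NM3_PER_UM3
        for b in np.unique(bins):
            sel = bins == b
            shell_vox = shell_counts[b] if b < len(shell_counts) else 0
            if shell_vox == 0:
                continue
            vol = shell_vox * voxvol_um3
            rows.append(
                dict(
                    bin_low=b * bin_width,
                    bin_high=(b + 1) * bin_width,
                    count=int(sel.sum()),
                    shell_volume_um3=vol,
                    density_um3=float(sel.sum() / vol),
                )
            )
    return pd.DataFrame(rows)


def neck_width_estimate(
    mask: LabelMask, dfield: DistanceField | None = None
) -> float | None:
    """Automated minimum neck diameter (nm).

    The neck's principal axis is found by PCA of its voxel coordinates;
    voxels are then binned into one-pitch slabs along that axis, the
    maximal inscribed radius of each slab is the largest
    centre-to-boundary distance it contains, and the neck width is twice
    the smallest slab radius.  The slab maxima trace the medial axis, so
    this is a discrete minimum-over-medial-axis estimate.  Returns
    ``None`` when the mask has no neck domain (stubby spine).
    """
    neck = mask.domain_of(DOMAIN_NECK)
    if not neck.any():
        return None
    cyt = mask.cytosol()
    edt = ndimage.distance_transform_edt(cyt) * mask.voxel_pitch
    coords = np.argwhere(neck).astype(float)
    centred = coords - coords.mean(axis=0)
    if len(coords) < 4:
        return float(2.0 * edt[neck].max())
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    t = centred @ axis
    bins = np.floor(t).astype(int)
    radii = {}
    vals = edt[neck]
    for b, v in zip(bins, vals):
        radii[b] = max(radii.get(b, 0.0), v)
    if not radii:
        return None
    return float(2.0 * min(radii.values()))
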