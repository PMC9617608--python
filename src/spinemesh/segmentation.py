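"""Cytosol masking, denoising and local-threshold binarization.

Binarization operates on *absorption* polarity: strongly stained
(electron-dense, putative filament) voxels carry high values.  Raw
luminance volumes, where filaments are dark, must be negated on load
(``polarity="luminance"`` in the readers/CLI).

The local threshold adapts to the slow luminance drift along the z-axis of
a tomogram: within a cubic window around each voxel the local mean ``m``
and standard deviation ``s`` are computed over valid (cytosol) voxels only,
and the voxel is foreground iff its intensity strictly exceeds
``T = m - k*s`` (Niblack form; positive ``k`` lowers the threshold below
the local mean).  An alternative pure mean-offset form ``T = (1 - k)*m``
is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume import VolumeGrid, LabelMask

#: Sentinel for voxels excluded from analysis (outside cytosol).
MASKED_VALUE = 0.0

#: Minimum number of valid voxels a window must hold to classify its centre.
MIN_WINDOW_VALID = 8


@dataclass
class BinarizedVolume:
    """Boolean foreground volume with the parameters that produced it."""

    foreground: np.ndarray
    voxel_pitch: float = 2.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.foreground.shape

    def foreground_fraction(self, mask: LabelMask | None = None) -> float:
        if mask is None:
            return float(self.foreground.mean())
        cyt = mask.cytosol()
        n = np.count_nonzero(cyt)
        return float(np.count_nonzero(self.foreground & cyt) / n) if n else 0.0


def mask_intracellular(volume: VolumeGrid, mask: LabelMask) -> VolumeGrid:
    """Restrict a volume to the analyzable cytosol.

    Voxels outside the cytosol (extracellular space, membrane, ER, PSD,
    mitochondria) are set to the sentinel ``MASKED_VALUE`` and excluded
    from all later statistics; cytosol intensities are unchanged.
    """
    mask.check_companion(volume)
    cyt = mask.cytosol()
    if not cyt.any():
        raise ValueError("mask contains no cytosol voxels")
    data = np.where(cyt, volume.data, MASKED_VALUE)
    return VolumeGrid(data, voxel_pitch=volume.voxel_pitch, origin=volume.origin)


def gaussian_smooth(
    volume: VolumeGrid, sigma: float, mask: LabelMask | None = None
) -> VolumeGrid:
    """Isotropic Gaussian smoothing with SD ``sigma`` in nm.

    With a mask, masked voxels are excluded via renormalized (masked)
    convolution so that boundary voxels are not dragged toward the
    sentinel value.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if sigma < volume.voxel_pitch / 2:
        import warnings

        warnings.warn("smoothing kernel under-resolved (sigma < pitch/2)")
    sig_vox = sigma / volume.voxel_pitch
    if mask is None:
        out = ndimage.gaussian_filter(volume.data.astype(float), sig_vox, truncate=6.0)
    else:
        mask.check_companion(volume)
        valid = mask.cytosol().astype(float)
        num = ndimage.gaussian_filter(
            volume.data.astype(float) * valid, sig_vox, truncate=6.0
        )
        den = ndimage.gaussian_filter(valid, sig_vox, truncate=6.0)
        with np.errstate(invalid="ignore"):
            out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), MASKED_VALUE)
        out[valid == 0] = MASKED_VALUE
    return VolumeGrid(out, voxel_pitch=volume.voxel_pitch, origin=volume.origin)


def _window_span_voxels(window_size: float, pitch: float) -> int:
    """Odd voxel span nearest to ``window_size / pitch`` (ties round up)."""
    w = window_size / pitch
    span = int(round(w))
    if span % 2 == 0:
        span += 1
    return max(span, 3)


def local_threshold_binarize(
    volume: VolumeGrid,
    window_size: float = 20.0,
    k: float = 0.1,
    mask: LabelMask | None = None,
    threshold_form: str = "niblack",
) -> BinarizedVolume:
    """Local-threshold binarization on absorption polarity.

    For each cytosol voxel the mean ``m`` and SD ``s`` over the valid
    voxels of a cubic window are computed; the voxel is foreground iff its
    intensity strictly exceeds ``m - k*s`` (or ``(1-k)*m`` for the
    mean-offset form).  Windows with fewer than ``MIN_WINDOW_VALID`` valid
    voxels classify as background.
    """
    span = _window_span_voxels(window_size, volume.voxel_pitch)
    if span < 3:
        raise ValueError("window must span at least 3 voxels")
    if threshold_form not in ("niblack", "mean-offset"):
        raise ValueError("unknown threshold_form")
    data = volume.data.astype(np.float64)
    if mask is not None:
        mask.check_companion(volume)
        valid = mask.cytosol()
    else:
        valid = np.ones(volume.shape, dtype=bool)
    vf = valid.astype(np.float64)
    size = (span, span, span)
    # box sums over valid voxels only
    cnt = ndimage.uniform_filter(vf, size=size, mode="constant") * span**3
    s1 = ndimage.uniform_filter(data * vf, size=size, mode="constant") * span**3
    s2 = ndimage.uniform_filter(data**2 * vf, size=size, mode="constant") * span**3
    cnt_r = np.maximum(np.rint(cnt), 1.0)
    m = s1 / cnt_r
    var = np.maximum(s2 / cnt_r - m**2, 0.0)
    # kill floating-point residue so constant regions give s = 0 exactly
    var[var < 1e-10 * (m**2 + 1.0)] = 0.0
    s = np.sqrt(var)
    if threshold_form == "niblack":
        thr = m - k * s
    else:
        thr = (1.0 - k) * m
    # strict inequality with a relative guard so exact ties (constant
    # regions) classify as background despite box-filter rounding
    eps = 1e-9 * (np.abs(thr) + 1.0)
    fg = (data > thr + eps) & valid & (np.rint(cnt) >= MIN_WINDOW_VALID)
    return BinarizedVolume(
        fg,
        voxel_pitch=volume.voxel_pitch,
        origin=volume.origin,
        provenance={
            "window_size": window_size,
            "k": k,
            "span_voxels": span,
            "threshold_form": threshold_form,
        },
    )


def segmentation_correlation(
    volume: VolumeGrid, b: BinarizedVolume, mask: LabelMask | None = None
) -> float:
    """Pearson correlation between absorption intensity and the binary
    field over the cytosol (the k-selection criterion)."""
    if mask is not None:
        sel = mask.cytosol()
    else:
        sel = np.ones(volume.shape, dtype=bool)
    x = volume.data[sel].astype(float)
    y = b.foreground[sel].astype(float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def binarization_sweep(
    volume: VolumeGrid,
    mask: LabelMask,
    k_values,
    window_size: float = 20.0,
    stub_min: float = 4.0,
    sigma_vol: float = 4.0,
    threshold_form: str = "niblack",
):
    """Sweep the threshold parameter k and report, per k, the foreground
    fraction, the intensity/segmentation Pearson correlation and the
    downstream skeleton summary statistics (cumulative branch length, node
    density, reconstructed cytoskeleton volume fraction).

    Returns a pandas DataFrame with one row per k.
    """
    import pandas as pd

    from .skeletonize import skeletonize_binary
    from .graph import build_graph
    from .topology import node_density
    from .spatial import cytoskeleton_volume_fraction

    k_values = list(k_values)
    if len(k_values) < 2:
        raise ValueError("need at least two k values")
    rows = []
    for k in k_values:
        b = local_threshold_binarize(
            volume, window_size=window_size, k=k, mask=mask,
            threshold_form=threshold_form,
        )
        ff = b.foreground_fraction(mask)
        r = segmentation_correlation(volume, b, mask)
        if not b.foreground.any():
            rows.append(
                dict(k=k, foreground_fraction=0.0, pearson_r=r,
                     cumulative_branch_length_nm=0.0, node_density_um3=0.0,
                     actin_volume_fraction=0.0, empty_foreground=True)
            )
            continue
        skel = skeletonize_binary(b, stub_min=stub_min)
        g = build_graph(skel, mask)
        cum_len = sum(br.arc_length for br in g.branches.values())
        dens = node_density(g, mask)["all"]
        vol_frac = cytoskeleton_volume_fraction(g, mask, sigma_vol=sigma_vol)["all"]
        rows.append(
            dict(k=k, foreground_fraction=ff, pearson_r=r,
                 cumulative_branch_length_nm=cum_len, node_density_um3=dens,
                 actin_volume_fraction=vol_frac, empty_foreground=False)
        )
    return pd.DataFrame(rows)
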