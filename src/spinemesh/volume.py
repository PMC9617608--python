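"""Core in-memory containers for tomographic volumes and compartment masks.

All physical quantities are expressed in nanometres.  Volumes live on an
isotropic voxel grid; the voxel with index ``(z, y, x)`` has its centre at
``origin + (index + 0.5) * voxel_pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Compartment label semantics shared by every mask in the package.
LABEL_EXTRACELLULAR = 0
LABEL_CYTOSOL = 1
LABEL_MEMBRANE = 2
LABEL_ER = 3
LABEL_PSD = 4
LABEL_MITOCHONDRIA = 5

LABEL_NAMES = {
    LABEL_EXTRACELLULAR: "extracellular",
    LABEL_CYTOSOL: "cytosol",
    LABEL_MEMBRANE: "membrane",
    LABEL_ER: "er",
    LABEL_PSD: "psd",
    LABEL_MITOCHONDRIA: "mitochondria",
}

#: Domain tags for connected cytosol regions.
DOMAIN_NONE = 0
DOMAIN_HEAD = 1
DOMAIN_NECK = 2

DOMAIN_NAMES = {DOMAIN_NONE: "none", DOMAIN_HEAD: "head", DOMAIN_NECK: "neck"}

NM3_PER_UM3 = 1e9


@dataclass
class VolumeGrid:
    """A 3D scalar field with a physical voxel pitch.

    Parameters
    ----------
    data
        3D array (z, y, x) of intensities, arbitrary units.
    voxel_pitch
        Edge length of one voxel in nm (isotropic).
    origin
        Physical offset of the grid corner in nm.
    """

    data: np.ndarray
    voxel_pitch: float = 2.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if not self.voxel_pitch > 0:
            raise ValueError("voxel_pitch must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_nm3(self) -> float:
        return float(self.voxel_pitch**3)

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions (nm) of voxel centres for (z,y,x) indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.voxel_pitch

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return replace(self, data=data)


@dataclass
class LabelMask:
    """Per-voxel compartment labels co-registered with a :class:`VolumeGrid`.

    ``labels`` uses the module-level ``LABEL_*`` constants.  ``domains``
    optionally tags each cytosol voxel as spine head or neck
    (``DOMAIN_HEAD`` / ``DOMAIN_NECK``); voxels outside the cytosol carry
    ``DOMAIN_NONE``.
    """

    labels: np.ndarray
    voxel_pitch: float = 2.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    domains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("label mask must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.domains is not None:
            self.domains = np.asarray(self.domains)
            if self.domains.shape != self.labels.shape:
                raise ValueError("domains must match label shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def cytosol(self) -> np.ndarray:
        """Boolean mask of analyzable cytosol voxels."""
        return self.labels == LABEL_CYTOSOL

    def cytosol_volume_nm3(self) -> float:
        return float(np.count_nonzero(self.cytosol())) * self.voxel_pitch**3

    def cytosol_volume_um3(self) -> float:
        return self.cytosol_volume_nm3() / NM3_PER_UM3

    def domain_of(self, tag: int) -> np.ndarray:
        """Cytosol voxels belonging to a given domain tag."""
        cyt = self.cytosol()
        if self.domains is None:
            return cyt if tag == DOMAIN_NONE else np.zeros_like(cyt)
        return cyt & (self.domains == tag)

    def domain_tags_present(self) -> list[int]:
        if self.domains is None:
            return [DOMAIN_NONE]
        tags = np.unique(self.domains[self.cytosol()])
        return [int(t) for t in tags if t != DOMAIN_NONE] or [DOMAIN_NONE]

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.voxel_pitch

    def check_companion(self, volume: VolumeGrid) -> None:
        if volume.shape != self.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume {volume.shape}"
            )
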