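"""Analysis configuration.

The defaults encode the standard processing parameters for binned tomograms
at 2 nm voxel pitch: a 2 nm Gaussian denoising kernel, a 20 nm local
threshold window with Niblack offset k = 0.1, a 4 nm stub-pruning cutoff,
a 4 nm kernel for cytoskeleton volume reconstruction (half the 8 nm
filament diameter), a 10 nm membrane shell for branch-end analyses and
3 nm bins for spatial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    sigma_smooth: float = 2.0  # nm, Gaussian denoising kernel SD
    window_size: float = 20.0  # nm, local threshold window
    k: float = 0.1  # unitless Niblack offset
    threshold_form: str = "niblack"  # {"niblack", "mean-offset"}
    stub_min: float = 4.0  # nm, minimum retained terminal branch
    sigma_vol: float = 4.0  # nm, volume-reconstruction kernel SD
    filament_diameter: float = 8.0  # nm
    shell_width: float = 10.0  # nm, membrane shell for branch-end stats
    profile_bin: float = 3.0  # nm, spatial profile bin size
    voxel_pitch: float = 2.0  # nm, fallback pitch when headers lack one
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sigma_smooth",
            "window_size",
            "stub_min",
            "sigma_vol",
            "filament_diameter",
            "shell_width",
            "profile_bin",
            "voxel_pitch",
        ):
            if not getattr(self, name) > 0 and name != "stub_min":
                raise ValueError(f"{name} must be positive")
        if self.stub_min < 0:
            raise ValueError("stub_min must be non-negative")
        if not self.window_size > self.sigma_smooth:
            raise ValueError("window_size must exceed sigma_smooth")
        if not self.window_size > self.stub_min:
            raise ValueError("window_size must exceed stub_min")
        if self.threshold_form not in ("niblack", "mean-offset"):
            raise ValueError("threshold_form must be 'niblack' or 'mean-offset'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
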