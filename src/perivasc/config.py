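"""Run configuration for the perivascular quantification pipeline.

All spatial windows are in micrometres. The defaults encode the analysis
conventions used throughout the package: tau intensity is exported for tissue
within 100 um of a vessel surface, "surface tau" means intensity within 3 um
of the mask, segments are 10 um along-vessel intervals, objects are counted in
a 30 um shell, and segments are ranked into deciles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the pipeline.

    Parameters
    ----------
    surface_window_um : float
        Distance from the vessel mask defining "surface" tissue (default 3).
    bin_length_um : float
        Length of one along-vessel segment bin (default 10).
    shell_max_um : float
        Outer radius of the object-density shell (default 30).
    export_max_um : float
        Outer radius of the voxel-record export region (default 100).
    profile_step_um : float
        Distance step of the radial intensity profile (default 1).
    n_percentile_groups : int
        Number of rank groups for surface-tau scoring (default 10, deciles).
    coloc_radius_um : float
        Maximum neuron-to-NFT centroid distance for a neuron to count as
        NFT-bearing (default 5).
    rng_seed : int
        Seed for any stochastic step (e.g. scene simulation).
    """

    surface_window_um: float = 3.0
    bin_length_um: float = 10.0
    shell_max_um: float = 30.0
    export_max_um: float = 100.0
    profile_step_um: float = 1.0
    n_percentile_groups: int = 10
    coloc_radius_um: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.surface_window_um <= self.shell_max_um <= self.export_max_um):
            raise ValueError(
                "require 0 < surface_window_um <= shell_max_um <= export_max_um, "
                f"got {self.surface_window_um}, {self.shell_max_um}, {self.export_max_um}"
            )
        if self.bin_length_um <= 0:
            raise ValueError("bin_length_um must be > 0")
        if self.profile_step_um <= 0:
            raise ValueError("profile_step_um must be > 0")
        if self.n_percentile_groups < 2:
            raise ValueError("n_percentile_groups must be >= 2")
        if self.coloc_radius_um <= 0:
            raise ValueError("coloc_radius_um must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
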