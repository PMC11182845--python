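"""Cross-sample harmonization of tau intensity.

Fluorescence intensity is not comparable across cleared-tissue samples:
staining efficiency, laser power and depth attenuation shift and stretch the
scale per sample. The pipeline therefore records, per sample, raw intensities
for three reference regimes — image background, tissue autofluorescence, and
unambiguous phospho-tau positivity — at 3 z-depths with 10 measurements per
category per depth, and maps each sample onto a canonical scale by a
two-segment piecewise-linear function anchored at the three category means.

Canonical targets are fixed at (0, 1, 2) for (background, autofluorescence,
positive); beyond the end anchors the adjacent segment's slope extrapolates
linearly, preserving the ordering of extreme tangle intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ImageVolume

CATEGORIES = ("background", "autofluorescence", "positive")
CANONICAL_TARGETS = (0.0, 1.0, 2.0)


@dataclass
class NormalizationAnchors:
    """Per-sample anchor measurements and their category means.

    ``raw_measurements`` maps category -> array of raw values (all depths
    pooled; by convention 3 depths x 10 values = 30 per category).
    """

    raw_measurements: dict[str, np.ndarray]
    anchor_means: tuple[float, float, float]
    canonical_targets: tuple[float, float, float] = CANONICAL_TARGETS

    def __post_init__(self) -> None:
        b, a, p = self.anchor_means
        if not (b < a < p):
            raise ValueError(
                f"anchor order violated: background {b} < autofluorescence {a} "
                f"< positive {p} required"
            )
        t0, t1, t2 = self.canonical_targets
        if not (t0 < t1 < t2):
            raise ValueError("canonical targets must be strictly increasing")

    @classmethod
    def from_raw(
        cls,
        raw: Mapping[str, Sequence[float]],
        canonical_targets: tuple[float, float, float] = CANONICAL_TARGETS,
    ) -> "NormalizationAnchors":
        arrays = {c: np.asarray(raw[c], dtype=float) for c in CATEGORIES}
        means = tuple(float(arrays[c].mean()) for c in CATEGORIES)
        return cls(arrays, means, canonical_targets)

    def to_dict(self) -> dict:
        return {
            "raw_measurements": {c: v.tolist() for c, v in self.raw_measurements.items()},
            "anchor_means": list(self.anchor_means),
            "canonical_targets": list(self.canonical_targets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationAnchors":
        return cls(
            {c: np.asarray(v, dtype=float) for c, v in d["raw_measurements"].items()},
            tuple(d["anchor_means"]),
            tuple(d.get("canonical_targets", CANONICAL_TARGETS)),
        )


def collect_anchors(
    volume: ImageVolume,
    sample_sites: Mapping[str, Sequence[tuple[int, int, int]]],
    n_depths: int = 3,
) -> NormalizationAnchors:
    """Read anchor intensities at operator-supplied voxel sites.

    ``sample_sites`` maps each category to voxel indices; the sites of each
    category must span exactly ``n_depths`` distinct z-planes with at least
    one site per plane. The anchor mean is the grand mean over all sites.
    """
    raw: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        sites = np.asarray(sample_sites[cat], dtype=int)
        if sites.ndim != 2 or sites.shape[1] != 3 or len(sites) == 0:
            raise ValueError(f"{cat}: sites must be a non-empty (n, 3) index array")
        depths = np.unique(sites[:, 2])
        if len(depths) != n_depths:
            raise ValueError(
                f"{cat}: sites span {len(depths)} z-depths, expected {n_depths}"
            )
        raw[cat] = volume.data[sites[:, 0], sites[:, 1], sites[:, 2]].astype(float)
    return NormalizationAnchors.from_raw(raw)


def piecewise_linear_normalize(
    intensity: np.ndarray | float, anchors: NormalizationAnchors
) -> np.ndarray | float:
    """Map raw intensity onto the canonical scale.

    Linear between adjacent anchors, linear extrapolation beyond the end
    anchors with the adjacent segment's slope; strictly monotone.
    """
    b, a, p = anchors.anchor_means
    t0, t1, t2 = anchors.canonical_targets
    x = np.asarray(intensity, dtype=float)
    lower = t0 + (x - b) * (t1 - t0) / (a - b)
    upper = t1 + (x - a) * (t2 - t1) / (p - a)
    out = np.where(x <= a, lower, upper)
    if np.isscalar(intensity) or np.ndim(intensity) == 0:
        return float(out)
    return out


def normalize_volume(volume: ImageVolume, anchors: NormalizationAnchors) -> ImageVolume:
    """Voxelwise piecewise-linear normalization of a whole volume."""
    return ImageVolume(
        data=piecewise_linear_normalize(volume.data, anchors),
        spacing=volume.spacing,
        channel=volume.channel,
    )


def normalize_to_reference(
    values: pd.Series, reference_ids: Sequence, percent_change: bool = False
) -> pd.Series:
    """Rescale per-sample summaries by the mean of a reference sample set.

    With ``percent_change`` the result is (value/reference - 1) * 100, so a
    value equal to the reference mean maps to 0%.
    """
    values = pd.Series(values, dtype=float)
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference set is empty")
    missing = [r for r in reference_ids if r not in values.index]
    if missing:
        raise ValueError(f"reference ids not in values: {missing}")
    ref_mean = float(values.loc[reference_ids].mean())
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    out = values / ref_mean
    if percent_change:
        out = (out - 1.0) * 100.0
    return out
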