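"""Neuron / NFT densities in the perivascular shell.

Segmented objects (neuron somata and neurofibrillary tangles) get
vessel-relative coordinates: distance to the nearest vessel surface and, for
objects within the 30 um shell, the arc-length coordinate along that vessel.
Per 10 um segment bin the module computes the shell volume (voxel-counted,
mm^3), object densities, and the percent of neurons bearing an NFT — a
neuron counts as NFT-bearing when an NFT centroid lies within a small
colocalization radius of it (default 5 um).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .geometry import VesselModel, assign_along_distance
from .io import ImageVolume
from .profiles import n_bins_for_length

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

UM3_PER_MM3 = 1e9


def segment_objects(
    volume: ImageVolume,
    threshold: float,
    min_size: int,
    object_class: str,
) -> pd.DataFrame:
    """Threshold + 26-connected components stand-in segmenter.

    Components smaller than ``min_size`` voxels are discarded as noise;
    centroids are mean voxel world positions. The class label comes from the
    channel being segmented.
    """
    labels, n = ndimage.label(volume.data > threshold, structure=_STRUCT26)
    if n == 0:
        return pd.DataFrame(columns=["id", "x_um", "y_um", "z_um", "class"])
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index=keep)
    pos = np.asarray(centroids, dtype=float).reshape(-1, 3) * np.asarray(volume.spacing)
    return pd.DataFrame(
        {
            "id": np.arange(len(keep)),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "class": object_class,
        }
    )


def _interp_distance(field: np.ndarray, spacing, points_um: np.ndarray) -> np.ndarray:
    coords = (points_um / np.asarray(spacing, dtype=float)).T
    return ndimage.map_coordinates(field, coords, order=1, mode="nearest")


def assign_objects(
    objects: pd.DataFrame,
    vessels: Sequence[VesselModel],
    config: PipelineConfig,
    layers: ImageVolume | None = None,
) -> pd.DataFrame:
    """Attach vessel-relative coordinates to segmented objects.

    ``d_surface_um`` is the (trilinearly interpolated) distance to the
    nearest vessel's surface; objects within ``shell_max_um`` additionally
    get ``vessel_id``, ``bin_index`` and ``s_along_um`` on that vessel.
    Equidistant objects go to the lower vessel_id. Objects beyond the shell
    keep their distance but stay unassigned.
    """
    if len(vessels) == 0:
        raise ValueError("need at least one vessel")
    vessels = sorted(vessels, key=lambda v: v.vessel_id)
    out = objects.copy()
    pts = out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(pts) == 0:
        for col in ("d_surface_um", "s_along_um"):
            out[col] = np.nan
        out["vessel_id"] = pd.array([], dtype="Int64")
        out["bin_index"] = pd.array([], dtype="Int64")
        return out
    dists = np.column_stack(
        [_interp_distance(v.distance_field, v.spacing, pts) for v in vessels]
    )
    nearest = np.argmin(dists, axis=1)  # first occurrence = lower vessel_id
    d_near = dists[np.arange(len(pts)), nearest]
    out["d_surface_um"] = d_near
    out["vessel_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["bin_index"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["s_along_um"] = np.nan
    in_shell = d_near <= config.shell_max_um
    for j, v in enumerate(vessels):
        sel = in_shell & (nearest == j)
        if not sel.any():
            continue
        s = assign_along_distance(pts[sel], v.centerline, v.arclength)
        nb = n_bins_for_length(v.length_um, config.bin_length_um)
        out.loc[sel, "vessel_id"] = v.vessel_id
        out.loc[sel, "s_along_um"] = s
        out.loc[sel, "bin_index"] = np.clip(
            np.floor(s / config.bin_length_um).astype(int), 0, nb - 1
        )
    if layers is not None:
        idx = np.rint(pts / np.asarray(layers.spacing)).astype(int)
        idx = np.clip(idx, 0, np.asarray(layers.shape) - 1)
        out["layer"] = layers.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def compute_shell_volumes(
    vessel: VesselModel,
    config: PipelineConfig,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Voxel-counted volume (mm^3) of the <=30 um shell per segment bin.

    The shell excludes the vessel's own mask (objects cannot occupy the
    lumen) and any ``exclude`` voxels (e.g. tissue nearer to another vessel).
    """
    d = vessel.distance_field
    sel = (d <= config.shell_max_um) & ~vessel.mask
    if exclude is not None:
        sel &= ~exclude
    idx = np.argwhere(sel)
    voxvol = float(np.prod(vessel.spacing))
    nb = n_bins_for_length(vessel.length_um, config.bin_length_um)
    out = pd.DataFrame({"vessel_id": vessel.vessel_id, "bin_index": np.arange(nb)})
    if len(idx) == 0:
        out["shell_voxel_count"] = 0
        out["shell_volume_mm3"] = 0.0
        return out
    pos = idx * np.asarray(vessel.spacing)
    s = assign_along_distance(pos, vessel.centerline, vessel.arclength)
    k = np.clip(np.floor(s / config.bin_length_um).astype(int), 0, nb - 1)
    counts = np.bincount(k, minlength=nb)
    out["shell_voxel_count"] = counts
    out["shell_volume_mm3"] = counts * voxvol / UM3_PER_MM3
    return out


def mark_nft_bearing(
    objects: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Flag neurons with an NFT centroid within the colocalization radius."""
    out = objects.copy()
    neurons = out["class"] == "neuron"
    nfts = out["class"] == "nft"
    flag = np.zeros(len(out), dtype=bool)
    if neurons.any() and nfts.any():
        tree = cKDTree(out.loc[nfts, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
        d, _ = tree.query(out.loc[neurons, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
        flag[np.flatnonzero(neurons.to_numpy())] = d <= config.coloc_radius_um
    out["nft_bearing"] = flag & neurons.to_numpy()
    return out


def compute_densities(
    objects: pd.DataFrame,
    shell_volumes: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per (vessel, bin) object counts, densities and NFT-bearing fraction.

    ``pct_neurons_with_nft`` is NaN where no neurons fall in the bin; an
    object in a zero-volume bin is a geometry inconsistency and raises.
    """
    if "nft_bearing" not in objects.columns:
        objects = mark_nft_bearing(objects, config)
    assigned = objects[objects["vessel_id"].notna()].copy()
    assigned["vessel_id"] = assigned["vessel_id"].astype(int)
    assigned["bin_index"] = assigned["bin_index"].astype(int)
    key = ["vessel_id", "bin_index"]
    grouped = assigned.groupby(key)
    counts = grouped.apply(
        lambda g: pd.Series(
            {
                "neuron_count": int((g["class"] == "neuron").sum()),
                "nft_count": int((g["class"] == "nft").sum()),
                "neurons_with_nft": int(g["nft_bearing"].sum()),
            }
        ),
        include_groups=False,
    ).reset_index()
    out = shell_volumes.merge(counts, on=key, how="outer")
    for c in ("neuron_count", "nft_count", "neurons_with_nft"):
        out[c] = out[c].fillna(0).astype(int)
    occupied = (out["neuron_count"] + out["nft_count"]) > 0
    if (occupied & (out["shell_volume_mm3"].fillna(0) <= 0)).any():
        raise ValueError("objects assigned to a bin with zero shell volume")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["neuron_density_per_mm3"] = out["neuron_count"] / out["shell_volume_mm3"]
        out["nft_density_per_mm3"] = out["nft_count"] / out["shell_volume_mm3"]
    out["pct_neurons_with_nft"] = np.where(
        out["neuron_count"] > 0,
        100.0 * out["neurons_with_nft"] / out["neuron_count"].replace(0, np.nan),
        np.nan,
    )
    return out


def nft_fraction_by_decile(
    density: pd.DataFrame, bins: pd.DataFrame
) -> pd.DataFrame:
    """Per-donor per-decile percent of neurons with an NFT.

    Counts are pooled over all of a donor's bins in the decile:
    100 * sum(NFT-bearing neurons) / sum(neurons). Donor x decile cells with
    no neurons are missing.
    """
    key = [c for c in ("donor", "vessel_id", "bin_index") if c in bins.columns]
    merged = density.merge(
        bins[key + ["decile"]],
        on=[c for c in key if c in density.columns],
        how="inner",
    )
    merged = merged[merged["decile"].notna()]
    if "donor" not in merged.columns:
        merged = merged.assign(donor="sample")
    g = merged.groupby(["donor", "decile"])[["neurons_with_nft", "neuron_count"]].sum()
    g = g.reset_index()
    g["pct_neurons_with_nft"] = np.where(
        g["neuron_count"] > 0,
        100.0 * g["neurons_with_nft"] / g["neuron_count"].replace(0, np.nan),
        np.nan,
    )
    return g
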