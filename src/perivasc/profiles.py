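"""Vessel-relative tau quantification.

The core data structure is the **voxel record table**: one row per tissue
voxel within 100 um of a vessel surface, carrying world position, raw and
normalized tau intensity, cortical layer, distance-from-surface ``d_surface``
and distance-along-vessel ``s_along``. From it the pipeline builds

* **segment bins**: 10 um along-vessel intervals with the mean normalized
  tau of their surface voxels (d_surface <= 3 um);
* **deciles**: rank groups of segment bins by surface tau, pooled across
  vessels and donors (decile 10 = most surface tau);
* **radial profiles**: per donor and decile, percent change of tau relative
  to the donor's whole-image mean as a function of distance from the surface;
* **heatmaps**: per-vessel rows of log10 surface tau over bins;
* **layer summaries**: per-donor per-cortical-layer mean surface tau.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geometry import VesselModel, assign_along_distance
from .io import ImageVolume

RECORD_COLUMNS = [
    "vessel_id", "x_um", "y_um", "z_um", "raw_intensity", "norm_intensity",
    "layer", "d_surface_um", "s_along_um",
]


def extract_voxel_records(
    tau_norm: ImageVolume,
    vessel: VesselModel,
    layers: ImageVolume | None,
    config: PipelineConfig,
    tau_raw: ImageVolume | None = None,
    other_min_distance: np.ndarray | None = None,
    other_masks: np.ndarray | None = None,
) -> pd.DataFrame:
    """One record per voxel within ``export_max_um`` of this vessel's surface.

    Voxels inside other vessels' masks are excluded, and — when
    ``other_min_distance`` (elementwise minimum of the other vessels'
    distance fields) is given — so are voxels strictly nearer to another
    vessel, so that each tissue voxel is attributed to exactly one vessel.
    """
    if tau_norm.shape != vessel.distance_field.shape:
        raise ValueError(
            f"grid mismatch: tau {tau_norm.shape} vs distance {vessel.distance_field.shape}"
        )
    if layers is not None and layers.shape != tau_norm.shape:
        raise ValueError("layer volume grid mismatch")
    d = vessel.distance_field
    sel = d <= config.export_max_um
    if other_masks is not None:
        sel &= ~other_masks
    if other_min_distance is not None:
        sel &= d <= other_min_distance  # ties go to the lower vessel_id caller order
    idx = np.argwhere(sel)
    pos = idx * np.asarray(tau_norm.spacing)
    s_along = assign_along_distance(pos, vessel.centerline, vessel.arclength)
    df = pd.DataFrame(
        {
            "vessel_id": vessel.vessel_id,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "raw_intensity": (
                tau_raw.data[sel] if tau_raw is not None else np.nan
            ),
            "norm_intensity": tau_norm.data[sel],
            "layer": layers.data[sel] if layers is not None else 0,
            "d_surface_um": d[sel],
            "s_along_um": s_along,
        }
    )
    return df


def extract_all_voxel_records(
    tau_norm: ImageVolume,
    vessels: Sequence[VesselModel],
    layers: ImageVolume | None,
    config: PipelineConfig,
    tau_raw: ImageVolume | None = None,
) -> pd.DataFrame:
    """Voxel records for every vessel with nearest-vessel attribution.

    A voxel within range of several vessels is attributed to the nearest one
    (ties to the lower vessel_id), so no voxel is double-counted.
    """
    vessels = sorted(vessels, key=lambda v: v.vessel_id)
    any_mask = np.zeros(tau_norm.shape, dtype=bool)
    for v in vessels:
        any_mask |= v.mask
    frames = []
    for i, v in enumerate(vessels):
        others = [w for w in vessels if w.vessel_id != v.vessel_id]
        if others:
            other_min = np.minimum.reduce([w.distance_field for w in others])
            # strict inequality for later ids, <= for earlier: implement the
            # lower-id tie rule by comparing with a tiny bias
            earlier = [w.distance_field for w in vessels[:i]]
            later = [w.distance_field for w in vessels[i + 1:]]
            sel_other = np.full(tau_norm.shape, np.inf)
            if earlier:
                sel_other = np.minimum(sel_other, np.minimum.reduce(earlier) * (1 - 1e-12) - 1e-12)
            if later:
                sel_other = np.minimum(sel_other, np.minimum.reduce(later))
            other_min = sel_other
        else:
            other_min = None
        frames.append(
            extract_voxel_records(
                tau_norm, v, layers, config,
                tau_raw=tau_raw,
                other_min_distance=other_min,
                other_masks=(any_mask & ~v.mask) if others else None,
            )
        )
    return pd.concat(frames, ignore_index=True)


def n_bins_for_length(length_um: float, bin_length_um: float) -> int:
    return max(1, int(math.ceil(length_um / bin_length_um - 1e-9)))


def attach_bin_index(
    records: pd.DataFrame, vessel_length_um: float, config: PipelineConfig
) -> pd.DataFrame:
    """Add the along-vessel ``bin_index`` column ([k*L, (k+1)*L) intervals;
    the final, possibly short, bin is closed at the vessel end)."""
    nb = n_bins_for_length(vessel_length_um, config.bin_length_um)
    k = np.floor(records["s_along_um"].to_numpy() / config.bin_length_um).astype(int)
    records = records.copy()
    records["bin_index"] = np.clip(k, 0, nb - 1)
    return records


def bin_segments(
    records: pd.DataFrame, vessel_length_um: float, config: PipelineConfig
) -> pd.DataFrame:
    """Aggregate one vessel's records into 10 um segment bins.

    Every bin of the tiling is present in the output; bins with no surface
    voxels (d_surface <= surface window) carry NaN surface_mean and are
    excluded from decile ranking downstream. End bins shorter than the bin
    length are kept and flagged ``short_bin``.
    """
    if records["vessel_id"].nunique() > 1:
        raise ValueError("bin_segments expects records from a single vessel")
    if "bin_index" not in records.columns:
        records = attach_bin_index(records, vessel_length_um, config)
    L = config.bin_length_um
    nb = n_bins_for_length(vessel_length_um, L)
    vid = records["vessel_id"].iloc[0] if len(records) else -1
    surface = records[records["d_surface_um"] <= config.surface_window_um]
    agg = surface.groupby("bin_index")["norm_intensity"].agg(["mean", "size"])
    counts = records.groupby("bin_index").size()
    # majority cortical layer of each bin's surface voxels; ties -> smaller label
    def _majority(x: pd.Series) -> int:
        vc = x.value_counts()
        top = vc[vc == vc.max()]
        return int(min(top.index))

    layer = surface.groupby("bin_index")["layer"].agg(_majority)
    out = pd.DataFrame({"bin_index": np.arange(nb)})
    out["vessel_id"] = vid
    out["s_start_um"] = out["bin_index"] * L
    out["s_end_um"] = np.minimum((out["bin_index"] + 1) * L, vessel_length_um)
    out["short_bin"] = (out["s_end_um"] - out["s_start_um"]) < L - 1e-9
    out["surface_mean"] = out["bin_index"].map(agg["mean"])
    out["surface_voxel_count"] = (
        out["bin_index"].map(agg["size"]).fillna(0).astype(int)
    )
    out["n_voxels"] = out["bin_index"].map(counts).fillna(0).astype(int)
    out["surface_layer"] = out["bin_index"].map(layer)
    return out[
        ["vessel_id", "bin_index", "s_start_um", "s_end_um", "short_bin",
         "surface_mean", "surface_voxel_count", "n_voxels", "surface_layer"]
    ]


def assign_deciles(
    bins: pd.DataFrame,
    config: PipelineConfig | None = None,
    scope: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank segment bins by surface tau into percentile groups (deciles).

    Ranking pools all rankable bins (surface_voxel_count > 0) within each
    scope group (default: one pooled scope across all vessels and donors).
    Group g holds rank fractions in ((g-1)/G, g/G]; ties in surface_mean
    break deterministically by (donor, vessel_id, bin_index).
    """
    g_count = (config or PipelineConfig()).n_percentile_groups
    bins = bins.copy()
    bins["decile"] = pd.array([pd.NA] * len(bins), dtype="Int64")
    tie_cols = [c for c in ("donor", "vessel_id", "bin_index") if c in bins.columns]

    def _rank(group: pd.DataFrame) -> None:
        rankable = group[group["surface_voxel_count"] > 0]
        n = len(rankable)
        if n < g_count:
            raise ValueError(
                f"only {n} rankable bins in scope; need >= {g_count} for "
                f"{g_count} percentile groups"
            )
        order = rankable.sort_values(["surface_mean"] + tie_cols).index
        ranks = np.arange(1, n + 1)
        dec = np.ceil(ranks * g_count / n).astype(int)
        bins.loc[order, "decile"] = dec

    if scope:
        for _, grp in bins.groupby(list(scope)):
            _rank(grp)
    else:
        _rank(bins)
    return bins


def radial_profile(
    records: pd.DataFrame,
    bins: pd.DataFrame,
    image_mean: float | Mapping,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Percent change of tau vs distance from the surface, per donor and decile.

    Records inherit the decile of their segment bin. For each distance step
    [k, k+1) um, percent change = (mean norm intensity / donor whole-image
    mean - 1) * 100, so 0% means indistinguishable from the image average.
    """
    key = [c for c in ("donor", "vessel_id", "bin_index") if c in bins.columns]
    merged = records.merge(
        bins[key + ["decile"]], on=[c for c in key if c in records.columns], how="inner"
    )
    merged = merged[merged["decile"].notna()]
    merged["distance_step"] = np.floor(
        merged["d_surface_um"].to_numpy() / config.profile_step_um
    ).astype(int)
    if "donor" not in merged.columns:
        merged["donor"] = "sample"
    means = (
        merged.groupby(["donor", "decile", "distance_step"])["norm_intensity"]
        .agg(["mean", "size"])
        .reset_index()
    )
    if isinstance(image_mean, Mapping):
        ref = means["donor"].map(image_mean).astype(float)
    else:
        ref = float(image_mean)
    if np.any(np.asarray(ref) <= 0):
        raise ValueError("whole-image mean must be positive")
    means["d_um"] = means["distance_step"] * config.profile_step_um
    means["pct_change"] = (means["mean"] / ref - 1.0) * 100.0
    means = means.rename(columns={"size": "n_voxels"})
    return means[["donor", "decile", "distance_step", "d_um", "pct_change", "n_voxels"]]


def summarize_radial(profile: pd.DataFrame) -> pd.DataFrame:
    """Across-donor mean and SEM of the radial percent-change curves."""
    g = profile.groupby(["decile", "distance_step"])["pct_change"]
    out = g.agg(["mean", "sem", "size"]).reset_index()
    out = out.rename(columns={"mean": "pct_change_mean", "sem": "pct_change_sem",
                              "size": "n_donors"})
    return out


def build_heatmap(bins: pd.DataFrame, image_mean: float | Mapping) -> pd.DataFrame:
    """Per-vessel rows of log10(surface tau / whole-image mean) over bins.

    Rows are vessels (donor, vessel_id), columns bin indices padded to the
    longest vessel; empty bins and non-positive ratios are missing (NaN).
    """
    bins = bins.copy()
    if "donor" not in bins.columns:
        bins["donor"] = "sample"
    if isinstance(image_mean, Mapping):
        ref = bins["donor"].map(image_mean).astype(float)
    else:
        ref = float(image_mean)
    ratio = bins["surface_mean"] / ref
    with np.errstate(invalid="ignore", divide="ignore"):
        bins["log_ratio"] = np.where(ratio > 0, np.log10(ratio), np.nan)
    return bins.pivot_table(
        index=["donor", "vessel_id"], columns="bin_index", values="log_ratio",
        dropna=False,
    )


def layer_surface_summary(bins: pd.DataFrame) -> pd.DataFrame:
    """Per-donor per-cortical-layer mean surface tau over segment bins.

    Each bin contributes through its majority surface layer; unassigned
    tissue (layer 0) is excluded.
    """
    bins = bins.copy()
    if "donor" not in bins.columns:
        bins["donor"] = "sample"
    valid = bins[bins["surface_layer"].notna() & (bins["surface_layer"] != 0)]
    out = (
        valid.groupby(["donor", "surface_layer"])["surface_mean"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"surface_layer": "layer", "mean": "surface_tau_mean",
                         "size": "n_bins"})
    )
    out["layer"] = out["layer"].astype(int)
    return out
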