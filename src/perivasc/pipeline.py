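"""End-to-end orchestration: scene -> geometry -> normalization -> profiles
-> densities -> cohort statistics.

Each donor image (real or synthetic) lives in one directory (the scene
bundle). :func:`run_scene_pipeline` processes one donor; :func:`analyze_cohort`
pools segment bins across donors, assigns surface-tau deciles cohort-wide,
and produces radial profiles, heatmaps, layer summaries, the NFT-fraction
table and the repeated-measures ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import density as dens
from . import profiles as prof
from .config import PipelineConfig
from .geometry import (VesselModel, build_vessel_model, save_vessel_model)
from .io import ImageVolume, read_object_table, read_volume
from .normalization import NormalizationAnchors, normalize_volume
from .stats import RMAnovaResult, rm_anova
from .synthetic import Scene, SceneSpec, generate_scene, write_scene


@dataclass
class SceneResult:
    """Everything the pipeline derives from one donor image."""

    donor: str
    config: PipelineConfig
    vessels: list[VesselModel]
    records: pd.DataFrame  # voxel records, bin_index attached
    bins: pd.DataFrame  # segment bins (no deciles yet)
    shell_volumes: pd.DataFrame
    objects: pd.DataFrame  # vessel-relative coordinates attached
    density: pd.DataFrame
    image_mean: float  # whole-image mean of the normalized tau volume
    diameters_um: list[float] = field(default_factory=list)


def process_scene(
    tau_raw: ImageVolume,
    masks: Sequence[np.ndarray],
    layers: ImageVolume | None,
    anchors: NormalizationAnchors,
    objects: pd.DataFrame,
    config: PipelineConfig,
    donor: str = "sample",
) -> SceneResult:
    """Run geometry, normalization, profiling and density for one donor."""
    tau_norm = normalize_volume(tau_raw, anchors)
    image_mean = float(tau_norm.data.mean())
    vessels = [
        build_vessel_model(mask, tau_raw.spacing, vessel_id=vi)
        for vi, mask in enumerate(masks)
    ]
    records = prof.extract_all_voxel_records(
        tau_norm, vessels, layers, config, tau_raw=tau_raw
    )
    bin_frames = []
    rec_frames = []
    for v in vessels:
        rv = records[records["vessel_id"] == v.vessel_id]
        rv = prof.attach_bin_index(rv, v.length_um, config)
        rec_frames.append(rv)
        bin_frames.append(prof.bin_segments(rv, v.length_um, config))
    records = pd.concat(rec_frames, ignore_index=True)
    bins = pd.concat(bin_frames, ignore_index=True)
    records["donor"] = donor
    bins["donor"] = donor

    # shell volumes with nearest-vessel attribution (no voxel counted twice)
    vols = []
    for v in vessels:
        others = [w for w in vessels if w.vessel_id != v.vessel_id]
        exclude = None
        if others:
            other_min = np.minimum.reduce([w.distance_field for w in others])
            exclude = other_min < v.distance_field
            for w in others:
                exclude |= w.mask
        vols.append(dens.compute_shell_volumes(v, config, exclude=exclude))
    shell_volumes = pd.concat(vols, ignore_index=True)

    objects_assigned = dens.assign_objects(objects, vessels, config, layers=layers)
    objects_assigned = dens.mark_nft_bearing(objects_assigned, config)
    density = dens.compute_densities(objects_assigned, shell_volumes, config)
    density["donor"] = donor

    return SceneResult(
        donor=donor,
        config=config,
        vessels=vessels,
        records=records,
        bins=bins,
        shell_volumes=shell_volumes,
        objects=objects_assigned,
        density=density,
        image_mean=image_mean,
        diameters_um=[v.diameter_um for v in vessels],
    )


def process_scene_dir(
    scene_dir: str | Path, config: PipelineConfig, donor: str | None = None
) -> SceneResult:
    """Run :func:`process_scene` on an on-disk scene bundle."""
    scene_dir = Path(scene_dir)
    donor = donor or scene_dir.name
    tau = read_volume(scene_dir / "tau.tif", channel="tau")
    layers_path = scene_dir / "layers.tif"
    layers = read_volume(layers_path, channel="layers") if layers_path.exists() else None
    mask_paths = sorted(scene_dir.glob("vessel_*_mask.h5"))
    if not mask_paths:
        raise FileNotFoundError(f"{scene_dir}: no vessel masks (vessel_*_mask.h5)")
    masks = [read_volume(p).data.astype(bool) for p in mask_paths]
    anchors_path = scene_dir / "anchors.json"
    if anchors_path.exists():
        anchors = NormalizationAnchors.from_dict(json.loads(anchors_path.read_text()))
    else:
        truth = json.loads((scene_dir / "truth.json").read_text())
        anchors = NormalizationAnchors.from_dict(truth["anchors"])
    objects_path = scene_dir / "objects.csv"
    objects = (
        read_object_table(objects_path)
        if objects_path.exists()
        else pd.DataFrame(columns=["id", "x_um", "y_um", "z_um", "class"])
    )
    return process_scene(tau, masks, layers, anchors, objects, config, donor=donor)


@dataclass
class CohortResult:
    """Cohort-level outputs pooled over donors."""

    config: PipelineConfig
    bins: pd.DataFrame  # decile-labelled segment bins
    radial: pd.DataFrame
    radial_summary: pd.DataFrame
    heatmap: pd.DataFrame
    layer_summary: pd.DataFrame
    nft_by_decile: pd.DataFrame
    anova: RMAnovaResult | None
    image_means: dict
    diameters_um: dict


def analyze_cohort(
    scenes: Sequence[SceneResult],
    config: PipelineConfig,
    decile_scope: Sequence[str] | None = None,
) -> CohortResult:
    """Pool donors, rank deciles, and compute the cohort-level tables.

    ``decile_scope`` defaults to cohort-wide pooling; pass ``("donor",)`` to
    rank deciles within each donor instead.
    """
    bins = pd.concat([s.bins for s in scenes], ignore_index=True)
    records = pd.concat([s.records for s in scenes], ignore_index=True)
    density = pd.concat(
        [s.density.assign(donor=s.donor) for s in scenes], ignore_index=True
    )
    image_means = {s.donor: s.image_mean for s in scenes}
    bins = prof.assign_deciles(bins, config, scope=decile_scope)
    radial = prof.radial_profile(records, bins, image_means, config)
    radial_summary = prof.summarize_radial(radial)
    heatmap = prof.build_heatmap(bins, image_means)
    layer_summary = prof.layer_surface_summary(bins)
    nft = dens.nft_fraction_by_decile(density, bins)
    anova = None
    wide = nft.pivot_table(index="donor", columns="decile",
                           values="pct_neurons_with_nft", dropna=False)
    try:
        anova = rm_anova(wide)
    except ValueError:
        anova = None  # too few complete decile levels (e.g. single donor)
    return CohortResult(
        config=config,
        bins=bins,
        radial=radial,
        radial_summary=radial_summary,
        heatmap=heatmap,
        layer_summary=layer_summary,
        nft_by_decile=nft,
        anova=anova,
        image_means=image_means,
        diameters_um={s.donor: s.diameters_um for s in scenes},
    )


def simulate_cohort(
    base_spec: SceneSpec,
    n_donors: int,
    seed: int,
    outdir: str | Path | None = None,
    gain_range: tuple[float, float] = (0.8, 1.2),
    offset_range: tuple[float, float] = (-10.0, 20.0),
) -> list[Scene]:
    """Generate ``n_donors`` scenes differing in seed and a per-donor affine
    intensity distortion (the cross-sample staining difference the
    normalization stage must undo)."""
    import dataclasses

    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_donors):
        spec_i = dataclasses.replace(
            base_spec,
            seed=int(rng.integers(0, 2**31 - 1)),
            gain=float(rng.uniform(*gain_range)),
            offset=float(rng.uniform(*offset_range)),
        )
        scene = generate_scene(spec_i)
        scenes.append(scene)
        if outdir is not None:
            write_scene(scene, Path(outdir) / f"donor_{i:02d}")
    return scenes


def scene_to_result(
    scene: Scene, config: PipelineConfig, donor: str = "sample"
) -> SceneResult:
    """Run the pipeline directly on an in-memory scene."""
    return process_scene(
        scene.tau, scene.masks, scene.layers, scene.anchors, scene.objects,
        config, donor=donor,
    )


def write_scene_outputs(result: SceneResult, outdir: str | Path,
                        export_voxels: bool = True) -> None:
    """Write one donor's derived tables and geometry files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for v in result.vessels:
        save_vessel_model(v, outdir)
    if export_voxels:
        result.records.to_csv(outdir / "voxel_records.csv", index=False)
    result.bins.to_csv(outdir / "segment_bins.csv", index=False)
    result.shell_volumes.to_csv(outdir / "shell_volumes.csv", index=False)
    result.objects.to_csv(outdir / "objects_assigned.csv", index=False)
    result.density.to_csv(outdir / "density_table.csv", index=False)
    (outdir / "scene_summary.json").write_text(
        json.dumps(
            {
                "donor": result.donor,
                "image_mean": result.image_mean,
                "diameters_um": result.diameters_um,
                "vessel_lengths_um": [v.length_um for v in result.vessels],
            },
            indent=2,
        )
    )


def write_cohort_outputs(cohort: CohortResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.bins.to_csv(outdir / "segment_bins_deciled.csv", index=False)
    cohort.radial.to_csv(outdir / "radial_profiles.csv", index=False)
    cohort.radial_summary.to_csv(outdir / "radial_profiles_summary.csv", index=False)
    cohort.heatmap.to_csv(outdir / "heatmap.csv")
    cohort.layer_summary.to_csv(outdir / "layer_summary.csv", index=False)
    cohort.nft_by_decile.to_csv(outdir / "nft_fraction_by_decile.csv", index=False)
    report = {
        "image_means": cohort.image_means,
        "diameters_um": cohort.diameters_um,
        "rm_anova": cohort.anova.to_dict() if cohort.anova else None,
    }
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=2))
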