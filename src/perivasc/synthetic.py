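"""Synthetic cleared-tissue phantoms.

Every downstream stage of the pipeline is testable without real data via
volumetric scenes that carry the statistical structure the analysis assumes:

* tubular vessels (straight, arc or helix paths) of ~10-25 um diameter
  spanning the cortical layers;
* a tau channel with three intensity regimes — Gaussian image background,
  low-frequency autofluorescence blotches, and AT8-like positivity — where
  the positive signal is anchored to chosen arc-length segments of a vessel
  and decays exponentially with distance from its surface
  (amplitude * exp(-d_surface / decay_length));
* Poisson-placed neurons whose probability of bearing an NFT increases
  linearly (clamped) with the local normalized surface tau of the nearest
  vessel segment;
* a layer label volume partitioning the tissue into cortical layers 1-6
  along the vessel axis.

Each scene also records its ground truth (true centerlines, enrichment
segments, anchor measurements, NFT link) so recovery tests can compare the
pipeline's estimates against construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .geometry import assign_along_distance, compute_distance_field
from .io import ImageVolume, write_object_table, write_volume
from .normalization import NormalizationAnchors, piecewise_linear_normalize

UM3_PER_MM3 = 1e9


@dataclass
class VesselSpec:
    """A synthetic vessel: a continuous path swept by a circular cross-section."""

    path_kind: str = "straight"  # straight | arc | helix
    length_um: float = 90.0
    radius_um: float = 6.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    curvature_radius_um: float | None = None  # arc
    helix_radius_um: float | None = None  # helix
    helix_pitch_um: float | None = None  # helix
    flat_caps: bool = True  # truncate at the path ends, like a traced mask

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.length_um <= 0:
            raise ValueError("radius_um and length_um must be > 0")
        if self.path_kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        self.origin = tuple(float(v) for v in self.origin)
        self.direction = tuple(float(v) for v in self.direction)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


def vessel_path(spec: VesselSpec, step_um: float = 0.25) -> np.ndarray:
    """Arc-length parameterized samples of the continuous vessel path (um)."""
    n = max(2, int(np.ceil(spec.length_um / step_um)) + 1)
    t = np.linspace(0.0, spec.length_um, n)
    origin = np.asarray(spec.origin, dtype=float)
    a = _unit(spec.direction)
    if spec.path_kind == "straight":
        return origin[None, :] + t[:, None] * a[None, :]
    u, v = _perp_basis(a)
    if spec.path_kind == "arc":
        if not spec.curvature_radius_um or spec.curvature_radius_um <= 0:
            raise ValueError("arc path needs curvature_radius_um > 0")
        R = spec.curvature_radius_um
        phi = t / R
        return (
            origin[None, :]
            + R * np.sin(phi)[:, None] * a[None, :]
            + R * (1.0 - np.cos(phi))[:, None] * u[None, :]
        )
    # helix
    if not spec.helix_radius_um or spec.helix_radius_um <= 0:
        raise ValueError("helix path needs helix_radius_um > 0")
    if not spec.helix_pitch_um or spec.helix_pitch_um <= 0:
        raise ValueError("helix path needs helix_pitch_um > 0")
    rh, pitch = spec.helix_radius_um, spec.helix_pitch_um
    arc_per_turn = np.hypot(2 * np.pi * rh, pitch)
    theta = 2 * np.pi * t / arc_per_turn
    z = pitch * t / arc_per_turn
    return (
        origin[None, :]
        + z[:, None] * a[None, :]
        + rh * (np.cos(theta) - 1.0)[:, None] * u[None, :]
        + rh * np.sin(theta)[:, None] * v[None, :]
    )


def generate_vessel(
    spec: VesselSpec, shape, spacing, path_step_um: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one vessel: (path points at <=1 um steps, binary mask).

    A voxel belongs to the mask iff its sample position lies within
    ``radius_um`` of the continuous path; with ``spec.flat_caps`` the tube is
    additionally truncated at the two path-end planes, the way a manually
    traced mask ends where tracing stops. The whole tube must fit inside the
    volume.
    """
    shape = np.asarray(shape, dtype=int)
    spacing = np.asarray(spacing, dtype=float)
    extent = (shape - 1) * spacing
    path = vessel_path(spec, path_step_um)
    r = spec.radius_um
    if np.any(path - r < -1e-9) or np.any(path + r > extent + 1e-9):
        raise ValueError("vessel path (plus radius) exits the volume")
    lo = np.maximum(np.floor((path.min(axis=0) - r) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((path.max(axis=0) + r) / spacing).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    pos = idx * spacing
    tree = cKDTree(path)
    d, near = tree.query(pos)
    mask = np.zeros(tuple(shape), dtype=bool)
    inside = d <= r + 1e-9
    if spec.flat_caps:
        t0 = _unit(path[1] - path[0])
        t1 = _unit(path[-1] - path[-2])
        behind = (near == 0) & ((pos - path[0]) @ t0 < -1e-9)
        beyond = (near == len(path) - 1) & ((pos - path[-1]) @ t1 > 1e-9)
        inside &= ~(behind | beyond)
    sel = idx[inside]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    # path resampled at <= 1 um for downstream use
    keep = max(1, int(round(1.0 / path_step_um)))
    coarse = path[::keep]
    if not np.array_equal(coarse[-1], path[-1]):
        coarse = np.vstack([coarse, path[-1]])
    return coarse, mask


@dataclass
class SceneSpec:
    """Full specification of one synthetic scene (one donor image)."""

    shape: tuple[int, int, int] = (64, 64, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    vessels: list[VesselSpec] = field(
        default_factory=lambda: [
            VesselSpec(origin=(16.0, 16.0, 10.0), length_um=75.0, radius_um=6.0),
            VesselSpec(origin=(48.0, 48.0, 10.0), length_um=75.0, radius_um=8.0),
        ]
    )
    tau_bg_mean: float = 100.0
    tau_bg_sd: float = 10.0
    tau_auto_mean: float = 160.0
    tau_auto_sd: float = 15.0
    tau_pos_mean: float = 400.0
    autofluor_fraction: float = 0.2
    autofluor_scale_um: float = 1.5  # lipofuscin-like granular speckle
    # per-vessel-index list of (arc_start_um, arc_end_um, amplitude, decay_length_um)
    enrichment_segments: dict[int, list[tuple[float, float, float, float]]] = field(
        default_factory=lambda: {0: [(35.0, 55.0, 300.0, 10.0)]}
    )
    neuron_rate_per_mm3: float = 100000.0
    nft_base_prob: float = 0.05
    nft_slope: float = 0.25
    layer_boundaries_um: tuple[float, ...] = (16.0, 32.0, 48.0, 64.0, 80.0)
    layer_axis: int = 2
    gain: float = 1.0  # per-donor affine intensity distortion
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_bg_mean < self.tau_auto_mean < self.tau_pos_mean):
            raise ValueError("need tau_bg_mean < tau_auto_mean < tau_pos_mean")
        if not (0.0 <= self.nft_base_prob <= 1.0):
            raise ValueError("nft_base_prob must be in [0, 1]")
        for segs in self.enrichment_segments.values():
            for s0, s1, amp, decay in segs:
                if amp < 0:
                    raise ValueError("enrichment amplitude must be >= 0")
                if decay <= 0:
                    raise ValueError("decay_length_um must be > 0")
                if s1 <= s0:
                    raise ValueError("enrichment segment must have s1 > s0")
        if self.neuron_rate_per_mm3 < 0:
            raise ValueError("neuron_rate_per_mm3 must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vessels"] = [dataclasses.asdict(v) for v in self.vessels]
        d["enrichment_segments"] = {
            str(k): [list(seg) for seg in v] for k, v in self.enrichment_segments.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["vessels"] = [VesselSpec(**v) for v in d.get("vessels", [])]
        d["enrichment_segments"] = {
            int(k): [tuple(seg) for seg in v]
            for k, v in d.get("enrichment_segments", {}).items()
        }
        for key in ("shape", "spacing", "layer_boundaries_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Scene:
    """In-memory scene bundle."""

    spec: SceneSpec
    tau: ImageVolume  # raw (per-donor affine applied)
    layers: ImageVolume
    masks: list[np.ndarray]
    paths: list[np.ndarray]  # true centerlines, um, <=1 um steps
    distance_fields: list[np.ndarray]
    objects: pd.DataFrame
    anchors: NormalizationAnchors
    anchor_sites: dict
    truth: dict


def _layer_volume(spec: SceneSpec) -> ImageVolume:
    shape = tuple(spec.shape)
    axis_coords = np.arange(shape[spec.layer_axis]) * spec.spacing[spec.layer_axis]
    labels_1d = 1 + np.searchsorted(np.asarray(spec.layer_boundaries_um), axis_coords,
                                    side="right")
    reshape = [1, 1, 1]
    reshape[spec.layer_axis] = -1
    labels = np.broadcast_to(labels_1d.reshape(reshape), shape).astype(np.int16)
    return ImageVolume(np.ascontiguousarray(labels), spec.spacing, channel="layers")


def _true_surface_scores(
    spec: SceneSpec,
    enrich_at: callable,
    dfields: list[np.ndarray],
    s_fields: list[np.ndarray],
    config: PipelineConfig,
    anchors: NormalizationAnchors,
) -> dict[int, np.ndarray]:
    """Per-vessel per-bin normalized surface tau, from the noise-free field."""
    scores: dict[int, np.ndarray] = {}
    for vi, vspec in enumerate(spec.vessels):
        nb = max(1, int(np.ceil(vspec.length_um / config.bin_length_um - 1e-9)))
        d = dfields[vi]
        s = s_fields[vi]
        surf = d <= config.surface_window_um
        ideal = spec.tau_bg_mean + enrich_at(vi, d, s)
        raw = spec.offset + spec.gain * ideal
        norm = piecewise_linear_normalize(raw, anchors)
        k = np.clip((s[surf] / config.bin_length_um).astype(int), 0, nb - 1)
        sums = np.bincount(k, weights=norm[surf], minlength=nb)
        counts = np.bincount(k, minlength=nb)
        with np.errstate(invalid="ignore"):
            scores[vi] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return scores


def generate_scene(
    spec: SceneSpec, config: PipelineConfig | None = None
) -> Scene:
    """Build a full scene: vessels, tau field, layers, objects, ground truth.

    Deterministic given ``spec`` (including its seed).
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    voxvol_mm3 = float(np.prod(spacing)) / UM3_PER_MM3

    paths, masks, dfields, s_fields = [], [], [], []
    for vspec in spec.vessels:
        path, mask = generate_vessel(vspec, shape, spacing)
        paths.append(path)
        masks.append(mask)
        dfields.append(compute_distance_field(mask, spacing))
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        s_path = np.concatenate([[0.0], np.cumsum(seg)])
        idx = np.indices(shape).reshape(3, -1).T
        pos = idx * spacing
        s_vox = assign_along_distance(pos, path, s_path).reshape(shape)
        s_fields.append(s_vox)

    # ---- tau field: background + autofluorescence blotches + enrichment
    base = rng.normal(spec.tau_bg_mean, spec.tau_bg_sd, size=shape)
    lowfreq = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=shape), sigma=spec.autofluor_scale_um / spacing
    )
    thresh = np.quantile(lowfreq, 1.0 - spec.autofluor_fraction)
    blotch = lowfreq > thresh
    extra_sd = np.sqrt(max(spec.tau_auto_sd**2 - spec.tau_bg_sd**2, 0.0))
    base[blotch] += (spec.tau_auto_mean - spec.tau_bg_mean) + rng.normal(
        0.0, extra_sd, size=int(blotch.sum())
    )

    def enrich_at(vi: int, d: np.ndarray, s: np.ndarray) -> np.ndarray:
        total = np.zeros_like(d)
        for s0, s1, amp, decay in spec.enrichment_segments.get(vi, []):
            in_seg = (s >= s0) & (s < s1)
            total += np.where(in_seg, amp * np.exp(-d / decay), 0.0)
        return total

    enrich = np.zeros(shape)
    for vi in range(len(spec.vessels)):
        enrich += enrich_at(vi, dfields[vi], s_fields[vi])

    ideal = base + enrich
    raw = np.clip(spec.offset + spec.gain * ideal, 0.0, None)
    tau = ImageVolume(raw, tuple(spacing), channel="tau")
    layers = _layer_volume(spec)

    # ---- anchor measurements (operator-style: 3 depths x 10 sites/category)
    anchors, anchor_sites = _collect_scene_anchors(
        spec, raw, blotch, enrich, dfields, rng
    )

    # ---- objects: Poisson neurons, NFT flag via the clamped linear link
    any_mask = np.zeros(shape, dtype=bool)
    for m in masks:
        any_mask |= m
    tissue_idx = np.argwhere(~any_mask)
    tissue_mm3 = len(tissue_idx) * voxvol_mm3
    n_neurons = int(rng.poisson(spec.neuron_rate_per_mm3 * tissue_mm3))
    scores = _true_surface_scores(spec, enrich_at, dfields, s_fields, config, anchors)
    obj_rows = []
    if n_neurons > 0:
        pick = rng.integers(0, len(tissue_idx), size=n_neurons)
        jitter = rng.uniform(0.0, 0.5, size=(n_neurons, 3)) * spacing
        pos = tissue_idx[pick] * spacing + jitter
        # keep positions outside vessel lumina after jitter
        near = np.rint(pos / spacing).astype(int)
        near = np.clip(near, 0, np.asarray(shape) - 1)
        in_lumen = any_mask[near[:, 0], near[:, 1], near[:, 2]]
        pos[in_lumen] = tissue_idx[pick[in_lumen]] * spacing
        dist_all = np.stack(
            [dfields[vi][tissue_idx[pick][:, 0], tissue_idx[pick][:, 1],
                         tissue_idx[pick][:, 2]] for vi in range(len(spec.vessels))],
            axis=1,
        )
        nearest = np.argmin(dist_all, axis=1)
        d_near = dist_all[np.arange(n_neurons), nearest]
        score = np.zeros(n_neurons)
        for i in range(n_neurons):
            if d_near[i] <= config.shell_max_um:
                vi = int(nearest[i])
                s_val = s_fields[vi][tuple(tissue_idx[pick[i]])]
                nb = len(scores[vi])
                k = min(int(s_val / config.bin_length_um), nb - 1)
                val = scores[vi][k]
                score[i] = 0.0 if np.isnan(val) else val
        p_nft = np.clip(spec.nft_base_prob + spec.nft_slope * score, 0.0, 1.0)
        has_nft = rng.random(n_neurons) < p_nft
        oid = 0
        for i in range(n_neurons):
            obj_rows.append(
                {"id": oid, "x_um": pos[i, 0], "y_um": pos[i, 1], "z_um": pos[i, 2],
                 "class": "neuron"}
            )
            oid += 1
        for i in np.flatnonzero(has_nft):
            off = rng.normal(0.0, 0.8, size=3)  # NFT sits on/inside the soma
            obj_rows.append(
                {"id": oid, "x_um": pos[i, 0] + off[0], "y_um": pos[i, 1] + off[1],
                 "z_um": pos[i, 2] + off[2], "class": "nft"}
            )
            oid += 1
    objects = pd.DataFrame(
        obj_rows, columns=["id", "x_um", "y_um", "z_um", "class"]
    )

    truth = {
        "seed": spec.seed,
        "gain": spec.gain,
        "offset": spec.offset,
        "centerlines": [p.tolist() for p in paths],
        "vessel_lengths_um": [float(v.length_um) for v in spec.vessels],
        "vessel_radii_um": [float(v.radius_um) for v in spec.vessels],
        "enrichment_segments": {
            str(k): [list(seg) for seg in v]
            for k, v in spec.enrichment_segments.items()
        },
        "nft_model": {"base_prob": spec.nft_base_prob, "slope": spec.nft_slope},
        "neuron_rate_per_mm3": spec.neuron_rate_per_mm3,
        "n_neurons": int((objects["class"] == "neuron").sum()),
        "anchors": anchors.to_dict(),
        "true_surface_scores": {str(k): v.tolist() for k, v in scores.items()},
    }
    return Scene(
        spec=spec, tau=tau, layers=layers, masks=masks, paths=paths,
        distance_fields=dfields, objects=objects, anchors=anchors,
        anchor_sites=anchor_sites, truth=truth,
    )


def _collect_scene_anchors(
    spec: SceneSpec,
    raw: np.ndarray,
    blotch: np.ndarray,
    enrich: np.ndarray,
    dfields: list[np.ndarray],
    rng: np.random.Generator,
    n_per_depth: int = 10,
) -> tuple[NormalizationAnchors, dict]:
    """Emulate the operator's anchor protocol on ground-truth regime masks.

    Background and autofluorescence sites come from the true regime masks at
    3 z-depths. Positive sites come from enriched surface voxels when the
    scene has them; a scene without positivity (e.g. a control donor) uses
    calibration values drawn from the nominal positive regime under the
    donor's affine distortion, standing in for the operator's reference.
    """
    shape = raw.shape
    # regimes tolerate enrichment well below the noise floor
    floor = 0.2 * spec.tau_bg_sd
    clean_bg = ~blotch & (enrich < floor)
    auto_reg = blotch & (enrich < floor)
    pos_reg = enrich >= 0.5 * max(
        [seg[2] for segs in spec.enrichment_segments.values() for seg in segs],
        default=np.inf,
    )
    depths = [int(round(f * (shape[2] - 1))) for f in (0.25, 0.5, 0.75)]
    sites: dict[str, list] = {"background": [], "autofluorescence": [], "positive": []}
    raw_vals: dict[str, list] = {"background": [], "autofluorescence": [], "positive": []}
    for cat, region in (("background", clean_bg), ("autofluorescence", auto_reg),
                        ("positive", pos_reg)):
        for zi, z in enumerate(depths):
            zz = z
            cand = np.argwhere(region[:, :, zz])
            # walk nearby planes if this one lacks candidates
            dz = 1
            while len(cand) == 0 and (zz - dz >= 0 or zz + dz < shape[2]):
                for alt in (zz - dz, zz + dz):
                    if 0 <= alt < shape[2]:
                        cand = np.argwhere(region[:, :, alt])
                        if len(cand):
                            zz = alt
                            break
                dz += 1
            if len(cand) == 0:
                continue
            pick = cand[rng.integers(0, len(cand), size=n_per_depth)]
            for ij in pick:
                sites[cat].append((int(ij[0]), int(ij[1]), int(zz)))
                raw_vals[cat].append(float(raw[ij[0], ij[1], zz]))
        # fake distinct depths if the walk collapsed them (rare tiny scenes)
    if len(raw_vals["positive"]) == 0:
        # control donor: operator-supplied positive calibration values
        vals = spec.offset + spec.gain * rng.normal(
            spec.tau_pos_mean, spec.tau_bg_sd, size=3 * n_per_depth
        )
        raw_vals["positive"] = [float(v) for v in vals]
        sites["positive"] = []
    anchors = NormalizationAnchors.from_raw(raw_vals)
    return anchors, sites


def write_scene(scene: Scene, outdir: str | Path) -> Path:
    """Write the scene bundle: volumes, masks, objects, spec, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(scene.tau, outdir / "tau.tif")
    write_volume(scene.layers, outdir / "layers.tif")
    for vi, mask in enumerate(scene.masks):
        write_volume(
            ImageVolume(mask.astype(np.uint8), scene.tau.spacing, channel="vessel"),
            outdir / f"vessel_{vi:02d}_mask.h5",
        )
    write_object_table(scene.objects, outdir / "objects.csv")
    (outdir / "scene_spec.json").write_text(json.dumps(scene.spec.to_dict(), indent=2))
    (outdir / "truth.json").write_text(json.dumps(scene.truth, indent=2))
    return outdir


def load_scene_spec(path: str | Path) -> SceneSpec:
    return SceneSpec.from_dict(json.loads(Path(path).read_text()))
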