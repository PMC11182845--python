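"""Per-vessel geometry: surface distance field, centerline, and diameter.

A vessel arrives as a binary mask on the image grid. Three quantities drive
everything downstream:

* the **surface distance field** ``d(v)``: for each voxel, the Euclidean
  distance (um, anisotropy-aware) to the nearest mask voxel, 0 inside the
  mask — distance inside the vessel is defined as 0 (surface and lumen),
  so a 3 um surface window captures the mask plus the first 3 um of
  abluminal tissue;
* the **centerline**: an ordered polyline of um points with cumulative arc
  length ``s`` (s = 0 at the endpoint whose world coordinate tuple is
  lexicographically smaller, making orientation deterministic);
* the **diameter**: maximal cross-sectional chord averaged over a few
  centerline sites.

The centerline is the longest geodesic path through the 3D skeleton of the
mask (spur branches fall away automatically), smoothed with a short moving
average, resampled at <=1 um steps, and extended along the end tangents to
undo the end retraction intrinsic to topological thinning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VesselModel:
    """Geometry bundle for one vessel."""

    vessel_id: int
    mask: np.ndarray
    spacing: tuple[float, float, float]
    centerline: np.ndarray  # (n, 3) um points
    arclength: np.ndarray  # (n,) cumulative um, strictly increasing
    distance_field: np.ndarray  # um, 0 on mask
    diameter_um: float

    @property
    def length_um(self) -> float:
        return float(self.arclength[-1])


def compute_distance_field(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (um) from each voxel to the nearest mask voxel.

    Zero inside the mask; anisotropic spacing is honoured via the EDT
    sampling argument.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty vessel mask")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> tuple[nx.Graph, np.ndarray]:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # half the 26-neighbourhood avoids duplicates
    ]
    for off in offsets:
        shifted = coords + off
        w = float(np.linalg.norm(np.asarray(off) * spacing))
        for a, b in zip(coords, shifted):
            j = index.get(tuple(b))
            if j is not None:
                g.add_edge(index[tuple(a)], j, weight=w)
    return g, coords


def _longest_geodesic(g: nx.Graph) -> list[int]:
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) >= 2 and len(endpoints) <= 64:
        best, best_len = None, -1.0
        for src in endpoints:
            lengths, paths = nx.single_source_dijkstra(g, src, weight="weight")
            for dst in endpoints:
                if dst != src and lengths.get(dst, -1.0) > best_len:
                    best_len = lengths[dst]
                    best = paths[dst]
        if best is not None:
            return best
    # degenerate skeleton (loop / many endpoints): double Dijkstra sweep
    src = next(iter(g.nodes))
    lengths = nx.single_source_dijkstra_path_length(g, src, weight="weight")
    far = max(lengths, key=lengths.get)
    lengths, paths = nx.single_source_dijkstra(g, far, weight="weight")
    far2 = max(lengths, key=lengths.get)
    return paths[far2]


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(points, dtype=float)
    n = len(points)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def _resample(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(2, int(np.ceil(total / step)) + 1)
    s_new = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(s_new, s, points[:, ax]) for ax in range(3)])


def _inside_mask(p: np.ndarray, mask: np.ndarray, spacing: np.ndarray) -> bool:
    idx = np.rint(p / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return False
    return bool(mask[tuple(idx)])


def _extend_end(points: np.ndarray, mask: np.ndarray, spacing: np.ndarray,
                at_start: bool, max_extend_um: float = 30.0) -> np.ndarray:
    """March along the end tangent while still inside the mask."""
    if at_start:
        p, q = points[0], points[min(4, len(points) - 1)]
    else:
        p, q = points[-1], points[-min(5, len(points))]
    tangent = p - q
    norm = np.linalg.norm(tangent)
    if norm < 1e-9:
        return points
    tangent /= norm
    step = 0.5 * float(min(spacing))
    extra = []
    pos = p.copy()
    for _ in range(int(max_extend_um / step)):
        nxt = pos + step * tangent
        if not _inside_mask(nxt, mask, spacing):
            break
        extra.append(nxt)
        pos = nxt
    if not extra:
        return points
    extra_arr = np.asarray(extra)
    if at_start:
        return np.vstack([extra_arr[::-1], points])
    return np.vstack([points, extra_arr])


def extract_centerline(
    mask: np.ndarray,
    spacing,
    *,
    smooth_window: int = 5,
    step_um: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the centerline polyline and its cumulative arc length.

    Returns ``(points, s)`` with points in um world coordinates sampled at
    <= ``step_um`` intervals and ``s`` strictly increasing from 0.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        raise ValueError("empty vessel mask")
    _, n_comp = ndimage.label(mask, structure=_STRUCT26)
    if n_comp != 1:
        raise ValueError(f"vessel mask has {n_comp} connected components, expected 1")
    skel = skeletonize(mask)
    if not skel.any():
        # a mask thinner than the thinning kernel can vanish; fall back to the
        # mask voxels themselves (tiny vessels in tests)
        skel = mask
    g, coords = _skeleton_graph(skel, spacing)
    path_idx = _longest_geodesic(g)
    points = coords[path_idx].astype(float) * spacing
    if len(points) < 2:
        raise ValueError("skeleton reduced to a point; mask too small for a centerline")
    points = _moving_average(points, smooth_window)
    points = _resample(points, step_um)
    points = _extend_end(points, mask, spacing, at_start=True)
    points = _extend_end(points, mask, spacing, at_start=False)
    points = _resample(points, step_um)
    if tuple(points[0]) > tuple(points[-1]):
        points = points[::-1]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    points = points[keep]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    return points, s


def assign_along_distance(
    points: np.ndarray, centerline: np.ndarray, arclength: np.ndarray
) -> np.ndarray:
    """Arc-length coordinate of the nearest centerline vertex for each point.

    Points are um world positions (anisotropy already absorbed). Ties between
    equidistant vertices break toward the smaller arc length.
    """
    if len(centerline) == 0:
        raise ValueError("empty centerline")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(centerline)
    if len(centerline) == 1:
        return np.zeros(len(points)) + arclength[0]
    d, idx = tree.query(points, k=2)
    nearest = idx[:, 0].copy()
    tied = d[:, 1] - d[:, 0] <= 1e-9
    if tied.any():
        # re-resolve exact ties toward the smallest arc length (= smallest index)
        for i in np.flatnonzero(tied):
            cand = tree.query_ball_point(points[i], d[i, 0] + 1e-9)
            nearest[i] = min(cand)
    return arclength[nearest]


def measure_diameter(
    mask: np.ndarray,
    spacing,
    centerline: np.ndarray,
    arclength: np.ndarray,
    n_sites: int = 3,
    n_angles: int = 24,
) -> float:
    """Vessel diameter: mean over ``n_sites`` centerline sites of the maximal
    chord across the local cross-section (perpendicular to the tangent).

    Sites sit at evenly spaced arc-length fractions (25/50/75% for 3 sites).
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if len(centerline) < 3:
        raise ValueError("centerline too short to measure a diameter")
    total = arclength[-1]
    fractions = [(i + 1) / (n_sites + 1) for i in range(n_sites)]
    step = 0.25 * float(min(spacing))
    max_march = int(np.ceil(np.linalg.norm(np.asarray(mask.shape) * spacing) / step))
    diameters = []
    for frac in fractions:
        s_target = frac * total
        k = int(np.searchsorted(arclength, s_target))
        k = min(max(k, 1), len(centerline) - 2)
        tangent = centerline[k + 1] - centerline[k - 1]
        norm = np.linalg.norm(tangent)
        if norm < 1e-9:
            continue  # degenerate tangent: skip site
        tangent /= norm
        # orthonormal basis of the cross-sectional plane
        ref = np.array([1.0, 0.0, 0.0])
        if abs(tangent @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(tangent, ref)
        u /= np.linalg.norm(u)
        v = np.cross(tangent, u)
        p0 = centerline[k]
        best = 0.0
        for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
            direction = np.cos(theta) * u + np.sin(theta) * v
            chord = 0.0
            for sign in (1.0, -1.0):
                t = step
                while t < max_march * step:
                    if not _inside_mask(p0 + sign * t * direction, mask, spacing):
                        break
                    t += step
                chord += t - step
            best = max(best, chord)
        diameters.append(best)
    if not diameters:
        raise ValueError("all diameter sites degenerate")
    return float(np.mean(diameters))


def build_vessel_model(
    mask: np.ndarray, spacing, vessel_id: int = 0
) -> VesselModel:
    """Convenience: distance field + centerline + diameter for one mask."""
    centerline, s = extract_centerline(mask, spacing)
    return VesselModel(
        vessel_id=vessel_id,
        mask=np.asarray(mask, dtype=bool),
        spacing=tuple(float(x) for x in spacing),
        centerline=centerline,
        arclength=s,
        distance_field=compute_distance_field(mask, spacing),
        diameter_um=measure_diameter(mask, spacing, centerline, s),
    )


def save_vessel_model(model: VesselModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vid = model.vessel_id
    with h5py.File(outdir / f"vessel_{vid:02d}_distance.h5", "w") as f:
        d = f.create_dataset("data", data=model.distance_field)
        d.attrs["spacing"] = model.spacing
        d.attrs["channel"] = "distance"
        m = f.create_dataset("mask", data=model.mask.astype(np.uint8))
        m.attrs["spacing"] = model.spacing
    pd.DataFrame(
        {
            "x_um": model.centerline[:, 0],
            "y_um": model.centerline[:, 1],
            "z_um": model.centerline[:, 2],
            "s_um": model.arclength,
        }
    ).to_csv(outdir / f"vessel_{vid:02d}_centerline.csv", index=False)
    (outdir / f"vessel_{vid:02d}_geometry.json").write_text(
        json.dumps(
            {
                "vessel_id": vid,
                "diameter_um": model.diameter_um,
                "length_um": model.length_um,
                "mask_voxels": int(model.mask.sum()),
            },
            indent=2,
        )
    )


def load_vessel_model(outdir: str | Path, vessel_id: int) -> VesselModel:
    outdir = Path(outdir)
    with h5py.File(outdir / f"vessel_{vessel_id:02d}_distance.h5", "r") as f:
        distance = f["data"][()]
        spacing = tuple(float(s) for s in f["data"].attrs["spacing"])
        mask = f["mask"][()].astype(bool)
    cl = pd.read_csv(outdir / f"vessel_{vessel_id:02d}_centerline.csv")
    geom = json.loads((outdir / f"vessel_{vessel_id:02d}_geometry.json").read_text())
    return VesselModel(
        vessel_id=vessel_id,
        mask=mask,
        spacing=spacing,
        centerline=cl[["x_um", "y_um", "z_um"]].to_numpy(),
        arclength=cl["s_um"].to_numpy(),
        distance_field=distance,
        diameter_um=float(geom["diameter_um"]),
    )
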