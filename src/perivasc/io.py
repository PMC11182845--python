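"""Readers and writers for the formats the pipeline touches.

Volumes are 3D scalar grids carried as :class:`ImageVolume` with per-axis
voxel spacing in micrometres. Two on-disk formats are supported:

* multi-page TIFF, one page per z-plane, with a JSON sidecar (same stem,
  ``.json`` extension) holding ``spacing`` and ``channel``;
* HDF5 with a single 3D dataset ``data`` carrying ``spacing`` and ``channel``
  attributes.

In memory the axis order is always (x, y, z), z being the TIFF page index.
The world position of voxel (i, j, k) is (i*sx, j*sy, k*sz) um.

Object tables (segmented neurons / NFTs) are CSV with columns
``id, x_um, y_um, z_um, class`` where class is ``neuron`` or ``nft``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

OBJECT_CLASSES = ("neuron", "nft")
OBJECT_COLUMNS = ["id", "x_um", "y_um", "z_um", "class"]


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and a channel tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim} axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.channel == "layers":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("layer volume must be integer-typed")
            if self.data.min() < 0:
                raise ValueError("layer labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_positions_um(self, indices: np.ndarray) -> np.ndarray:
        """World positions (um) of an (n, 3) array of voxel indices."""
        return np.asarray(indices, dtype=float) * np.asarray(self.spacing)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(
    path: str | Path,
    channel: str | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> ImageVolume:
    """Read a volume from multi-page TIFF or HDF5.

    For TIFF, spacing must come from the JSON sidecar or the ``spacing``
    argument; for HDF5 it may also come from dataset attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "data" in f:
                dset = f["data"]
            else:
                candidates = [k for k in f if isinstance(f[k], h5py.Dataset)]
                if len(candidates) != 1:
                    raise ValueError(f"{path}: expected one dataset, found {candidates}")
                dset = f[candidates[0]]
            if dset.ndim != 3:
                raise ValueError(f"{path}: dataset is {dset.ndim}D, need a 3D dataset")
            data = dset[()]
            if spacing is None and "spacing" in dset.attrs:
                spacing = tuple(float(s) for s in dset.attrs["spacing"])
            if channel is None and "channel" in dset.attrs:
                channel = str(dset.attrs["channel"])
    elif suffix in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            raise ValueError(f"{path}: single-page TIFF is 2D, need a z-stack")
        if pages.ndim != 3:
            raise ValueError(f"{path}: TIFF has {pages.ndim} axes, need 3")
        # tifffile yields (z, y, x); normalize to (x, y, z)
        data = np.ascontiguousarray(pages.transpose(2, 1, 0))
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if spacing is None and "spacing" in meta:
                spacing = tuple(float(s) for s in meta["spacing"])
            if channel is None and "channel" in meta:
                channel = str(meta["channel"])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if spacing is None:
        raise ValueError(f"{path}: spacing unknown (no metadata and no sidecar)")
    return ImageVolume(data=data, spacing=spacing, channel=channel or "")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (+ sidecar) or HDF5, by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=volume.data)
            dset.attrs["spacing"] = volume.spacing
            dset.attrs["channel"] = volume.channel
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            np.ascontiguousarray(volume.data.transpose(2, 1, 0)),
            photometric="minisblack",
        )
        _sidecar_path(path).write_text(
            json.dumps({"spacing": list(volume.spacing), "channel": volume.channel})
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_object_table(path: str | Path) -> pd.DataFrame:
    """Read a segmented-object table (CSV).

    Returns a DataFrame with columns ``id, x_um, y_um, z_um, class``;
    vessel-relative columns are attached later by the density stage.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["class"].isin(OBJECT_CLASSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row} has unknown class {df['class'].iloc[row]!r}; "
            f"allowed: {OBJECT_CLASSES}"
        )
    return df[OBJECT_COLUMNS].copy()


def write_object_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Record of one pipeline stage run: config, seed, input hashes, outputs."""

    stage: str
    config: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_input(self, name: str, path: str | Path) -> None:
        self.inputs[name] = {"path": str(path), "sha256": file_sha256(path)}

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(
                {
                    "stage": self.stage,
                    "config": self.config,
                    "seed": self.seed,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                },
                indent=2,
            )
        )
        return path
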