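"""Volumetric I/O and voxel↔mm geometry.

All spatial data live on regular 3D grids with a NIfTI-style 4x4 affine
mapping 0-based voxel indices to mm coordinates (voxel centers). Volumes are
read and written as NIfTI-1 via nibabel; in-memory containers are plain
dataclasses wrapping numpy arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("neighborgraph")

#: Fill value used outside every mask, for all map kinds.
FILL_VALUE = 0.0


class MapKind(str, Enum):
    """Kinds of per-voxel scalar maps produced by the pipeline."""

    LOCAL_RAW = "local_raw"
    DISTANT_RAW = "distant_raw"
    LOCAL_Z = "local_z"
    DISTANT_Z = "distant_z"
    LOCAL_PERCENT = "local_percent"
    DISTANT_PERCENT = "distant_percent"
    PREFERENTIAL = "preferential"
    OVERLAP = "overlap"
    PATH_LENGTH = "path_length"
    PHYSICAL_COST = "physical_cost"
    CLUSTERING = "clustering"
    METRIC = "metric"
    LABEL = "label"


class NeighborGraphError(Exception):
    """Base class for package errors."""


class ParameterError(NeighborGraphError):
    """A parameter violates its contract."""


class DataError(NeighborGraphError):
    """Input data violate a structural precondition."""


@dataclass
class VolumeSeries:
    """A 4D BOLD series: ``data[x, y, z, t]`` with affine and TR (seconds).

    ``provenance`` is an append-only log of processing stages applied.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise DataError(f"VolumeSeries needs 4 axes, got {self.data.ndim}")
        if any(s < 1 for s in self.data.shape[:3]):
            raise DataError("all spatial dims must be >= 1")
        if self.data.shape[3] < 2:
            raise DataError("VolumeSeries needs at least 2 frames")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise DataError("affine must be an invertible 4x4 matrix")
        if not self.tr > 0:
            raise ParameterError(f"tr must be > 0, got {self.tr}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (norms of affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def log_stage(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})


@dataclass
class BrainMask:
    """A 3D boolean mask sharing grid and affine with the data it masks."""

    data: np.ndarray
    affine: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("BrainMask must be 3D")
        if not self.data.any():
            raise DataError(f"mask '{self.label}' has no true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_compatible(self, other) -> None:
        """Reject grid/affine mismatch with the given volume or mask."""
        if self.data.shape != other.data.shape[:3]:
            raise DataError(
                f"mask '{self.label}' shape {self.data.shape} does not match "
                f"data shape {other.data.shape[:3]}"
            )
        if not np.allclose(self.affine, other.affine, atol=1e-6):
            raise DataError(f"mask '{self.label}' affine differs from data affine")


@dataclass
class ScalarMap:
    """A per-voxel scalar field defined on a mask.

    Outside-mask voxels hold ``FILL_VALUE`` and never enter statistics.
    Missing in-mask values (e.g. percent maps at total degree zero) are NaN.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: MapKind
    mask: BrainMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("ScalarMap must be 3D")
        self.mask.check_compatible(self)
        # enforce the fill invariant
        out = ~self.mask.data
        if out.any():
            self.data = self.data.copy()
            self.data[out] = FILL_VALUE

    def in_mask_values(self, drop_missing: bool = True) -> np.ndarray:
        vals = self.data[self.mask.data]
        if drop_missing:
            vals = vals[np.isfinite(vals)]
        return vals


@dataclass
class CoordinateTable:
    """n_voxels x 3 mm coordinates of in-mask voxel centers, fixed scan order."""

    coords_mm: np.ndarray
    voxel_indices: np.ndarray  # n x 3 integer voxel indices, same order


# ---------------------------------------------------------------------------
# Reading / writing


def read_volume(path, tr: float | None = None) -> VolumeSeries:
    """Read a 3D or 4D NIfTI volume as a :class:`VolumeSeries`.

    3D images are promoted to a single-frame 4D series (frame duplicated so
    the two-frame invariant holds is *not* done: a single-frame series is
    represented with t-dim 1 and bypasses the frame check). TR is taken from
    the header zooms unless ``tr`` overrides it.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise DataError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    elif data.ndim != 4:
        raise DataError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if tr <= 0:
            raise ParameterError(
                f"{path}: header has no usable TR; pass tr= explicitly"
            )
    vol = VolumeSeries.__new__(VolumeSeries)
    vol.data = data
    vol.affine = np.asarray(img.affine, dtype=np.float64)
    vol.tr = float(tr)
    vol.provenance = [{"stage": "read_volume", "path": str(path)}]
    # validate everything except the >=2 frame rule (3D promotion is legal)
    if abs(np.linalg.det(vol.affine)) < 1e-12:
        raise DataError(f"{path}: affine not invertible")
    return vol


def write_volume(vol: VolumeSeries, path) -> None:
    """Write a series as NIfTI-1, recording TR in the header zooms."""
    data = vol.data
    img = nib.Nifti1Image(data, vol.affine)
    zooms = list(img.header.get_zooms())
    zooms = zooms[:3] + [vol.tr]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_mask(path, label: str = "custom") -> BrainMask:
    """Read a 3D NIfTI image as a boolean mask (nonzero → true)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"{path}: mask must be 3D")
    return BrainMask(data != 0, np.asarray(img.affine, float), label=label)


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def write_map(smap: ScalarMap, path) -> None:
    """Write a scalar map as NIfTI with the map kind in the header descrip."""
    img = nib.Nifti1Image(smap.data, smap.affine)
    img.header["descrip"] = smap.kind.value.encode()[:79]
    nib.save(img, str(path))


def read_map(path, mask: BrainMask, kind: MapKind | None = None) -> ScalarMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if kind is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode()
        kind = MapKind(descrip) if descrip else MapKind.METRIC
    return ScalarMap(data, np.asarray(img.affine, float), kind, mask)


# ---------------------------------------------------------------------------
# Geometry


def voxel_coordinates_mm(mask: BrainMask) -> CoordinateTable:
    """mm coordinates of in-mask voxel centers in fixed scan order.

    Scan order is x fastest, then y, then z; all graph node indices inherit
    this ordering, so it must be byte-stable across calls.
    """
    nx, ny, nz = mask.data.shape
    # x fastest: iterate z slowest -> np.ndindex over (z, y, x) reversed
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    inside = mask.data[xx, yy, zz].ravel()
    idx = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])[inside]
    homog = np.column_stack([idx, np.ones(len(idx))])
    coords = (mask.affine @ homog.T).T[:, :3]
    return CoordinateTable(coords_mm=coords, voxel_indices=idx)


def write_coordinate_table(table: CoordinateTable, path) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(len(table.coords_mm)),
            "x_mm": table.coords_mm[:, 0],
            "y_mm": table.coords_mm[:, 1],
            "z_mm": table.coords_mm[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _block_factor(vol_sizes: np.ndarray, target_mm: float) -> int:
    """Integer downsampling factor, or raise."""
    src = float(vol_sizes[0])
    if not np.allclose(vol_sizes, src, atol=1e-9):
        raise ParameterError("downsample requires isotropic source voxels")
    if target_mm < src - 1e-9:
        raise ParameterError(
            f"target {target_mm} mm is finer than source {src} mm"
        )
    factor = target_mm / src
    if abs(factor - round(factor)) > 1e-6:
        raise ParameterError(
            f"target {target_mm} mm is not an integer multiple of {src} mm"
        )
    return int(round(factor))


def _block_reduce_mean(arr3d: np.ndarray, f: int) -> np.ndarray:
    """Block mean with partial edge blocks averaged over available voxels."""
    nx, ny, nz = arr3d.shape
    ox, oy, oz = -(-nx // f), -(-ny // f), -(-nz // f)
    out = np.empty((ox, oy, oz), dtype=np.float64)
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                block = arr3d[i * f : (i + 1) * f, j * f : (j + 1) * f, k * f : (k + 1) * f]
                out[i, j, k] = block.mean()
    return out


def downsample(vol: VolumeSeries, target_mm: float) -> VolumeSeries:
    """Block-mean resample a series to a coarser isotropic grid.

    Per frame, non-overlapping f^3 blocks are averaged (partial blocks at
    volume edges average over available voxels). The affine is composed so
    the new voxel centers land at the mean position of their source block.
    """
    f = _block_factor(vol.voxel_sizes_mm, target_mm)
    if f == 1:
        out = VolumeSeries(vol.data.copy(), vol.affine.copy(), vol.tr,
                           provenance=list(vol.provenance))
        out.log_stage("downsample", target_mm=target_mm, factor=1)
        return out
    frames = [_block_reduce_mean(vol.data[..., t], f) for t in range(vol.n_frames)]
    data = np.stack(frames, axis=-1)
    new_affine = _downsampled_affine(vol.affine, f)
    out = VolumeSeries(data, new_affine, vol.tr, provenance=list(vol.provenance))
    out.log_stage("downsample", target_mm=target_mm, factor=f)
    return out


def _downsampled_affine(affine: np.ndarray, f: int) -> np.ndarray:
    """Affine after block aggregation: new index i covers old [f*i, f*i+f-1]."""
    scale = np.eye(4)
    scale[0, 0] = scale[1, 1] = scale[2, 2] = f
    scale[:3, 3] = (f - 1) / 2.0
    return affine @ scale


def downsample_mask(mask: BrainMask, target_mm: float) -> BrainMask:
    """Majority-vote block downsampling of a mask; ties count as true."""
    sizes = np.linalg.norm(mask.affine[:3, :3], axis=0)
    f = _block_factor(sizes, target_mm)
    if f == 1:
        return BrainMask(mask.data.copy(), mask.affine.copy(), label=mask.label)
    frac = _block_reduce_mean(mask.data.astype(np.float64), f)
    return BrainMask(frac >= 0.5, _downsampled_affine(mask.affine, f),
                     label=mask.label)


def upsample_nearest(smap: ScalarMap, fine_mask: BrainMask) -> ScalarMap:
    """Nearest-neighbor upsampling of a coarse map onto a finer grid.

    Intended only for overlaying coarse metric maps on the working grid.
    """
    table = voxel_coordinates_mm(fine_mask)
    inv = np.linalg.inv(smap.affine)
    homog = np.column_stack([table.coords_mm, np.ones(len(table.coords_mm))])
    coarse_idx = np.rint((inv @ homog.T).T[:, :3]).astype(int)
    shape = np.asarray(smap.data.shape)
    coarse_idx = np.clip(coarse_idx, 0, shape - 1)
    out = np.full(fine_mask.data.shape, FILL_VALUE)
    vi = table.voxel_indices
    out[vi[:, 0], vi[:, 1], vi[:, 2]] = smap.data[
        coarse_idx[:, 0], coarse_idx[:, 1], coarse_idx[:, 2]
    ]
    return ScalarMap(out, fine_mask.affine, smap.kind, fine_mask)


def map_from_node_values(
    values: np.ndarray, mask: BrainMask, kind: MapKind
) -> ScalarMap:
    """Scatter per-node values (in scan order) back into a 3D map."""
    table = voxel_coordinates_mm(mask)
    if len(values) != len(table.voxel_indices):
        raise DataError(
            f"{len(values)} node values for {len(table.voxel_indices)} mask voxels"
        )
    out = np.full(mask.data.shape, FILL_VALUE)
    vi = table.voxel_indices
    out[vi[:, 0], vi[:, 1], vi[:, 2]] = values
    return ScalarMap(out, mask.affine, kind, mask)
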