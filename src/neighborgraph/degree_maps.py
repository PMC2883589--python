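"""Local/distant degree maps and their normalizations.

A node's degree is partitioned by Euclidean distance to its neighbors:
edges within the neighborhood radius (default 14 mm, boundary inclusive)
count toward the local degree, edges beyond it toward the distant degree.
Local + distant always equals total degree. Maps are Z-scored (population
SD over in-mask voxels) so they can be averaged across subjects; the
preferential map is local Z − distant Z and the overlap map marks voxels
where both Z maps exceed a cutoff (default 1 SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .connectivity_graph import NeighborhoodSpec, VoxelGraph
from .io_volumes import (
    BrainMask,
    DataError,
    MapKind,
    ParameterError,
    ScalarMap,
    map_from_node_values,
    voxel_coordinates_mm,
)

logger = logging.getLogger("neighborgraph")


@dataclass
class DegreePair:
    """Per-node local and distant degree (counts, or GM-corrected ratios)."""

    local: np.ndarray
    distant: np.ndarray
    spec: NeighborhoodSpec
    r_threshold: float

    def __post_init__(self) -> None:
        # raw counts stay integer; GM-corrected pairs are float
        self.local = np.asarray(self.local)
        self.distant = np.asarray(self.distant)
        if self.local.shape != self.distant.shape:
            raise DataError("local/distant shape mismatch")

    def local_map(self, graph: VoxelGraph) -> ScalarMap:
        return map_from_node_values(self.local, graph.mask, MapKind.LOCAL_RAW)

    def distant_map(self, graph: VoxelGraph) -> ScalarMap:
        return map_from_node_values(self.distant, graph.mask, MapKind.DISTANT_RAW)


@dataclass
class NormalizedPair:
    """Standardized local/distant maps (``zscore`` or ``percent`` method)."""

    local_z: np.ndarray
    distant_z: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("zscore", "percent"):
            raise ParameterError("method must be 'zscore' or 'percent'")


def local_distant_degree(
    graph: VoxelGraph, spec: NeighborhoodSpec | None = None, block: int = 1024
) -> DegreePair:
    """Split every node's degree by neighbor distance against the radius.

    Distances are computed in row blocks so the full n x n distance matrix
    is never materialized for large graphs.
    """
    spec = spec or NeighborhoodSpec()
    n = graph.n_nodes
    local = np.zeros(n, dtype=np.int64)
    distant = np.zeros(n, dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        dist = cdist(graph.node_coords[start:stop], graph.node_coords)
        adj = graph.adjacency[start:stop]
        is_local = spec.is_local(dist)
        local[start:stop] = (adj & is_local).sum(axis=1)
        distant[start:stop] = (adj & ~is_local).sum(axis=1)
    return DegreePair(local, distant, spec, graph.r_threshold)


def radius_sweep(
    graph: VoxelGraph, radii_mm, boundary: str = "inclusive"
) -> list[DegreePair]:
    """One DegreePair per radius; radii must be positive and ascending."""
    radii = list(radii_mm)
    if any(r <= 0 for r in radii):
        raise ParameterError("radii must be positive")
    if radii != sorted(radii):
        raise ParameterError("radii must be sorted ascending")
    return [
        local_distant_degree(graph, NeighborhoodSpec(r, boundary))
        for r in radii
    ]


def zscore_values(values: np.ndarray) -> np.ndarray:
    """(v − mean) / population SD; NaNs (missing) are ignored and preserved."""
    finite = np.isfinite(values)
    vals = values[finite]
    sd = vals.std()  # population convention (divide by n)
    if sd == 0:
        raise DataError("degenerate map: zero variance, cannot Z-score")
    out = np.full_like(np.asarray(values, float), np.nan)
    out[finite] = (vals - vals.mean()) / sd
    return out


def zscore_map(smap: ScalarMap, mask: BrainMask | None = None) -> ScalarMap:
    """Z-score a map over its in-mask voxels; outside stays at fill."""
    mask = mask or smap.mask
    vals = smap.data[mask.data]
    z = zscore_values(vals)
    out = np.zeros_like(smap.data)
    out[mask.data] = z
    kind = {
        MapKind.LOCAL_RAW: MapKind.LOCAL_Z,
        MapKind.DISTANT_RAW: MapKind.DISTANT_Z,
    }.get(smap.kind, smap.kind)
    return ScalarMap(out, smap.affine, kind, mask)


def normalize_zscore(pair: DegreePair) -> NormalizedPair:
    return NormalizedPair(
        zscore_values(pair.local), zscore_values(pair.distant), "zscore"
    )


def percent_normalize(pair: DegreePair) -> NormalizedPair:
    """Distant% = 100 * distant / (distant + local); local% = 100 − distant%.

    Voxels with total degree 0 get NaN (missing) and are excluded from any
    downstream statistics, rather than a misleading 0.
    """
    total = pair.local + pair.distant
    with np.errstate(invalid="ignore", divide="ignore"):
        distant_pct = np.where(total > 0, 100.0 * pair.distant / total, np.nan)
    local_pct = 100.0 - distant_pct
    return NormalizedPair(local_pct, distant_pct, "percent")


def grey_matter_corrected_degree(
    graph: VoxelGraph,
    spec: NeighborhoodSpec | None = None,
    gm: BrainMask | None = None,
    block: int = 1024,
) -> DegreePair:
    """Degree weighted by grey-matter volume available on each side.

    Local counts divide by the number of GM voxels inside the node's sphere,
    distant counts by the GM voxels outside it, so voxels near tissue
    interfaces are not penalized for having fewer grey-matter neighbors.
    Spheres containing no GM voxel yield NaN, and nodes that are not
    themselves grey matter are reported as missing — the corrected maps are
    a grey-matter analysis.
    """
    spec = spec or NeighborhoodSpec()
    if gm is None:
        raise ParameterError("grey-matter mask required")
    if graph.mask is not None:
        gm.check_compatible(graph.mask)
    raw = local_distant_degree(graph, spec, block=block)
    gm_coords = voxel_coordinates_mm(gm).coords_mm
    n = graph.n_nodes
    n_gm = len(gm_coords)
    local = np.empty(n)
    distant = np.empty(n)
    # node's own GM membership, via its voxel index on the GM grid
    inv = np.linalg.inv(gm.affine)
    homog = np.column_stack([graph.node_coords, np.ones(n)])
    idx = np.rint((inv @ homog.T).T[:, :3]).astype(int)
    shape = np.asarray(gm.data.shape)
    on_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    member = np.zeros(n, dtype=bool)
    member[on_grid] = gm.data[idx[on_grid, 0], idx[on_grid, 1],
                              idx[on_grid, 2]]
    for start in range(0, n, block):
        stop = min(start + block, n)
        dist = cdist(graph.node_coords[start:stop], gm_coords)
        inside = spec.is_local(dist).sum(axis=1).astype(float)
        outside = n_gm - inside
        with np.errstate(invalid="ignore", divide="ignore"):
            local[start:stop] = np.where(
                inside > 0, raw.local[start:stop] / inside, np.nan
            )
            distant[start:stop] = np.where(
                outside > 0, raw.distant[start:stop] / outside, np.nan
            )
    local[~member] = np.nan
    distant[~member] = np.nan
    return DegreePair(local, distant, spec, graph.r_threshold)


def preferential_values(norm: NormalizedPair) -> np.ndarray:
    """Local Z − distant Z per node (relative topography measure)."""
    if norm.method != "zscore":
        raise ParameterError("preferential map requires zscore normalization")
    return norm.local_z - norm.distant_z


def preferential_map(norm: NormalizedPair, graph: VoxelGraph) -> ScalarMap:
    return map_from_node_values(
        preferential_values(norm), graph.mask, MapKind.PREFERENTIAL
    )


def overlap_values(norm: NormalizedPair, cutoff_z: float = 1.0) -> np.ndarray:
    """Boolean: both local Z and distant Z exceed the cutoff (default 1 SD)."""
    if norm.method != "zscore":
        raise ParameterError("overlap map requires zscore normalization")
    return (norm.local_z > cutoff_z) & (norm.distant_z > cutoff_z)


def overlap_map(
    norm: NormalizedPair, graph: VoxelGraph, cutoff_z: float = 1.0
) -> ScalarMap:
    return map_from_node_values(
        overlap_values(norm, cutoff_z).astype(float), graph.mask, MapKind.OVERLAP
    )


def group_average(maps: list[ScalarMap], rezscore: bool = False) -> ScalarMap:
    """Voxel-wise mean of same-kind maps on a shared grid.

    Missing (NaN) voxels are excluded per-voxel. With ``rezscore`` the group
    mean is re-standardized over the mask (display parity variant); the
    default is the plain mean of subject maps.
    """
    if not maps:
        raise ParameterError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.data.shape != first.data.shape or m.kind != first.kind:
            raise DataError("group_average requires same-grid, same-kind maps")
        if not np.allclose(m.affine, first.affine, atol=1e-6):
            raise DataError("group_average requires a shared affine")
    stack = np.stack([m.data for m in maps], axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    out = ScalarMap(mean, first.affine, first.kind, first.mask)
    if rezscore:
        out = zscore_map(out)
    logger.info("group_average over n=%d maps of kind %s", len(maps),
                first.kind.value)
    return out


def condition_difference(
    task_maps: list[ScalarMap], rest_maps: list[ScalarMap]
) -> ScalarMap:
    """Group mean(task) − group mean(rest), subjects paired by list order."""
    if len(task_maps) != len(rest_maps):
        raise DataError(
            f"{len(task_maps)} task maps vs {len(rest_maps)} rest maps"
        )
    task = group_average(task_maps)
    rest = group_average(rest_maps)
    return ScalarMap(task.data - rest.data, task.affine, task.kind, task.mask)
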