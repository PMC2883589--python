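"""Spatially embedded network metrics on the (coarsened) voxel graph.

Per node: average shortest-path length in hops (BFS over the unweighted
graph, averaged over reachable nodes), physical cost (mean Euclidean edge
length in mm), and clustering coefficient (fraction of neighbor pairs that
are themselves connected). For whole-brain runs the series is first
block-mean coarsened (default 8 mm) and the graph rebuilt at that grid with
the same correlation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .connectivity_graph import VoxelGraph, build_graph
from .io_volumes import (
    BrainMask,
    DataError,
    MapKind,
    ScalarMap,
    VolumeSeries,
    downsample,
    downsample_mask,
    map_from_node_values,
)

logger = logging.getLogger("neighborgraph")


@dataclass
class MetricMaps:
    """Per-node metric maps at the coarsened analysis grid."""

    path_length: ScalarMap
    physical_cost: ScalarMap
    clustering: ScalarMap
    coarsen_mm: float
    reachable_count: np.ndarray = field(default=None, repr=False)


def average_path_length(
    graph: VoxelGraph, harmonic: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean BFS hop count to all reachable other nodes.

    Unreachable pairs are excluded from the average; the second return value
    is the per-node count of reachable other nodes (transparency for
    disconnected graphs). Isolated or fully unreachable nodes get NaN. With
    ``harmonic`` the reciprocal-distance (efficiency-style) mean over *all*
    other nodes is returned instead.
    """
    adj = csr_matrix(graph.adjacency.astype(np.int8))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    np.fill_diagonal(dist, np.inf)  # exclude self from the average
    reachable = np.isfinite(dist)
    count = reachable.sum(axis=1)
    if harmonic:
        with np.errstate(divide="ignore"):
            inv = np.where(reachable, 1.0 / dist, 0.0)
        n_other = graph.n_nodes - 1
        return inv.sum(axis=1) / n_other, count
    total = np.where(reachable, dist, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def physical_cost(graph: VoxelGraph, block: int = 2048) -> np.ndarray:
    """Per-node mean Euclidean length (mm) of its edges; degree 0 → NaN."""
    n = graph.n_nodes
    deg = graph.degree
    cost = np.empty(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        dist = cdist(graph.node_coords[start:stop], graph.node_coords)
        cost[start:stop] = (graph.adjacency[start:stop] * dist).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(deg > 0, cost / np.maximum(deg, 1), np.nan)


def clustering_coefficient(graph: VoxelGraph) -> np.ndarray:
    """Per-node C_i = E_i / (D_i (D_i − 1) / 2).

    E_i counts edges among the neighbors of i (via the triangle identity
    E_i = (A³)_ii / 2). Nodes with degree ≤ 1 get 0 by convention.
    """
    a = graph.adjacency.astype(np.float64)
    deg = graph.degree.astype(np.float64)
    # (A @ A * A).sum(1) gives 2*E_i per node without forming A^3 fully
    e2 = ((a @ a) * a).sum(axis=1)  # = 2 * E_i
    possible = deg * (deg - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(possible > 0, e2 / possible, 0.0)
    return c


def metric_pipeline(
    vol: VolumeSeries,
    mask: BrainMask,
    r_threshold: float = 0.25,
    coarsen_mm: float = 8.0,
) -> MetricMaps:
    """Coarsen → correlate → threshold → three metric maps at the coarse grid.

    ``vol`` is the preprocessed series at the working grid; it is block-mean
    downsampled to ``coarsen_mm`` (mask by majority vote) and a fresh graph
    is thresholded at the same ``r_threshold``.
    """
    cvol = downsample(vol, coarsen_mm)
    cmask = downsample_mask(mask, coarsen_mm)
    graph = build_graph(cvol, cmask, r_threshold=r_threshold)
    return metrics_from_graph(graph, coarsen_mm)


def metrics_from_graph(graph: VoxelGraph, coarsen_mm: float = 8.0) -> MetricMaps:
    pl, count = average_path_length(graph)
    pc = physical_cost(graph)
    cc = clustering_coefficient(graph)
    if graph.mask is None:
        raise DataError("graph has no mask; cannot build metric maps")
    return MetricMaps(
        path_length=map_from_node_values(pl, graph.mask, MapKind.PATH_LENGTH),
        physical_cost=map_from_node_values(pc, graph.mask, MapKind.PHYSICAL_COST),
        clustering=map_from_node_values(cc, graph.mask, MapKind.CLUSTERING),
        coarsen_mm=coarsen_mm,
        reachable_count=count,
    )
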