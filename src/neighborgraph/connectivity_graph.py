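"""Thresholded voxel-level functional connectivity graphs.

Nodes are in-mask voxels (fixed x-fastest scan order) carrying mm
coordinates; edges are strictly supra-threshold positive Pearson
correlations between voxel time courses. The graph is undirected and
unweighted. Correlations can be computed densely or in row blocks; both
paths use the same arithmetic (standardize, then matrix product) so the
resulting edge sets agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_volumes import (
    BrainMask,
    DataError,
    ParameterError,
    VolumeSeries,
    voxel_coordinates_mm,
)

logger = logging.getLogger("neighborgraph")


@dataclass
class NeighborhoodSpec:
    """Distance rule splitting a node's edges into local and distant.

    ``radius_mm`` defaults to 14 mm (roughly three 4-mm voxels around the
    target). ``boundary='inclusive'`` assigns an edge at exactly the radius
    to the local side, so local and distant always partition the edge set
    with no gap.
    """

    radius_mm: float = 14.0
    boundary: str = "inclusive"

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ParameterError("radius_mm must be > 0")
        if self.boundary not in ("inclusive", "exclusive"):
            raise ParameterError("boundary must be 'inclusive' or 'exclusive'")

    def is_local(self, dist: np.ndarray) -> np.ndarray:
        if self.boundary == "inclusive":
            return dist <= self.radius_mm
        return dist < self.radius_mm


@dataclass
class VoxelGraph:
    """Undirected unweighted graph over in-mask voxels.

    ``adjacency`` is a dense symmetric boolean matrix with empty diagonal;
    ``node_coords`` holds mm coordinates in scan order; ``node_index`` maps
    node → (i, j, k) voxel index; ``mask`` is kept so per-node results can be
    scattered back into volume space.
    """

    node_coords: np.ndarray
    adjacency: np.ndarray
    node_index: np.ndarray
    r_threshold: float
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.adjacency.shape[0]
        if n < 2:
            raise DataError("VoxelGraph needs at least 2 nodes")
        if self.adjacency.shape != (n, n):
            raise DataError("adjacency must be square")
        if np.any(np.diag(self.adjacency)):
            raise DataError("adjacency has self-edges")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise DataError("adjacency not symmetric")
        if self.node_coords.shape != (n, 3):
            raise DataError("node_coords must be n x 3")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


def masked_timeseries(vol: VolumeSeries, mask: BrainMask) -> np.ndarray:
    """In-mask voxel time courses (n_voxels x n_frames), scan order."""
    mask.check_compatible(vol)
    table = voxel_coordinates_mm(mask)
    vi = table.voxel_indices
    return vol.data[vi[:, 0], vi[:, 1], vi[:, 2], :]


def drop_zero_variance(
    ts: np.ndarray, mask: BrainMask
) -> tuple[np.ndarray, BrainMask]:
    """Remove zero-variance voxels from the mask (correlation undefined)."""
    sd = ts.std(axis=1)
    bad = sd == 0
    if not bad.any():
        return ts, mask
    logger.warning("excluding %d zero-variance voxels from mask", int(bad.sum()))
    table = voxel_coordinates_mm(mask)
    new = mask.data.copy()
    vi = table.voxel_indices[bad]
    new[vi[:, 0], vi[:, 1], vi[:, 2]] = False
    return ts[~bad], BrainMask(new, mask.affine, label=mask.label)


def _standardize_rows(ts: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows so correlation is a plain dot product."""
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DataError("zero-variance voxel in correlation input; "
                        "call drop_zero_variance first")
    return centered / norms


def correlation_matrix(vol: VolumeSeries, mask: BrainMask) -> np.ndarray:
    """Dense n x n Pearson correlation matrix over in-mask voxels."""
    if vol.n_frames < 3:
        raise DataError("correlation needs at least 3 frames")
    ts = masked_timeseries(vol, mask)
    z = _standardize_rows(ts)
    corr = z @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def threshold_graph(
    corr: np.ndarray,
    coords: np.ndarray,
    r_threshold: float = 0.25,
    mask: BrainMask | None = None,
    node_index: np.ndarray | None = None,
) -> VoxelGraph:
    """Binarize a correlation matrix into an undirected unweighted graph.

    An edge (i, j) exists iff r_ij > r_threshold strictly; negative
    correlations never form edges.
    """
    if not r_threshold > 0:
        raise ParameterError("r_threshold must be positive")
    corr = np.asarray(corr)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise DataError("correlation matrix must be symmetric")
    adj = corr > r_threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T
    if node_index is None:
        node_index = np.zeros((corr.shape[0], 3), dtype=int)
    return VoxelGraph(np.asarray(coords, float), adj, node_index,
                      r_threshold, mask=mask)


def build_graph(
    vol: VolumeSeries, mask: BrainMask, r_threshold: float = 0.25
) -> VoxelGraph:
    """Time series → correlation → thresholded graph, dense path."""
    ts = masked_timeseries(vol, mask)
    ts, mask = drop_zero_variance(ts, mask)
    if ts.shape[0] < 2:
        raise DataError("fewer than 2 usable voxels in mask")
    if vol.n_frames < 3:
        raise DataError("correlation needs at least 3 frames")
    z = _standardize_rows(ts)
    corr = z @ z.T
    adj = corr > r_threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T
    table = voxel_coordinates_mm(mask)
    return VoxelGraph(table.coords_mm, adj, table.voxel_indices,
                      r_threshold, mask=mask)


def build_graph_blockwise(
    vol: VolumeSeries,
    mask: BrainMask,
    r_threshold: float = 0.25,
    block: int = 512,
) -> VoxelGraph:
    """Same graph as :func:`build_graph` without holding the full float
    correlation matrix: row blocks of the standardized data are multiplied
    against the whole matrix and thresholded immediately."""
    ts = masked_timeseries(vol, mask)
    ts, mask = drop_zero_variance(ts, mask)
    if ts.shape[0] < 2:
        raise DataError("fewer than 2 usable voxels in mask")
    if vol.n_frames < 3:
        raise DataError("correlation needs at least 3 frames")
    z = _standardize_rows(ts)
    n = z.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for start in range(0, n, block):
        stop = min(start + block, n)
        adj[start:stop] = (z[start:stop] @ z.T) > r_threshold
    np.fill_diagonal(adj, False)
    adj &= adj.T  # guard against asymmetric float rounding across blocks
    table = voxel_coordinates_mm(mask)
    return VoxelGraph(table.coords_mm, adj, table.voxel_indices,
                      r_threshold, mask=mask)


def pairwise_distances(graph: VoxelGraph) -> np.ndarray:
    """Dense n x n Euclidean distance matrix (mm) between node coordinates."""
    if not np.all(np.isfinite(graph.node_coords)):
        raise DataError("node coordinates must be finite")
    return cdist(graph.node_coords, graph.node_coords)


def restrict_to_hemisphere(
    graph: VoxelGraph, side: str, midline_mm: float = 0.0
) -> VoxelGraph:
    """Induced subgraph on one hemisphere (x strictly beyond the midline).

    Left is x < midline, right is x > midline; nodes exactly on the midline
    belong to neither and are dropped with a log message. Node ordering is
    preserved among survivors.
    """
    x = graph.node_coords[:, 0]
    if side == "left":
        keep = x < midline_mm
    elif side == "right":
        keep = x > midline_mm
    else:
        raise ParameterError("side must be 'left' or 'right'")
    on_mid = int(np.sum(x == midline_mm))
    if on_mid:
        logger.info("%d nodes exactly on midline excluded", on_mid)
    if keep.sum() < 2:
        raise DataError(f"hemisphere restriction '{side}' leaves <2 nodes")
    sub_mask = None
    if graph.mask is not None:
        new = np.zeros_like(graph.mask.data)
        vi = graph.node_index[keep]
        new[vi[:, 0], vi[:, 1], vi[:, 2]] = True
        sub_mask = BrainMask(new, graph.mask.affine,
                             label=f"hemisphere-{side}")
    return VoxelGraph(
        graph.node_coords[keep],
        graph.adjacency[np.ix_(keep, keep)],
        graph.node_index[keep],
        graph.r_threshold,
        mask=sub_mask,
    )


def export_edge_list(graph: VoxelGraph, edges_path, nodes_path) -> None:
    """Plain-text interop: one 'i j' pair per line (i < j) plus a node table."""
    iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
    with open(edges_path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{i} {j}\n")
    with open(nodes_path, "w") as fh:
        fh.write("index\tx_mm\ty_mm\tz_mm\n")
        for i, (x, y, z) in enumerate(graph.node_coords):
            fh.write(f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
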