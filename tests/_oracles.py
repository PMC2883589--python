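"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written as plain scalar loops, separate
from the package's vectorized code paths.
"""

from collections import deque

import numpy as np


def coords_by_matrix_multiply(mask_data, affine):
    """Per-voxel 4x4 multiply, x-fastest scan order."""
    out = []
    nx, ny, nz = mask_data.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if mask_data[i, j, k]:
                    v = affine @ np.array([i, j, k, 1.0])
                    out.append(v[:3])
    return np.array(out)


def block_mean_downsample(arr3d, f):
    nx, ny, nz = arr3d.shape
    ox, oy, oz = -(-nx // f), -(-ny // f), -(-nz // f)
    out = np.zeros((ox, oy, oz))
    for i in range(ox):
        for j in range(oy):
            for k in range(oz):
                vals = []
                for a in range(i * f, min((i + 1) * f, nx)):
                    for b in range(j * f, min((j + 1) * f, ny)):
                        for c in range(k * f, min((k + 1) * f, nz)):
                            vals.append(arr3d[a, b, c])
                out[i, j, k] = sum(vals) / len(vals)
    return out


def pearson_r_direct(x, y):
    """Textbook summation form of the product-moment correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[t] - mx) * (y[t] - my) for t in range(n))
    den = (sum((x[t] - mx) ** 2 for t in range(n))
           * sum((y[t] - my) ** 2 for t in range(n))) ** 0.5
    return num / den


def correlation_matrix_direct(ts):
    n = ts.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pearson_r_direct(ts[i], ts[j])
    return out


def edges_by_double_loop(corr, r_threshold):
    n = corr.shape[0]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if corr[i, j] > r_threshold:
                edges.add((i, j))
    return edges


def distances_by_scalar_loop(coords):
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for d in range(3):
                s += (coords[i][d] - coords[j][d]) ** 2
            out[i, j] = s ** 0.5
    return out


def local_distant_by_loop(adjacency, coords, radius, inclusive=True):
    n = adjacency.shape[0]
    local = np.zeros(n, dtype=int)
    distant = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j or not adjacency[i, j]:
                continue
            d = sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3)) ** 0.5
            is_local = d <= radius if inclusive else d < radius
            if is_local:
                local[i] += 1
            else:
                distant[i] += 1
    return local, distant


def bfs_path_lengths(adjacency, source):
    """Hop distances from one source; -1 for unreachable."""
    n = adjacency.shape[0]
    dist = [-1] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adjacency[u, v] and dist[v] < 0:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def average_path_length_by_bfs(adjacency):
    """Per-node mean hops over reachable others; NaN if none reachable."""
    n = adjacency.shape[0]
    out = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        dist = bfs_path_lengths(adjacency, i)
        reach = [d for j, d in enumerate(dist) if j != i and d > 0]
        counts[i] = len(reach)
        if reach:
            out[i] = sum(reach) / len(reach)
    return out, counts


def clustering_by_triple_loop(adjacency):
    n = adjacency.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adjacency[i, j]]
        d = len(nbrs)
        if d <= 1:
            continue
        e = 0
        for a in range(d):
            for b in range(a + 1, d):
                if adjacency[nbrs[a], nbrs[b]]:
                    e += 1
        out[i] = e / (d * (d - 1) / 2)
    return out


def physical_cost_by_loop(adjacency, coords):
    n = adjacency.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        lengths = []
        for j in range(n):
            if adjacency[i, j]:
                d = sum((coords[i][k] - coords[j][k]) ** 2
                        for k in range(3)) ** 0.5
                lengths.append(d)
        if lengths:
            out[i] = sum(lengths) / len(lengths)
    return out


def ols_residuals_by_normal_equations(X, y):
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    return y - X @ beta


def random_geometric_graph(rng, n, box_mm=60.0, connect_mm=18.0):
    """Random geometric adjacency + coordinates (mm) in a cube."""
    coords = rng.uniform(0, box_mm, size=(n, 3))
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[i] - coords[j])
            if d <= connect_mm:
                adj[i, j] = adj[j, i] = True
    return adj, coords


def erdos_renyi_graph(rng, n, p):
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = adj | adj.T
    return adj
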