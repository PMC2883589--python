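# neighborgraph

Voxel-wise mapping of **local versus distant functional connectivity** in
resting-state fMRI, with spatially embedded network metrics.

Spontaneous BOLD fluctuations correlate between brain regions, and the
*degree* of a voxel — how many other voxels it is strongly correlated with —
is a simple, powerful marker of network hubs. But a raw degree count mixes
two very different kinds of coupling: short-range coherence with the
immediate cortical neighborhood and long-range coupling with remote regions.
`neighborgraph` separates them. It builds a thresholded, undirected,
unweighted correlation graph over all in-mask voxels and splits every
voxel's degree by the Euclidean distance to its neighbors, yielding local
and distant degree maps, their standardized (Z) versions, a preferential
map, an overlap map, and per-node graph metrics (average path length,
physical wiring cost, clustering coefficient). It is intended for
researchers analysing volumetric resting-state or task fMRI, and ships a
ground-truth synthetic BOLD generator so the whole pipeline can be
validated without any scanner data.

## The method

For preprocessed voxel time courses `x_i(t)` the package forms the Pearson
correlation matrix

    r_ij = Σ_t (x_i(t) − x̄_i)(x_j(t) − x̄_j) / (σ_i σ_j)

and keeps an edge (i, j) wherever `r_ij > 0.25` (strictly; negative
correlations never form edges). With `f_ij` the Euclidean distance between
voxel centers and a neighborhood radius `ρ = 14 mm`:

- **local degree**   `L_i = #{ j : r_ij > 0.25 and f_ij ≤ ρ }`
- **distant degree** `D_i = #{ j : r_ij > 0.25 and f_ij > ρ }`

There is no gap between the two: `L_i + D_i` is the voxel's total degree.
Each map is standardized by Z-score within the mask so maps can be averaged
across subjects; the **preferential map** is `Z_local − Z_distant` and the
**overlap map** marks voxels with `Z_local > 1` and `Z_distant > 1`.
On a coarsened grid (8 mm), per-node metrics are computed on the same kind
of graph: average shortest-path length in hops (over reachable nodes),
physical cost `(1/D_i) Σ_j f_ij` over the node's edges, and clustering
coefficient `C_i = E_i / (D_i (D_i − 1)/2)` where `E_i` counts edges among
the node's neighbors.

Preprocessing follows standard functional-connectivity practice: removal of
the first 4 frames, per-voxel detrending plus an ideal low-pass below
0.08 Hz, 4 mm FWHM Gaussian smoothing, regression of nuisance signals
(whole-brain, ventricle and white-matter means, optional motion parameters,
and their backward-difference derivatives), and block-mean downsampling to
a 4 mm working grid.

## Worked example

Generate the default synthetic cohort (ten subjects; one planted local
module and one hub pair whose spheres share a latent signal across 60 mm),
run the full pipeline, and average the standardized maps:

```python
import numpy as np
import neighborgraph as ng

design = ng.SyntheticDesign()          # 16x16x12 grid, 4 mm voxels, 120 frames
cfg = ng.PreprocessConfig()            # drop 4, <0.08 Hz, 4 mm FWHM, 4 mm grid
spec = ng.NeighborhoodSpec()           # 14 mm local neighborhood

local_z, distant_z = [], []
for i in range(10):
    sub = ng.generate_subject(design, "rest", seed_offset=i)
    pre = ng.preprocess_run(sub.vol, cfg,
                            nuisance_masks=[sub.whole_brain] + sub.nuisance_rois)
    graph = ng.build_graph(pre, sub.whole_brain, r_threshold=0.25)
    pair = ng.local_distant_degree(graph, spec)
    norm = ng.normalize_zscore(pair)
    local_z.append(norm.local_z)
    distant_z.append(norm.distant_z)

local_z = np.mean(local_z, axis=0)
distant_z = np.mean(distant_z, axis=0)
pref = local_z - distant_z
```

Evaluating those maps at the planted ground-truth voxels prints:

```
group local Z  — module mean +1.35, background mean -0.03
group distant Z — hub mean   +1.04, background mean -0.02
preferential (local Z - distant Z): module +1.45, hub -0.37
module voxels in top decile of local Z: 97%
```

The planted local module stands out in the local-degree map with a positive
preferential value (locally over-connected), while the hub pair stands out
in the distant-degree map with a negative preferential value (distantly
over-connected) — the two signatures the method is designed to separate.

The same analysis is available from a shell:

```sh
neighborgraph synth --subjects 10 --out data/
neighborgraph degree --bold data/sub-00_rest_bold.nii.gz \
    --mask data/mask_whole_brain.nii.gz --radius-mm 14 --r-threshold 0.25 \
    --normalize zscore --out maps/
```

plus `preprocess`, `metrics`, `sweep`, `overlap`, `diff`, and `run` (full
cohort pipeline from a JSON config, with provenance and file hashes).

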