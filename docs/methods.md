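# Methods

## Model and procedure

`neighborgraph` treats every in-mask voxel as a node of an undirected,
unweighted graph. Edges are strictly supra-threshold positive Pearson
correlations between preprocessed voxel time courses (`r > 0.25` by
default); negative correlations never form edges, since after global-signal
regression the sign of a correlation is not interpretable. Every node
carries the mm coordinate of its voxel center (affine-transformed), and
each node's degree is partitioned by Euclidean distance into a local part
(neighbors within a 14 mm radius sphere, boundary inclusive) and a distant
part (everything beyond). Local and distant always partition the edge set —
there is no gap, and `local + distant = degree` is asserted exhaustively in
the tests.

The preprocessing pipeline runs in a fixed order: initial-frame removal
(default 4 frames, T1 equilibration) → temporal filter → spatial smoothing
(4 mm FWHM, per-frame 3D Gaussian; a no-smoothing variant supports the
corresponding control analysis) → nuisance regression → block-mean
downsampling to the working grid (4 mm). Degree maps are Z-scored within
the mask so subjects can be averaged; group maps are plain voxel-wise means
of subject Z maps (a re-standardized variant exists behind a flag for
display parity). The preferential map is `Z_local − Z_distant`; the overlap
map is the conjunction `Z_local > c` and `Z_distant > c` with `c = 1` SD.
Task-vs-rest difference maps subtract group means, pairing subjects by
list order. Network metrics (per-node BFS path length, mean Euclidean edge
length, clustering coefficient) are computed on a graph rebuilt at an 8 mm
grid with the same correlation threshold, and reported at that resolution
(nearest-neighbor upsampling is available for overlay only).

## Parameters that matter

| parameter | default | units | role |
| --- | --- | --- | --- |
| `r_threshold` | 0.25 | – | edge cutoff; strict `>`, positive only |
| `radius_mm` | 14 | mm | local/distant boundary; ≤ radius is local |
| `highcut_hz` | 0.08 | Hz | low-pass edge; bin at the edge is retained |
| `drop_frames` | 4 | frames | T1-equilibration removal |
| `fwhm_mm` | 4 | mm | Gaussian smoothing width (0 disables) |
| `working_mm` | 4 | mm | analysis grid for degree maps |
| `metric_mm` (`coarsen_mm`) | 8 | mm | grid for path/cost/clustering |
| `cutoff_z` | 1.0 | SD | overlap-map threshold |

## Numerical choices

- **Temporal filter.** The literature specifies only a passband, so the
  filter is realized as least-squares detrending (constant + linear) per
  voxel followed by an ideal discrete-Fourier low-pass: bins strictly above
  the high-cut are zeroed, the DC bin is zeroed, and a bin exactly at the
  high-cut is retained. Ringing from the ideal filter is accepted on these
  short runs; the contract (stop-band residual < 1 % variance, pass-band
  retention ≥ 95 %, ramps removed to < 1e−8 relative) is asserted directly.
  Nuisance regressors are passed through the same filter before regression
  so residuals cannot regain out-of-band variance.
- **Z-scoring** uses the population SD (divide by n). The convention cancels
  in any cross-subject comparison; it is fixed so example values are exact.
- **Downsampling** is a block mean over non-overlapping integer-factor
  blocks (partial edge blocks average the voxels available); masks
  downsample by majority vote with ties counting as in-mask. Non-integer
  grid ratios are rejected rather than interpolated.
- **Smoothing** converts FWHM to sigma via `FWHM / (2√(2 ln 2))` per axis in
  voxel units from the affine scales, so anisotropic grids smooth
  isotropically in mm. Boundary handling is zero-padded convolution.
- **Degenerate inputs.** Zero-variance voxels are removed from the mask
  (with a logged count) before correlation; a constant degree map refuses
  Z-scoring; percent normalization at total degree 0 yields a missing value
  (NaN) excluded from downstream statistics, not a 0.
- **Disconnected graphs.** Per-node path length averages over reachable
  nodes only and reports the reachable count; isolated nodes are missing.
  A harmonic (efficiency-style) variant is available behind a flag.
  Clustering of nodes with degree ≤ 1 is 0 by the common convention.
- **Exact boundaries.** A correlation exactly at the threshold is *not* an
  edge (`r > 0.25` strict); an edge exactly at the radius *is* local
  (inclusive boundary, configurable). Voxels exactly on the midline belong
  to neither hemisphere in restricted analyses and are dropped with a log
  message.
- **Memory.** The full correlation or distance matrix never has to be
  materialized: correlation thresholding and distance partitioning run in
  row blocks, and the blockwise path is tested to produce the identical
  edge set as the dense path.
- **Grey-matter correction** divides local counts by the number of GM
  voxels inside the node's sphere and distant counts by the GM voxels
  outside it. Both sides use the GM denominator (the symmetric extension of
  a correction described for the search sphere only). Nodes that are not
  themselves grey matter are reported as missing: the corrected maps are a
  grey-matter analysis.

## The synthetic generator

Real resting-state data cannot ship with the package, so
`synthetic_fmri` generates ground-truth cohorts that express the
statistical structure the method assumes: slow (< 0.08 Hz) coherent
fluctuations shared within compact regions, embedded in spatially
structured noise.

- **Latents.** Each planted region's course is a sum of four random-phase
  sinusoids plus band-limited Gaussian noise, unit SD. Sinusoid frequencies
  are assigned from a shared grid with spacing > 1/T (run duration T), so
  distinct latents — and the global confound — are mutually uncorrelated
  over the finite run; otherwise global-signal regression would remove
  planted signal through chance correlation with the regressor.
- **Background.** Grey-matter voxels carry a spatially smooth field
  (Gaussian-smoothed white noise, FWHM 8.5 mm, 80 % variance share) plus
  white noise; this gives the background realistic local connectivity, which
  is what keeps planted hubs from appearing spuriously local-preferential.
  The top and bottom z-slabs are labelled non-grey and carry a halved share
  of the structured field, emulating tissue that shares little cortical
  fluctuation — and giving the grey-matter correction a genuine interface
  to correct.
- **Mixing.** A voxel is a convex, unit-variance mix:
  `√(1 − Σa²)·background + Σ a·latent`. Without this normalization,
  planted voxels would carry excess variance and systematically *lose*
  noise-floor correlations with the rest of the volume, biasing their
  distant degree downward. The signal share is capped at 0.95, enforcing a
  noise floor.
- **Default design.** 16×16×12 grid of 4 mm voxels centred on the origin
  (x = left–right), 120 frames at TR 4 s, one task-flagged local module
  (r = 8 mm, amplitude 0.35) in the left hemisphere, one hub pair
  (r = 8 mm spheres, amplitude 0.7) exactly 60 mm apart across the midline,
  global confound (0.5), linear drift, task gain 1.5. The TR makes the run
  480 s long, approaching the amount of per-subject data in typical
  resting-state studies; with much shorter runs the sample-correlation
  noise floor at `r > 0.25` (a few percent of all pairs) would swamp
  planted distant structure of this size. Amplitudes were chosen once, by
  pilot runs of the oracle pipeline, so that the module stays below edge
  saturation (leaving the task gain room to add edges) and recovery margins
  hold across independent base seeds; they are shipped defaults, not
  per-test knobs. The default seed is fixed (20100610) so documented
  numbers reproduce.
- **What it does not emulate.** Head motion, scanner artifacts,
  physiological (cardiac/respiratory) cycles, hemodynamic convolution,
  anatomical geometry (the "brain" is a box), and distance-dependent
  noise correlations beyond the smooth field. Passing tests therefore show
  that the *method* recovers the structures it targets under its own
  assumptions — not that those assumptions hold in any given dataset.

## Design choices where the design was open

- Downsampling by block mean rather than nearest-neighbor subsampling:
  degree estimation should average signal, not discard it.
- Whether smoothing precedes regression is fixed as filter → smooth →
  regress, the order in which the stages are conventionally described.
- Thresholding uses raw r (no Fisher transform).
- Hemisphere restriction defines left as x < 0 in the affine frame.
- Condition pairing is positional; no subject-ID parsing.
- In hemisphere-restricted analyses the planted hub pair loses its distant
  partner by construction (it straddles the midline), so the
  single-hemisphere control is assessed on the local-module ranking, which
  is what that control concerns.
- In a sphere-pair hub design, within-sphere and cross-sphere planted
  correlations are equal by construction, so hubs gain local and distant
  degree in near-equal measure; their *percent* distant share is only
  weakly elevated over background. The percent-normalization control is
  therefore assessed on the module-vs-background and hub-vs-module
  orderings, which are structural.

## Known limitations

- Euclidean distance approximates cortical distance; no geodesics.
- The graph is unweighted and positive-edge only; no weighted or
  negative-edge analyses.
- Group maps are descriptive means; no inferential statistics across
  subjects.
- The ideal low-pass rings on short runs; with very few frames the
  effective temporal degrees of freedom are small and the supra-threshold
  noise-edge rate correspondingly large.
- Registration/normalization is assumed done upstream; masks must share
  the data grid exactly.

## Problem sizes used in the shipped checks

Oracle-equivalence runs use 100 random graphs of 20–200 nodes; cohort
recovery uses the default design at n = 10 subjects per cohort (about 3 000
voxels per graph); reliability uses two independent n = 10 cohorts; metric
maps are computed at the 8 mm grid (384 voxels). These sizes make the whole
validation suite run in well under a minute for the script and a few tens
of seconds for the cohort fixture, while keeping every recovery margin
comfortably away from its threshold.
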