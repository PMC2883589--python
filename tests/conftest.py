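import numpy as np
import pytest

import neighborgraph as ng


def make_graph(adjacency, coords, mask=None, r_threshold=0.25):
    """Assemble a VoxelGraph directly from adjacency + coordinates."""
    n = adjacency.shape[0]
    return ng.VoxelGraph(
        node_coords=np.asarray(coords, float),
        adjacency=np.asarray(adjacency, bool),
        node_index=np.zeros((n, 3), dtype=int),
        r_threshold=r_threshold,
        mask=mask,
    )


def analyze_rest_subject(design, i, cfg=None, spec=None, condition="rest"):
    """One subject through preprocess -> graph -> degree maps."""
    cfg = cfg or ng.PreprocessConfig()
    spec = spec or ng.NeighborhoodSpec()
    sub = ng.generate_subject(design, condition, i)
    pre = ng.preprocess_run(
        sub.vol, cfg, nuisance_masks=[sub.whole_brain] + sub.nuisance_rois
    )
    graph = ng.build_graph(pre, sub.whole_brain, r_threshold=0.25)
    pair = ng.local_distant_degree(graph, spec)
    norm = ng.normalize_zscore(pair)
    return sub, pre, graph, pair, norm


def node_labels(sub):
    """Planted-region selectors in graph node (scan) order."""
    vi = ng.voxel_coordinates_mm(sub.whole_brain).voxel_indices
    module = sub.module_voxels[vi[:, 0], vi[:, 1], vi[:, 2]]
    hub = sub.hub_voxels[vi[:, 0], vi[:, 1], vi[:, 2]]
    return module, hub


@pytest.fixture(scope="session")
def default_design():
    return ng.SyntheticDesign()


@pytest.fixture(scope="session")
def cohort_results(default_design):
    """Group-level results of the reference synthetic study.

    Computed once per session: the default rest cohort (n=10) with all
    control variants (no smoothing, left hemisphere, grey-matter corrected,
    percent normalization), the paired task cohort, and an independent
    second rest cohort for the reliability analogue.
    """
    design = default_design
    cfg = ng.PreprocessConfig()
    cfg_nosmooth = ng.PreprocessConfig(smoothing_enabled=False)
    spec = ng.NeighborhoodSpec()
    n = 10

    res = {k: [] for k in [
        "local_z", "distant_z", "pref", "local_raw", "distant_raw",
        "task_local_z", "task_local_raw",
        "nosmooth_local_z", "nosmooth_distant_z",
        "left_local_z", "gm_pref", "distant_pct", "conservation_ok",
    ]}
    for i in range(n):
        sub, pre, graph, pair, norm = analyze_rest_subject(design, i, cfg, spec)
        res["local_z"].append(norm.local_z)
        res["distant_z"].append(norm.distant_z)
        res["pref"].append(ng.preferential_values(norm))
        res["local_raw"].append(pair.local)
        res["distant_raw"].append(pair.distant)
        res["conservation_ok"].append(
            bool(np.array_equal(pair.local + pair.distant, graph.degree))
        )
        # control variants on the same subject
        gpair = ng.grey_matter_corrected_degree(graph, spec, sub.grey_matter)
        res["gm_pref"].append(ng.preferential_values(ng.normalize_zscore(gpair)))
        res["distant_pct"].append(ng.percent_normalize(pair).distant_z)
        left = ng.restrict_to_hemisphere(graph, "left")
        lpair = ng.local_distant_degree(left, spec)
        res["left_local_z"].append(
            ng.zscore_values(lpair.local.astype(float)))

        _, _, _, npair, nnorm = analyze_rest_subject(
            design, i, cfg_nosmooth, spec)
        res["nosmooth_local_z"].append(nnorm.local_z)
        res["nosmooth_distant_z"].append(nnorm.distant_z)

        _, _, _, tpair, tnorm = analyze_rest_subject(
            design, i, cfg, spec, condition="task")
        res["task_local_z"].append(tnorm.local_z)
        res["task_local_raw"].append(tpair.local)

    out = {k: np.mean(v, axis=0) for k, v in res.items()
           if k != "conservation_ok"}
    out["conservation_ok"] = all(res["conservation_ok"])

    # reliability analogue: an independent second cohort
    design_b = ng.SyntheticDesign(seed=design.seed + 1000)
    out["cohort_b_local_z"] = np.mean(
        [analyze_rest_subject(design_b, i, cfg, spec)[4].local_z
         for i in range(n)], axis=0)

    sub = ng.generate_subject(design, "rest", 0)
    out["module_nodes"], out["hub_nodes"] = node_labels(sub)
    left_graph = ng.restrict_to_hemisphere(
        analyze_rest_subject(design, 0, cfg, spec)[2], "left")
    vi = left_graph.node_index
    out["left_module_nodes"] = sub.module_voxels[vi[:, 0], vi[:, 1], vi[:, 2]]
    out["n_subjects"] = n
    return out


@pytest.fixture(scope="session")
def swept_subject(default_design):
    """Subject 0's graph and a 6-18 mm radius sweep."""
    sub, pre, graph, pair, norm = analyze_rest_subject(default_design, 0)
    radii = [6.0, 10.0, 14.0, 18.0]
    return {
        "graph": graph,
        "radii": radii,
        "pairs": ng.radius_sweep(graph, radii),
    }
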