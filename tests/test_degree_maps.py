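import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neighborgraph as ng

import _oracles
from conftest import make_graph


@pytest.fixture
def rng():
    return np.random.default_rng(5)


def geometric_graph(rng, n=60):
    adj, coords = _oracles.random_geometric_graph(rng, n, box_mm=50,
                                                  connect_mm=20)
    return make_graph(adj, coords)


class TestLocalDistantDegree:
    def test_isolated_node(self):
        adj = np.zeros((3, 3), bool)
        adj[1, 2] = adj[2, 1] = True
        g = make_graph(adj, np.array([[0., 0, 0], [30., 0, 0], [35., 0, 0]]))
        pair = ng.local_distant_degree(g, ng.NeighborhoodSpec(14.0))
        assert pair.local[0] == 0 and pair.distant[0] == 0

    def test_distance_binning_boundary_inclusive(self):
        coords = np.array([[0., 0, 0], [5., 0, 0], [10., 0, 0],
                           [20., 0, 0], [14., 0, 0]])
        adj = np.zeros((5, 5), bool)
        for j in range(1, 5):
            adj[0, j] = adj[j, 0] = True
        g = make_graph(adj, coords)
        pair = ng.local_distant_degree(g, ng.NeighborhoodSpec(14.0))
        # neighbors at 5, 10, 14 are local (inclusive); 20 is distant
        assert pair.local[0] == 3 and pair.distant[0] == 1
        excl = ng.local_distant_degree(
            g, ng.NeighborhoodSpec(14.0, boundary="exclusive"))
        assert excl.local[0] == 2 and excl.distant[0] == 2

    def test_matches_per_node_loop_oracle(self, rng):
        g = geometric_graph(rng)
        pair = ng.local_distant_degree(g, ng.NeighborhoodSpec(14.0), block=7)
        local, distant = _oracles.local_distant_by_loop(
            g.adjacency, g.node_coords, 14.0)
        np.testing.assert_array_equal(pair.local, local)
        np.testing.assert_array_equal(pair.distant, distant)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(1.0, 80.0))
    def test_conservation_at_any_radius(self, seed, radius):
        rng = np.random.default_rng(seed)
        g = geometric_graph(rng, n=30)
        pair = ng.local_distant_degree(g, ng.NeighborhoodSpec(radius))
        np.testing.assert_array_equal(pair.local + pair.distant, g.degree)


class TestRadiusSweep:
    def test_extreme_radii(self, rng):
        g = geometric_graph(rng)
        huge = ng.local_distant_degree(g, ng.NeighborhoodSpec(1000.0))
        assert np.all(huge.distant == 0)
        tiny = ng.local_distant_degree(g, ng.NeighborhoodSpec(1e-9))
        assert np.all(tiny.local == 0)

    def test_monotone_in_radius(self, rng):
        g = geometric_graph(rng)
        pairs = ng.radius_sweep(g, [6.0, 10.0, 14.0, 18.0])
        for a, b in zip(pairs, pairs[1:]):
            assert np.all(b.local >= a.local)
            assert np.all(b.distant <= a.distant)

    def test_rejects_unsorted_or_nonpositive(self, rng):
        g = geometric_graph(rng, n=10)
        with pytest.raises(ng.ParameterError):
            ng.radius_sweep(g, [14.0, 6.0])
        with pytest.raises(ng.ParameterError):
            ng.radius_sweep(g, [-1.0, 6.0])


class TestZScore:
    def test_three_voxel_hand_computation(self):
        z = ng.zscore_values(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_idempotent_and_shift_invariant(self, rng):
        v = rng.standard_normal(50)
        z = ng.zscore_values(v)
        np.testing.assert_allclose(ng.zscore_values(z), z, atol=1e-12)
        np.testing.assert_allclose(ng.zscore_values(v + 17.3), z, atol=1e-10)

    def test_zscore_map_leaves_outside_at_fill(self, rng):
        mdata = np.zeros((4, 4, 4), bool)
        mdata[:2] = True
        mask = ng.BrainMask(mdata, np.eye(4))
        data = np.zeros((4, 4, 4))
        data[mdata] = rng.standard_normal(mdata.sum())
        smap = ng.ScalarMap(data, np.eye(4), ng.MapKind.LOCAL_RAW, mask)
        z = ng.zscore_map(smap)
        assert np.all(z.data[~mdata] == 0.0)
        assert abs(z.data[mdata].mean()) < 1e-10
        assert abs(z.data[mdata].std() - 1) < 1e-10
        assert z.kind == ng.MapKind.LOCAL_Z

    def test_constant_map_rejected(self):
        with pytest.raises(ng.DataError):
            ng.zscore_values(np.full(10, 3.0))


class TestPercentNormalize:
    def test_printed_formula_and_boundaries(self):
        pair = ng.DegreePair(np.array([3, 0, 0]), np.array([1, 5, 0]),
                             ng.NeighborhoodSpec(), 0.25)
        norm = ng.percent_normalize(pair)
        assert norm.distant_z[0] == pytest.approx(25.0)
        assert norm.local_z[0] == pytest.approx(75.0)
        assert norm.distant_z[1] == pytest.approx(100.0)
        assert np.isnan(norm.distant_z[2])  # total degree 0 -> missing

    def test_values_bounded(self, rng):
        g = geometric_graph(rng)
        norm = ng.percent_normalize(
            ng.local_distant_degree(g, ng.NeighborhoodSpec(14.0)))
        vals = norm.distant_z[np.isfinite(norm.distant_z)]
        assert np.all((vals >= 0) & (vals <= 100))


class TestGreyMatterCorrection:
    def _mask_graph(self, rng, gm_fraction=1.0):
        design = ng.SyntheticDesign(grid_shape=(6, 6, 5), n_frames=40,
                                    modules=[], hub_pairs=[])
        sub = ng.generate_subject(design, "rest", 1)
        g = ng.build_graph(sub.vol, sub.whole_brain, r_threshold=0.1)
        gm_data = rng.random((6, 6, 5)) < gm_fraction
        gm_data[0, 0, 0] = True
        gm = ng.BrainMask(gm_data, design.affine, "grey-matter")
        return g, gm

    def test_uniform_gm_preserves_zscore_topography(self, rng):
        g, gm = self._mask_graph(rng, gm_fraction=1.01)  # all GM
        spec = ng.NeighborhoodSpec(6.0)
        raw = ng.local_distant_degree(g, spec)
        corr = ng.grey_matter_corrected_degree(g, spec, gm)
        keep = raw.local.std() > 0
        assert keep
        z_raw = ng.zscore_values(raw.local.astype(float))
        z_corr = ng.zscore_values(np.asarray(corr.local))
        # denominators vary across nodes (sphere truncation at the volume
        # edge), so only interior nodes share a constant denominator
        interior = np.all(
            (g.node_coords >= g.node_coords.min(0) + 6)
            & (g.node_coords <= g.node_coords.max(0) - 6), axis=1)
        ratio = np.asarray(corr.local)[interior] / np.maximum(
            raw.local[interior], 1)
        assert np.allclose(ratio[raw.local[interior] > 0],
                           ratio[raw.local[interior] > 0][0])
        assert z_raw.shape == z_corr.shape

    def test_half_gm_sphere_doubles_value(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [40.0, 0, 0],
                           [44.0, 0, 0]])
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        g = make_graph(adj, coords)  # no mask: GM lives on its own grid
        affine = np.diag([4.0, 1.0, 1.0, 1.0])
        # GM grid: 12 voxels along x at 4 mm; nodes 0/1 sit where GM is
        # complete, nodes at x=40/44 where half the sphere has no GM
        gm_data = np.zeros((12, 1, 1), bool)
        gm_data[:3] = True
        gm_data[10:12] = True
        gm = ng.BrainMask(gm_data, affine, "grey-matter")
        spec = ng.NeighborhoodSpec(8.0)
        corr = ng.grey_matter_corrected_degree(g, spec, gm)
        # node 0: raw local 1, GM voxels within 8mm of x=0: x in {0,4,8} -> 3
        assert corr.local[0] == pytest.approx(1 / 3)
        # node at x=40: raw local 1, GM within 8mm: x in {40,44} -> 2
        assert corr.local[2] == pytest.approx(1 / 2)

    def test_matches_counting_oracle(self, rng):
        g, gm = self._mask_graph(rng, gm_fraction=0.6)
        spec = ng.NeighborhoodSpec(9.0)
        corr = ng.grey_matter_corrected_degree(g, spec, gm)
        raw = ng.local_distant_degree(g, spec)
        gm_coords = ng.voxel_coordinates_mm(gm).coords_mm
        for i in range(0, g.n_nodes, 7):
            vi = g.node_index[i]
            if not gm.data[vi[0], vi[1], vi[2]]:
                # non-grey nodes are missing in the corrected analysis
                assert np.isnan(corr.local[i]) and np.isnan(corr.distant[i])
                continue
            inside = sum(
                1 for c in gm_coords
                if np.linalg.norm(c - g.node_coords[i]) <= 9.0)
            outside = len(gm_coords) - inside
            if inside:
                assert corr.local[i] == pytest.approx(raw.local[i] / inside)
            else:
                assert np.isnan(corr.local[i])
            if outside:
                assert corr.distant[i] == pytest.approx(
                    raw.distant[i] / outside)


class TestPreferentialAndOverlap:
    def test_preferential_arithmetic(self):
        norm = ng.NormalizedPair(np.array([1.0, 0.5]), np.array([-1.0, 0.5]),
                                 "zscore")
        np.testing.assert_allclose(ng.preferential_values(norm), [2.0, 0.0])

    def test_preferential_antisymmetric_under_swap(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        p1 = ng.preferential_values(ng.NormalizedPair(a, b, "zscore"))
        p2 = ng.preferential_values(ng.NormalizedPair(b, a, "zscore"))
        np.testing.assert_allclose(p1, -p2, atol=1e-12)

    def test_preferential_requires_zscore(self):
        with pytest.raises(ng.ParameterError):
            ng.preferential_values(
                ng.NormalizedPair(np.ones(3), np.ones(3), "percent"))

    def test_overlap_conjunction_and_cutoff_nesting(self, rng):
        lz, dz = rng.standard_normal(200), rng.standard_normal(200)
        norm = ng.NormalizedPair(lz, dz, "zscore")
        ov10 = ng.overlap_values(norm, 1.0)
        ov08 = ng.overlap_values(norm, 0.8)
        np.testing.assert_array_equal(ov10, (lz > 1.0) & (dz > 1.0))
        assert not np.any(ov10 & ~ov08)  # relaxed cutoff marks a superset
        single = ng.NormalizedPair(np.array([1.2]), np.array([0.9]), "zscore")
        assert not ng.overlap_values(single, 1.0)[0]


class TestGroupMaps:
    def _maps(self, rng, n, shape=(4, 4, 3)):
        mask = ng.BrainMask(np.ones(shape, bool), np.eye(4))
        return [ng.ScalarMap(rng.standard_normal(shape), np.eye(4),
                             ng.MapKind.LOCAL_Z, mask) for _ in range(n)], mask

    def test_single_map_and_cancellation(self, rng):
        maps, mask = self._maps(rng, 1)
        out = ng.group_average(maps)
        np.testing.assert_allclose(out.data, maps[0].data)
        neg = ng.ScalarMap(-maps[0].data, np.eye(4), ng.MapKind.LOCAL_Z, mask)
        np.testing.assert_allclose(ng.group_average([maps[0], neg]).data, 0.0,
                                   atol=1e-12)

    def test_matches_accumulate_oracle(self, rng):
        maps, _ = self._maps(rng, 10)
        out = ng.group_average(maps)
        acc = np.zeros_like(maps[0].data)
        for m in maps:
            acc += m.data
        np.testing.assert_allclose(out.data, acc / 10, atol=1e-12)

    def test_heterogeneous_grids_rejected(self, rng):
        maps, _ = self._maps(rng, 2)
        other, _ = self._maps(rng, 1, shape=(3, 3, 3))
        with pytest.raises(ng.DataError):
            ng.group_average([maps[0], other[0]])

    def test_condition_difference(self, rng):
        rest, mask = self._maps(rng, 3)
        bump = np.zeros((4, 4, 3))
        bump[1, 1, 1] = 0.5
        task = [ng.ScalarMap(m.data + bump, np.eye(4), m.kind, mask)
                for m in rest]
        diff = ng.condition_difference(task, rest)
        assert diff.data[1, 1, 1] == pytest.approx(0.5)
        assert abs(diff.data[0, 0, 0]) < 1e-12
        np.testing.assert_allclose(
            ng.condition_difference(rest, rest).data, 0.0, atol=1e-12)
        with pytest.raises(ng.DataError):
            ng.condition_difference(task, rest[:2])
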