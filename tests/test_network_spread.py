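"""Neighbor means, consensus connectomes and the spread statistic."""

import numpy as np
import pytest

import atroprop as ap
from atroprop.core_data import default_region_ids
from atroprop.network_spread import _neighbor_means_matrix


def _conn_from_adjacency(A, coords=None):
    R = len(A)
    if coords is None:
        coords = ap.make_geometry(max(R, 10), rng_seed=0)[:R]
    return ap.Connectome(default_region_ids(R), np.asarray(A, dtype=int), coords)


class TestNeighborMean:
    def test_path_graph_hand_enumeration(self):
        A = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        coords = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        conn = ap.Connectome(["a", "b", "c"], np.asarray(A), coords)
        m = ap.RegionalMap(["a", "b", "c"], [1.0, 2.0, 4.0])
        nm = ap.neighbor_mean(m, conn, "connected")
        np.testing.assert_allclose(nm.values, [2.0, 2.5, 2.0])

    def test_complete_graph_closed_form(self):
        R = 12
        A = np.ones((R, R), dtype=int) - np.eye(R, dtype=int)
        conn = _conn_from_adjacency(A)
        vals = np.arange(R, dtype=float)
        nm = ap.neighbor_mean(ap.RegionalMap(conn.region_ids, vals), conn)
        expected = (vals.sum() - vals) / (R - 1)
        np.testing.assert_allclose(nm.values, expected)

    def test_empty_graph_modes(self):
        R = 10
        conn = _conn_from_adjacency(np.zeros((R, R), dtype=int))
        vals = np.arange(R, dtype=float)
        m = ap.RegionalMap(conn.region_ids, vals)
        assert np.isnan(ap.neighbor_mean(m, conn, "connected").values).all()
        loo = ap.neighbor_mean(m, conn, "nonconnected").values
        np.testing.assert_allclose(loo, (vals.sum() - vals) / (R - 1))

    @pytest.mark.parametrize("mode", ["connected", "nonconnected"])
    def test_matches_brute_force_on_random_graphs(self, mode):
        """Matrix path equals an explicit per-region loop, including NaN."""
        rng = np.random.default_rng(12)
        for rep in range(25):
            R = int(rng.integers(10, 60))
            A = (rng.random((R, R)) < rng.uniform(0.05, 0.5)).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            vals = rng.standard_normal(R)
            if rep % 3 == 0:
                vals[rng.integers(R)] = np.nan
            got = _neighbor_means_matrix(vals[None, :], A, mode)[0]
            for i in range(R):
                nbrs = (
                    np.flatnonzero(A[i]) if mode == "connected"
                    else np.array([j for j in range(R) if j != i and A[i, j] == 0])
                )
                vv = vals[nbrs]
                vv = vv[np.isfinite(vv)]
                if len(vv) == 0:
                    assert np.isnan(got[i])
                else:
                    assert got[i] == pytest.approx(vv.mean(), abs=1e-12)


class TestWeightedNeighborMean:
    def test_uniform_weights_match_unweighted(self, connectome):
        vals = np.random.default_rng(3).standard_normal(connectome.n_regions)
        m = ap.RegionalMap(connectome.region_ids, vals)
        unw = ap.neighbor_mean(m, connectome)
        w = ap.neighbor_mean(
            m, connectome, edge_weights=np.ones_like(connectome.adjacency, float)
        )
        np.testing.assert_allclose(w.values, unw.values, equal_nan=True)

    def test_weights_shift_toward_heavy_edge(self):
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        coords = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        conn = ap.Connectome(["a", "b", "c"], A, coords)
        m = ap.RegionalMap(["a", "b", "c"], [0.0, 1.0, 3.0])
        W = np.array([[0, 3.0, 1.0], [3.0, 0, 0], [1.0, 0, 0]])
        got = ap.neighbor_mean(m, conn, edge_weights=W)
        assert got.values[0] == pytest.approx((3 * 1 + 1 * 3) / 4)


class TestConsensusConnectome:
    def _subjects(self, adjs, coords=None):
        return [_conn_from_adjacency(a, coords) for a in adjs]

    def test_identical_inputs_pass_through(self, connectome):
        subs = [
            ap.Connectome(connectome.region_ids, connectome.adjacency,
                          connectome.coordinates)
            for _ in range(4)
        ]
        cons = ap.consensus_connectome(subs)
        np.testing.assert_array_equal(cons.adjacency, connectome.adjacency)

    def test_minority_edge_dropped(self):
        R = 10
        base = np.zeros((R, R), dtype=int)
        base[0, 1] = base[1, 0] = 1
        with_e = base.copy()
        with_e[2, 3] = with_e[3, 2] = 1
        adjs = [with_e] * 3 + [base] * 7
        cons = ap.consensus_connectome(self._subjects(adjs), retain_fraction=0.5)
        assert cons.adjacency[0, 1] == 1
        assert cons.adjacency[2, 3] == 0

    def test_simulated_subjects_recover_group_density(self, small_cohort):
        truth = small_cohort.ground_truth.connectome
        cons = ap.consensus_connectome(small_cohort.subject_connectomes["AD"])
        assert abs(cons.density() - truth.density()) / truth.density() < 0.2

    def test_distance_binned_variant_preserves_edge_count(self, small_cohort):
        subs = small_cohort.subject_connectomes["FHAD"]
        cons = ap.consensus_connectome(subs, distance_binned=True)
        mean_edges = np.mean([c.adjacency.sum() / 2 for c in subs])
        got = cons.adjacency.sum() / 2
        assert abs(got - mean_edges) / mean_edges < 0.1

    def test_mismatched_regions_rejected(self, connectome):
        other = ap.Connectome(
            [f"x{i}" for i in range(connectome.n_regions)],
            connectome.adjacency, connectome.coordinates,
        )
        with pytest.raises(ap.RegionAlignmentError):
            ap.consensus_connectome([connectome, other])


class TestSpreadTest:
    def test_fixed_point_map_gives_r_one(self, connectome, distances):
        """A map equal to its own neighbor means correlates at r=1."""
        deg = connectome.degree.astype(float)
        A = connectome.adjacency.astype(float)
        # eigenvectors of the row-normalized adjacency satisfy
        # neighbor_mean(v) = lambda * v; the leading one is constant, so use
        # the largest positive non-trivial eigenvalue (via the symmetric
        # similarity transform for numerical stability)
        d_isqrt = 1.0 / np.sqrt(deg)
        M = A * d_isqrt[:, None] * d_isqrt[None, :]
        w, u = np.linalg.eigh(M)
        lam, vec = w[-2], d_isqrt * u[:, -2]
        assert lam > 0
        m = ap.RegionalMap(connectome.region_ids, vec)
        nm = ap.neighbor_mean(m, connectome).values
        r = np.corrcoef(vec, nm)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_pattern_detected_and_nonconnected_negative(self, connectome, distances):
        pat = ap.make_pattern(connectome, [5, 6, 7, 8], steps=8, decay=0.9)
        res = ap.spread_test(pat, connectome, distances, n_surr=99, rng_seed=3)
        assert res.connected.r_emp > 0
        assert res.connected.p_spin < 0.05
        assert res.nonconnected.r_emp < 0

    def test_zero_neighbor_regions_excluded_listwise(self, geometry):
        R = 60
        A = (np.random.default_rng(5).random((R, R)) < 0.2).astype(int)
        A = np.triu(A, 1); A = A + A.T
        A[0, :] = A[:, 0] = 0  # isolate region 0
        conn = ap.Connectome(default_region_ids(R), A, geometry)
        vals = np.random.default_rng(6).standard_normal(R)
        res = ap.spread_test(
            ap.RegionalMap(conn.region_ids, vals), conn, n_surr=20, rng_seed=0
        )
        assert "region_00" in res.excluded_regions[0]

    def test_batch_spread_tests_apply_fdr_per_side(self, connectome, distances):
        maps = {
            "diffused": ap.make_pattern(connectome, [5, 6, 7], steps=8, decay=0.9),
            "diffused2": ap.make_pattern(connectome, [20, 21], steps=8, decay=0.9),
        }
        table = ap.spread_tests(maps, {"group": connectome}, n_surr=49, rng_seed=2)
        assert len(table) == 2
        assert {"p_spin_connected_fdr", "p_spin_nonconnected_fdr"} <= set(table)
        assert (table["p_spin_connected_fdr"] >= table["p_spin_connected"] - 1e-12).all()

    def test_relabeling_invariance(self, connectome, distances):
        """A consistent permutation of regions leaves r and p unchanged."""
        pat = ap.make_pattern(connectome, [10, 11], steps=8, decay=0.9)
        res_a = ap.spread_test(pat, connectome, distances, n_surr=49, rng_seed=1)
        perm = np.random.default_rng(9).permutation(connectome.n_regions)
        conn_p = ap.Connectome(
            [connectome.region_ids[i] for i in perm],
            connectome.adjacency[np.ix_(perm, perm)],
            connectome.coordinates[perm],
        )
        map_p = ap.RegionalMap(conn_p.region_ids, pat.values[perm])
        res_b = ap.spread_test(map_p, conn_p, n_surr=49, rng_seed=1)
        assert res_a.connected.r_emp == pytest.approx(res_b.connected.r_emp)
        assert res_a.nonconnected.r_emp == pytest.approx(res_b.nonconnected.r_emp)
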