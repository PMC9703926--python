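import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

import sirscan
from sirscan.errors import InvalidArgumentError, NoCasesError
from sirscan.scan import enumerate_zones, run_flexscan, zone_llr

from conftest import make_region_table


def brute_force_zones(rt, K):
    """Exhaustive oracle: all connected subsets of size <= K within each
    region's K-nearest-neighbour candidate set (ties by region index)."""
    n = len(rt.table)
    D = rt.distance_matrix()
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for r, nbrs in rt.adjacency.items():
        G.add_edges_from((r, b) for b in nbrs)
    zones = set()
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))
        cand = sorted(int(c) for c in order[:K])
        for k in range(1, K + 1):
            for sub in itertools.combinations(cand, k):
                if i in sub and nx.is_connected(G.subgraph(sub)):
                    zones.add(tuple(sorted(sub)))
    return sorted(zones)


def path3():
    return make_region_table(
        [1, 1, 1], [1, 1, 1],
        [[0, 0], [1, 0], [2, 0]],
        {0: (1,), 1: (0, 2), 2: (1,)},
    )


class TestEnumerateZones:
    def test_path_graph_K2(self):
        assert enumerate_zones(path3(), 2) == [
            (0,), (0, 1), (1,), (1, 2), (2,)
        ]

    def test_K1_is_singletons(self, planar12):
        rt = make_region_table(
            np.ones(12), np.ones(12), planar12.centroids, planar12.adjacency
        )
        assert enumerate_zones(rt, 1) == [(i,) for i in range(12)]

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_lattice_matches_exhaustive_enumeration(self, grid9, K):
        rt = make_region_table(
            np.ones(9), np.ones(9), grid9.centroids, grid9.adjacency
        )
        assert enumerate_zones(rt, K) == brute_force_zones(rt, K)

    def test_invalid_K(self):
        with pytest.raises(InvalidArgumentError):
            enumerate_zones(path3(), 0)


class TestZoneLlr:
    def test_equal_rates_give_zero(self):
        assert zone_llr(2, 2, 10, 10) == 0.0

    def test_worked_value(self):
        expected = 5 * np.log(2.5) + 5 * np.log(5 / 8)
        assert zone_llr(5, 2, 10, 10) == pytest.approx(expected, abs=1e-12)

    def test_all_cases_inside(self):
        val = zone_llr(10, 4, 10, 10)
        assert val == pytest.approx(10 * np.log(10 / 4), abs=1e-12)

    def test_invalid_expected(self):
        with pytest.raises(InvalidArgumentError):
            zone_llr(1, 0, 10, 10)

    @given(
        o_z=st.integers(0, 20),
        e_z=st.floats(0.1, 9.9),
        extra=st.integers(0, 30),
    )
    def test_nonnegative_and_zero_iff_not_elevated(self, o_z, e_z, extra):
        O, E = o_z + extra, 10.0
        if O == 0:
            return
        llr = zone_llr(o_z, e_z, O, E)
        assert llr >= 0.0
        inside, outside = o_z / e_z, (O - o_z) / (E - e_z)
        if inside <= outside:
            assert llr == 0.0


class TestRunFlexscan:
    def test_proportional_counts_give_null_result(self, grid9):
        e = grid9.population_weight * 90
        o = e.copy()  # o exactly proportional to e everywhere
        rt = make_region_table(o, e, grid9.centroids, grid9.adjacency)
        res = run_flexscan(rt, K=3, R=99, seed=1)
        assert res.most_likely.llr == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_most_likely_cluster_matches_brute_force(self, planar12):
        rng = np.random.default_rng(8)
        e = rng.uniform(0.5, 3.0, 12)
        o = rng.poisson(e * np.where(np.arange(12) < 3, 3.0, 1.0)).astype(float)
        rt = make_region_table(o, e, planar12.centroids, planar12.adjacency)
        res = run_flexscan(rt, K=5, R=99, seed=2)
        O, E = o.sum(), e.sum()
        best = max(
            brute_force_zones(rt, 5),
            key=lambda z: zone_llr(o[list(z)].sum(), e[list(z)].sum(), O, E),
        )
        best_llr = zone_llr(o[list(best)].sum(), e[list(best)].sum(), O, E)
        assert res.most_likely.llr == pytest.approx(best_llr, abs=1e-10)
        assert set(res.most_likely.region_ids) == set(best)

    def test_observed_statistic_nondecreasing_in_K(self, planar12):
        rng = np.random.default_rng(3)
        e = rng.uniform(0.5, 3.0, 12)
        o = rng.poisson(e).astype(float) + 1
        rt = make_region_table(o, e, planar12.centroids, planar12.adjacency)
        stats = [
            run_flexscan(rt, K=k, R=9, seed=0).most_likely.llr
            for k in (1, 2, 4, 6)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(stats, stats[1:]))

    def test_p_value_invariant_to_region_relabelling(self, planar12):
        rng = np.random.default_rng(5)
        e = rng.uniform(0.5, 3.0, 12)
        o = rng.poisson(e * 1.5).astype(float)
        rt = make_region_table(o, e, planar12.centroids, planar12.adjacency)
        res = run_flexscan(rt, K=4, R=199, seed=7)

        perm = rng.permutation(12)
        inv = np.argsort(perm)
        # relabel: region i becomes perm[i]; reorder rows to new label order
        adjacency = {
            int(perm[r]): tuple(sorted(int(perm[n]) for n in nbrs))
            for r, nbrs in planar12.adjacency.items()
        }
        rt2 = make_region_table(
            o[inv], e[inv], planar12.centroids[inv], adjacency
        )
        res2 = run_flexscan(rt2, K=4, R=199, seed=7)
        assert res2.most_likely.llr == pytest.approx(res.most_likely.llr)
        assert abs(res2.p_value - res.p_value) <= 0.05

    def test_secondary_clusters_disjoint(self, planar12):
        rng = np.random.default_rng(6)
        e = rng.uniform(0.5, 3.0, 12)
        o = rng.poisson(e * 2.0).astype(float)
        rt = make_region_table(o, e, planar12.centroids, planar12.adjacency)
        res = run_flexscan(rt, K=3, R=9, seed=0)
        seen = set(res.most_likely.region_ids)
        for z in res.secondary:
            assert seen.isdisjoint(z.region_ids)
            seen.update(z.region_ids)

    def test_zero_cases_rejected(self, grid9):
        rt = make_region_table(
            np.zeros(9), np.ones(9), grid9.centroids, grid9.adjacency
        )
        with pytest.raises(NoCasesError):
            run_flexscan(rt, K=2, R=9, seed=0)

    def test_reported_relative_risk_is_observed_over_expected(self):
        zone = sirscan.Zone(region_ids=(1, 2), observed=24, expected=12.0,
                            llr=1.0)
        assert zone.relative_risk == pytest.approx(2.00)
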