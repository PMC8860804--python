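"""Directed NBS, cluster permutation, node typing and distance ANOVA."""

import numpy as np
import pytest
from oracles import anova_sums_of_squares, union_find_components
from scipy import sparse

from dirconn.network_stats import (
    classify_nodes,
    cluster_perm_power,
    form_clusters,
    grid_adjacency,
    link_distance_anova,
    link_distances,
    nbs_onesample_dpli,
    nbs_paired,
    network_overlap,
    sidak_adjust,
    weak_components,
)


class TestWeakComponents:
    def test_directed_chain_is_one_component(self):
        assert weak_components([(0, 1), (1, 2)]) == [{0, 1, 2}]

    def test_no_edges_no_multinode_components(self):
        comps = weak_components([], nodes=[0, 1, 2])
        assert all(len(c) == 1 for c in comps)

    def test_matches_union_find_oracle(self, rng):
        nodes = list(range(20))
        for _ in range(20):
            edges = [
                (int(a), int(b))
                for a, b in rng.integers(0, 20, size=(15, 2))
            ]
            got = weak_components(edges, nodes=nodes)
            expected = union_find_components(nodes, edges)
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestClassifyNodes:
    def test_chain(self):
        types = classify_nodes([(0, 1), (1, 2)])
        assert types == {0: "source", 1: "intermediate", 2: "sink"}

    def test_single_link(self):
        assert classify_nodes([(0, 1)]) == {0: "source", 1: "sink"}

    def test_star_hub_is_sink_with_degree_four(self):
        links = [(1, 0), (2, 0), (3, 0), (4, 0)]
        types = classify_nodes(links)
        assert types[0] == "sink"
        assert sum(1 for a, b in links if 0 in (a, b)) == 4

    def test_self_loop_is_intermediate(self):
        assert classify_nodes([(3, 3)]) == {3: "intermediate"}


class TestNbsPaired:
    def test_identical_conditions_yield_nothing(self, rng):
        a = rng.standard_normal((6, 8, 8))
        assert nbs_paired(a, a.copy(), n_perm=200, seed=0) == []

    def test_planted_component_recovered_from_matrices(self, rng):
        """Three links forming a weak component, shifted in condition A
        for every subject, come back as one significant component."""
        a = rng.standard_normal((12, 10, 10))
        b = rng.standard_normal((12, 10, 10))
        planted = {(0, 5), (1, 5), (2, 5)}
        for i, j in planted:
            a[:, i, j] += 2.0
        nets = nbs_paired(a, b, n_perm=500, seed=1)
        assert len(nets) == 1
        assert nets[0].p_value < 0.05
        assert planted <= nets[0].link_set()

    def test_too_few_subjects_rejected(self, rng):
        a = rng.standard_normal((2, 5, 5))
        with pytest.raises(ValueError, match="subjects"):
            nbs_paired(a, a, n_perm=10, seed=0)

    def test_zero_variance_link_excluded(self, rng):
        a = rng.standard_normal((8, 5, 5))
        b = rng.standard_normal((8, 5, 5))
        a[:, 1, 2] = b[:, 1, 2] = 0.7  # difference identically zero
        nets = nbs_paired(a, b, n_perm=100, seed=0)
        assert all((1, 2) not in n.link_set() for n in nets)

    def test_p_values_on_permutation_grid(self, rng):
        a = rng.standard_normal((10, 6, 6))
        b = rng.standard_normal((10, 6, 6))
        a[:, 0, 1] += 3.0
        n_perm = 99
        nets = nbs_paired(a, b, alpha_comp=1.1, n_perm=n_perm, seed=3)
        for net in nets:
            k = round(net.p_value * (n_perm + 1))
            assert net.p_value == pytest.approx(k / (n_perm + 1))
            assert 0 < net.p_value <= 1


class TestNbsOneSample:
    @staticmethod
    def _antisym(rng, n_subj, n_roi, planted=(), shift=1.5):
        z = rng.standard_normal((n_subj, n_roi, n_roi))
        m = z - np.transpose(z, (0, 2, 1))
        for i, j in planted:
            m[:, i, j] += shift
            m[:, j, i] -= shift
        m[:, np.arange(n_roi), np.arange(n_roi)] = np.nan
        return m

    def test_all_zero_matrices_yield_nothing(self):
        m = np.zeros((8, 6, 6))
        m[:, np.arange(6), np.arange(6)] = np.nan
        assert nbs_onesample_dpli(m, n_perm=100, seed=0) == []

    def test_consistent_lead_recovered(self, rng):
        planted = {(0, 3), (1, 3), (2, 3)}
        m = self._antisym(rng, 12, 10, planted)
        nets = nbs_onesample_dpli(m, n_perm=500, seed=5)
        assert len(nets) >= 1
        assert planted <= set().union(*(n.link_set() for n in nets))
        # only the leading direction of each pair is reported
        for net in nets:
            assert all((b, a) not in net.link_set() for a, b in net.link_set())

    def test_transposition_equivariance(self, rng):
        """Transposing every input reverses recovered link directions and
        leaves p-values unchanged."""
        m = self._antisym(rng, 10, 8, {(0, 4), (1, 4)})
        nets_fwd = nbs_onesample_dpli(m, n_perm=400, seed=9)
        nets_rev = nbs_onesample_dpli(
            np.transpose(m, (0, 2, 1)), n_perm=400, seed=9
        )
        fwd = sorted((n.p_value, tuple(sorted(n.link_set()))) for n in nets_fwd)
        rev = sorted(
            (n.p_value, tuple(sorted((b, a) for a, b in n.link_set())))
            for n in nets_rev
        )
        assert fwd == rev


class TestClusterPermutation:
    def test_toy_chain_cluster_mass(self):
        adjacency = sparse.diags(
            [np.ones(5), np.ones(5)], [1, -1], dtype=float
        ).tocsr()
        t = np.array([0.1, 0.2, 5.0, 6.0, 4.5, 0.3])
        clusters = form_clusters(t, adjacency, 3.0)
        assert len(clusters) == 1
        members, mass = clusters[0]
        assert sorted(members) == [2, 3, 4]
        assert mass == pytest.approx(15.5)

    def test_positive_and_negative_tails_separate(self):
        adjacency = sparse.csr_matrix(np.ones((4, 4)) - np.eye(4))
        t = np.array([5.0, 6.0, -7.0, -5.5])
        clusters = form_clusters(t, adjacency, 3.0)
        masses = sorted(round(m, 1) for _, m in clusters)
        assert masses == [-12.5, 11.0]

    def test_identical_conditions_give_empty_result(self, rng):
        maps = rng.standard_normal((8, 10))
        coords = rng.uniform(-50, 50, (10, 3))
        adj = grid_adjacency(coords)
        assert cluster_perm_power(maps, maps.copy(), adj, n_perm=200, seed=0) == []

    def test_isolated_planted_source_detected(self, rng):
        coords = rng.uniform(-50, 50, (8, 3))
        adj = grid_adjacency(coords, radius=1.0)  # every source isolated
        a = rng.standard_normal((10, 8))
        b = rng.standard_normal((10, 8))
        a[:, 3] += 3.0
        res = cluster_perm_power(
            a, b, adj, alpha_init=0.0005, n_perm=1000, seed=7, coords=coords
        )
        assert len(res) == 1
        assert list(res[0].members) == [3]
        assert res[0].p_value < 0.05
        assert np.allclose(res[0].peak_coord, coords[3])

    def test_source_relabeling_invariance(self, rng):
        """Permuting source indices (with adjacency permuted accordingly)
        permutes cluster membership but not masses or p-values."""
        coords = rng.uniform(-50, 50, (12, 3))
        adj = grid_adjacency(coords)
        a = rng.standard_normal((9, 12))
        b = rng.standard_normal((9, 12))
        a[:, [2, 5]] += 2.5
        perm = rng.permutation(12)
        res1 = cluster_perm_power(a, b, adj, alpha_init=0.01, n_perm=300, seed=11)
        adj_p = adj[perm][:, perm]
        res2 = cluster_perm_power(
            a[:, perm], b[:, perm], adj_p, alpha_init=0.01, n_perm=300, seed=11
        )
        stats1 = sorted((round(c.mass, 6), c.p_value) for c in res1)
        stats2 = sorted((round(c.mass, 6), c.p_value) for c in res2)
        assert stats1 == stats2


class TestDistanceAnova:
    def test_identical_groups_not_significant(self):
        g = np.array([10.0, 20.0, 30.0])
        report = link_distance_anova({"a": g, "b": g.copy(), "c": g.copy()})
        assert report["F"] == pytest.approx(0.0, abs=1e-12)
        assert report["p"] == pytest.approx(1.0)
        assert (report["posthoc"]["p_sidak"] > 0.99).all()

    def test_matches_sum_of_squares_oracle(self):
        groups = {
            "dpli_theta": np.array([10.0, 11.0, 12.0]),
            "dpli_gamma": np.array([30.0, 31.0, 32.0]),
            "nmi": np.array([50.0, 51.0, 52.0]),
        }
        report = link_distance_anova(groups)
        f_exp, p_exp = anova_sums_of_squares(list(groups.values()))
        assert report["F"] == pytest.approx(f_exp, rel=1e-12)
        assert report["p"] == pytest.approx(p_exp, rel=1e-9)

    def test_sidak_adjustment_value(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(1.0 - 0.98**3)

    def test_small_group_excluded(self):
        report = link_distance_anova(
            {
                "a": np.array([1.0, 2.0, 3.0]),
                "b": np.array([4.0, 5.0, 6.0]),
                "c": np.array([9.0]),
            }
        )
        assert report["excluded"] == ["c"]
        assert set(report["groups"]) == {"a", "b"}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            link_distance_anova({"a": np.array([1.0, 2.0])})

    def test_link_distances_euclidean(self):
        from dirconn.network_stats import DirectedNetwork

        net = DirectedNetwork(links=[(0, 1, 2.0)], p_value=0.01)
        centroids = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert link_distances([net], centroids) == pytest.approx([5.0])


def test_network_overlap_reports_shared_links():
    from dirconn.network_stats import DirectedNetwork

    a = [DirectedNetwork(links=[(0, 1, 2.0), (1, 2, 2.5)], p_value=0.01)]
    b = [DirectedNetwork(links=[(1, 2, 3.0), (4, 5, 2.2)], p_value=0.02)]
    assert network_overlap(a, b) == {(1, 2)}
    assert network_overlap(a, []) == set()
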