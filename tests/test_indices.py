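import math

import networkx as nx
import numpy as np
import pytest

import medianet as mn
from medianet.indices import index_columns

from .oracles import (
    brute_betweenness,
    brute_closeness,
    brute_topological_importance,
    connected_atlas_graphs,
    walk_effect_matrix,
)


class TestNormalizedDegree:
    def test_star_centre_and_leaf(self):
        nd = mn.normalized_degree(nx.star_graph(4))
        assert nd[0] == 1.0 and nd[1] == 0.25

    def test_isolated_node_is_zero(self):
        G = nx.path_graph(3)
        G.add_node(9)
        assert mn.normalized_degree(G)[9] == 0.0

    def test_path_end(self):
        assert mn.normalized_degree(nx.path_graph(3))[0] == 0.5

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            mn.normalized_degree(nx.Graph([("A", "A")]))


class TestNormalizedBetweenness:
    def test_path_centre_is_one(self):
        assert mn.normalized_betweenness(nx.path_graph(3))[1] == pytest.approx(1.0)

    def test_cycle4_is_one_sixth(self):
        nbc = mn.normalized_betweenness(nx.cycle_graph(4))
        assert all(v == pytest.approx(1 / 6) for v in nbc.values())

    def test_complete_graph_all_zero(self):
        assert all(v == 0.0 for v in mn.normalized_betweenness(nx.complete_graph(5)).values())

    def test_cross_component_pairs_contribute_nothing(self):
        G = nx.disjoint_union(nx.path_graph(3), nx.path_graph(3))
        nbc = mn.normalized_betweenness(G)
        # centre of a P3 inside a 6-node graph: only 1 of the 10 j<k pairs
        assert nbc[1] == pytest.approx(2 * 1 / (5 * 4))


class TestNormalizedCloseness:
    def test_path3(self):
        ncc = mn.normalized_closeness(nx.path_graph(3))
        assert ncc[1] == pytest.approx(1.0)
        assert ncc[0] == pytest.approx(2 / 3)

    def test_complete_graph_is_one(self):
        assert all(v == pytest.approx(1.0) for v in mn.normalized_closeness(nx.complete_graph(4)).values())

    def test_disconnected_uses_wasserman_faust(self):
        G = nx.Graph([(0, 1)])
        G.add_node(2)
        ncc = mn.normalized_closeness(G)
        assert ncc[0] == pytest.approx(0.5)
        assert ncc[2] == 0.0


class TestEffectMatrix:
    def test_one_step_k2(self):
        em = mn.one_step_matrix(nx.complete_graph(2))
        assert np.allclose(em.per_step[0].toarray(), [[0, 1], [1, 0]])

    def test_one_step_star(self, star3):
        a1 = mn.one_step_matrix(star3).per_step[0].toarray()
        assert np.allclose(a1[0], [0, 1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(a1[1], [1, 0, 0, 0])

    def test_empty_graph_zero_matrix(self):
        G = nx.empty_graph(3)
        em = mn.one_step_matrix(G)
        assert em.per_step[0].nnz == 0

    def test_k2_three_steps_cumulative(self):
        em = mn.effect_matrix(nx.complete_graph(2), 3)
        assert np.allclose(em.per_step[1].toarray(), np.eye(2))
        assert np.allclose(em.per_step[2].toarray(), [[0, 1], [1, 0]])
        assert em.cumulative.toarray()[0, 1] == pytest.approx(2 / 3)

    def test_star_two_step_leaf_to_leaf(self, star3):
        a2 = mn.effect_matrix(star3, 2).per_step[1].toarray()
        assert a2[1, 2] == pytest.approx(1 / 3)

    def test_rows_of_non_isolated_nodes_sum_to_one(self):
        G = nx.gnm_random_graph(12, 18, seed=4)
        G.add_node(99)
        em = mn.effect_matrix(G, 3)
        order = em.nodes
        for m in range(3):
            rows = np.asarray(em.per_step[m].sum(axis=1)).ravel()
            for v, s in zip(order, rows):
                expected = 1.0 if G.degree(v) > 0 else 0.0
                assert s == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_walk_enumeration(self, seed, m):
        G = nx.gnm_random_graph(7, 10, seed=seed)
        nodes, a_brute = walk_effect_matrix(G, m)
        em = mn.effect_matrix(G, m)
        assert em.nodes == nodes
        assert np.allclose(em.per_step[m - 1].toarray(), a_brute, atol=1e-12)


class TestTopologicalImportance:
    def test_k2_symmetry_forces_one(self):
        for n in (1, 2, 5):
            ti = mn.topological_importance(nx.complete_graph(2), n)
            assert all(v == pytest.approx(1.0) for v in ti.values())

    def test_star_one_and_two_steps(self, star3):
        ti1 = mn.topological_importance(star3, 1)
        assert ti1[0] == pytest.approx(3.0) and ti1[1] == pytest.approx(1 / 3)
        ti2 = mn.topological_importance(star3, 2)
        assert ti2[0] == pytest.approx(2.0) and ti2[1] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_conservation_sum_equals_n_nodes(self, n):
        G = nx.gnm_random_graph(30, 60, seed=n)
        if not nx.is_connected(G):
            G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        ti = mn.topological_importance(G, n)
        assert sum(ti.values()) == pytest.approx(G.number_of_nodes())

    def test_isolated_nodes_reduce_total_at_one_step(self):
        G = nx.path_graph(4)
        G.add_nodes_from([10, 11])
        ti = mn.topological_importance(G, 1)
        assert sum(ti.values()) == pytest.approx(4)
        assert ti[10] == 0.0


class TestTopologicalOverlap:
    def test_k2_no_shared_strong_interactors(self):
        to = mn.topological_overlap(nx.complete_graph(2), 3, 0.01)
        assert to == {0: 0, 1: 0}

    def test_star_all_nodes_overlap_six(self, star3):
        to = mn.topological_overlap(star3, 3, 0.01)
        assert all(v == 6 for v in to.values())

    def test_huge_threshold_empties_ranges(self, star3):
        assert all(v == 0 for v in mn.topological_overlap(star3, 3, 10.0).values())

    def test_threshold_monotonicity(self):
        G = nx.gnm_random_graph(25, 45, seed=8)
        hi = mn.topological_overlap(G, 3, 0.01)
        lo = mn.topological_overlap(G, 3, 0.005)
        assert all(hi[v] <= lo[v] for v in G.nodes)

    def test_pairwise_symmetry_via_direct_evaluation(self):
        G = nx.gnm_random_graph(10, 20, seed=3)
        em = mn.effect_matrix(G, 3)
        E = em.cumulative.toarray()
        strong = {
            i: {j for j in range(10) if j != i and E[j, i] > 0.01} for i in range(10)
        }
        to_brute = {
            i: sum(len(strong[i] & strong[j]) for j in range(10) if j != i)
            for i in range(10)
        }
        assert mn.topological_overlap(G, 3, 0.01) == to_brute

    def test_pure_final_step_switch(self):
        # on K2 the 3-step matrix a_3 = a_1, so the off-diagonal entry is 1
        to = mn.topological_overlap(nx.complete_graph(2), 3, 0.9, use_cumulative=False)
        assert to == {0: 0, 1: 0}  # S_1={2}, S_2={1}: still no shared member

    def test_requires_positive_threshold(self, star3):
        with pytest.raises(ValueError):
            mn.topological_overlap(star3, 3, 0.0)


class TestComputeAll:
    def test_deterministic_and_self_consistent(self):
        G = nx.gnm_random_graph(6, 9, seed=2)
        t1 = mn.compute_all(G)
        t2 = mn.compute_all(G)
        assert t1.equals(t2)
        assert np.allclose(t1["nD"], [mn.normalized_degree(G)[v] for v in t1.index])
        assert np.allclose(t1["nBC"], [mn.normalized_betweenness(G)[v] for v in t1.index])
        assert np.allclose(t1["nCC"], [mn.normalized_closeness(G)[v] for v in t1.index])
        assert np.allclose(t1["TI3"], [mn.topological_importance(G, 3)[v] for v in t1.index])
        assert np.allclose(
            t1["TO3_0.01"], [mn.topological_overlap(G, 3, 0.01)[v] for v in t1.index]
        )

    def test_column_ranges(self):
        G = nx.gnm_random_graph(40, 70, seed=5)
        t = mn.compute_all(G)
        for col in ("nD", "nCC", "nBC"):
            assert t[col].between(0, 1).all()
        assert (t["TI3"] >= 0).all()
        for col in ("TO3_0.01", "TO3_0.005"):
            assert (t[col] >= 0).all()
            assert (t[col] == t[col].astype(int)).all()

    def test_column_names(self):
        assert index_columns(3, (0.01, 0.005)) == [
            "nD", "nCC", "nBC", "TI3", "TO3_0.01", "TO3_0.005",
        ]

    def test_requires_three_nodes(self):
        with pytest.raises(ValueError):
            mn.compute_all(nx.complete_graph(2))

    def test_relabeling_invariance(self):
        G = nx.gnm_random_graph(12, 24, seed=9)
        mapping = {v: f"N{(v * 7) % 12:02d}" for v in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        tg, th = mn.compute_all(G), mn.compute_all(H)
        for v in G.nodes:
            assert np.allclose(tg.loc[v].to_numpy(), th.loc[mapping[v]].to_numpy())


def test_oracle_equivalence_on_all_small_connected_graphs():
    """nBC, nCC and TI^3 agree with exhaustive enumeration on every
    connected graph of at most 6 nodes."""
    graphs = connected_atlas_graphs(max_nodes=6)
    assert len(graphs) > 100
    for G in graphs:
        nbc, ncc = mn.normalized_betweenness(G), mn.normalized_closeness(G)
        ti = mn.topological_importance(G, 3)
        bbc, bcc = brute_betweenness(G), brute_closeness(G)
        bti = brute_topological_importance(G, 3)
        for v in G.nodes:
            assert math.isclose(nbc[v], bbc[v], abs_tol=1e-12)
            assert math.isclose(ncc[v], bcc[v], abs_tol=1e-12)
            assert math.isclose(ti[v], bti[v], abs_tol=1e-12)
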