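"""Protein structure networks: interaction strengths, hubs, clique
percolation, ensemble persistence.

The clique-percolation oracle is exhaustive subset enumeration plus
union-find transitive closure (conftest.brute_force_communities); networkx's
k_clique_communities provides a second independent route for the k−1 overlap
rule.
"""

import networkx as nx
import numpy as np
import pytest

from allosteer import psn
from allosteer import synthetic_data as syn
from conftest import brute_force_communities, random_graph, \
    structure_from_coords


def _psn_from_graph(graph: nx.Graph) -> psn.ContactNetwork:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((u, v, {"I": 5.0}) for u, v in graph.edges)
    return psn.ContactNetwork(graph=g, i_min=3.0, contact_distance_A=4.5)


class TestInteractionStrength:
    def test_distant_residues_score_zero(self):
        base = syn.make_contact_base(6, [(0, 2)])
        assert psn.interaction_strength(base, 0, 4, normalization="raw") == 0.0

    def test_formula_arithmetic_raw(self):
        # designed contact: 2x2 pseudo-atoms in range -> n_ij = 4, N = 100
        base = syn.make_contact_base(6, [(0, 2)])
        assert psn.interaction_strength(
            base, 0, 2, normalization="raw") == pytest.approx(4.0)

    def test_formula_with_custom_normalization(self):
        # n_ij = 4, N_i = 64, N_j = 100 -> 100*4/sqrt(6400) = 5.0
        base = syn.make_contact_base(6, [(0, 2)])
        base.residues[2].residue_type = "SER"
        strength = psn.interaction_strength(
            base, 0, 2, normalization={"ALA": 64.0, "SER": 100.0})
        assert strength == pytest.approx(5.0)

    def test_unknown_residue_type_raises_without_entry(self):
        base = syn.make_contact_base(6, [(0, 2)])
        with pytest.raises(KeyError, match="normalization"):
            psn.interaction_strength(base, 0, 2, normalization={"GLY": 10.0})


class TestBuildPsn:
    def test_infinite_cutoff_gives_edgeless_network(self):
        base = syn.make_contact_base(6, syn.clique_edges([0, 2, 4]))
        net = psn.build_psn(base, i_min=100.0, normalization="raw")
        assert net.graph.number_of_edges() == 0

    def test_designed_k4_recovered_exactly(self):
        edges = syn.clique_edges([0, 2, 4, 6])
        base = syn.make_contact_base(9, edges)
        net = psn.build_psn(base, i_min=3.0, normalization="raw")
        assert sorted(net.graph.edges) == edges

    def test_edge_count_monotone_in_i_min(self):
        base = syn.make_contact_base(9, syn.clique_edges([0, 2, 4, 6]))
        counts = [psn.build_psn(base, i_min=i_min,
                                normalization="raw").graph.number_of_edges()
                  for i_min in (2.0, 3.0, 3.9, 4.0, 5.0)]
        assert counts == sorted(counts, reverse=True)
        # strict ">": at i_min = 4.0 the designed 4% contacts drop out
        assert counts[2] > 0 and counts[3] == 0

    def test_edge_set_invariant_under_residue_reordering(self):
        edges = [(0, 2), (2, 4), (0, 4), (3, 6)]
        base = syn.make_contact_base(8, edges)
        permutation = [4, 0, 6, 2, 7, 1, 5, 3]
        residues = []
        for new_serial, old_serial in enumerate(permutation):
            old = base.residues[old_serial]
            residues.append(type(old)(
                chain_id=old.chain_id, author_number=old.author_number,
                serial_index=new_serial, residue_type=old.residue_type,
                ca_coord=old.ca_coord,
                sidechain_atoms=old.sidechain_atoms))
        shuffled = type(base)(residues=residues, label="shuffled")
        net_a = psn.build_psn(base, normalization="raw",
                              min_sequence_separation=0)
        net_b = psn.build_psn(shuffled, normalization="raw",
                              min_sequence_separation=0)

        def author_edges(net, structure):
            return {frozenset((structure.residues[u].author_number,
                               structure.residues[v].author_number))
                    for u, v in net.graph.edges}

        assert author_edges(net_a, base) == author_edges(net_b, shuffled)

    def test_gly_falls_back_to_ca(self):
        # bare beads 4 Å apart: Cα fallback puts them in contact
        s = structure_from_coords([[0, 0, 0], [20, 0, 0], [4, 0, 0]])
        net = psn.build_psn(s, i_min=0.5, normalization="raw")
        assert (0, 2) in net.graph.edges


class TestFindHubs:
    def test_star_center_is_hub(self):
        net = _psn_from_graph(nx.star_graph(4))
        hubs = psn.find_hubs(net)
        assert hubs.hubs == [0]

    def test_k4_has_no_hubs_degree_boundary(self):
        assert psn.find_hubs(_psn_from_graph(nx.complete_graph(4))).hubs == []

    def test_k5_all_hubs(self):
        assert psn.find_hubs(
            _psn_from_graph(nx.complete_graph(5))).hubs == [0, 1, 2, 3, 4]


class TestCliqueCommunities:
    def test_k4_single_community(self):
        result = psn.clique_communities(_psn_from_graph(nx.complete_graph(4)),
                                        k=3, overlap_rule="k-1")
        assert result.n_cliques == 4
        assert result.communities == [{0, 1, 2, 3}]

    def test_two_triangles_sharing_one_node(self):
        graph = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)])
        net = _psn_from_graph(graph)
        loose = psn.clique_communities(net, k=3, overlap_rule="k-2")
        strict = psn.clique_communities(net, k=3, overlap_rule="k-1")
        assert loose.communities == [{0, 1, 2, 3, 4}]
        assert strict.communities == [{0, 1, 2}, {2, 3, 4}]

    def test_triangle_free_graph_empty(self):
        result = psn.clique_communities(
            _psn_from_graph(nx.cycle_graph(5)), k=3)
        assert result.n_cliques == 0 and result.n_communities == 0

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError, match="k"):
            psn.clique_communities(_psn_from_graph(nx.complete_graph(4)), k=2)

    @pytest.mark.parametrize("overlap_rule", ["k-1", "k-2"])
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_on_random_graphs(self, k, overlap_rule):
        rng = np.random.default_rng(hash((k, overlap_rule)) % 2**31)
        for _ in range(50):
            graph = random_graph(rng, int(rng.integers(4, 13)), 0.4)
            result = psn.clique_communities(_psn_from_graph(graph), k=k,
                                            overlap_rule=overlap_rule)
            expected_cliques, expected_comms = brute_force_communities(
                graph, k, overlap_rule)
            assert set(result.cliques) == expected_cliques
            assert {frozenset(c) for c in result.communities} \
                == expected_comms

    def test_matches_networkx_for_k_minus_1_rule(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            graph = random_graph(rng, 12, 0.35)
            result = psn.clique_communities(_psn_from_graph(graph), k=3,
                                            overlap_rule="k-1")
            expected = {frozenset(c) for c in
                        nx.community.k_clique_communities(graph, 3)}
            assert {frozenset(c) for c in result.communities} == expected


class TestPersistenceFilter:
    @staticmethod
    def _ensemble_with_intact_count(intact_frames: int, total: int = 10):
        nodes = [0, 2, 4]
        edges = syn.clique_edges(nodes)
        base = syn.make_contact_base(6, edges)
        schedule = np.zeros((total, len(edges)), dtype=bool)
        schedule[:intact_frames, :] = True
        # in the remaining frames one edge is broken, so the clique is not
        # intact there
        schedule[intact_frames:, :2] = True
        return syn.make_scheduled_ensemble(base, edges, schedule)

    def test_clique_in_8_of_10_frames_retained(self):
        ensemble = self._ensemble_with_intact_count(8)
        result = psn.persistence_filter(ensemble, normalization="raw")
        assert result.cliques == [frozenset({0, 2, 4})]
        assert result.clique_persistence[frozenset({0, 2, 4})] \
            == pytest.approx(0.8)

    def test_clique_in_7_of_10_frames_dropped(self):
        ensemble = self._ensemble_with_intact_count(7)
        result = psn.persistence_filter(ensemble, normalization="raw")
        assert result.cliques == []

    def test_planted_stable_community_recovered(self):
        stable_nodes = [0, 2, 4, 6]
        stable = syn.clique_edges(stable_nodes)
        background = [(1, 8), (3, 8), (1, 3)]
        base = syn.make_contact_base(9, stable + background)
        ensemble, _ = syn.make_persistence_ensemble(
            base, stable, background, p_stable=0.95, p_background=0.3,
            n_frames=100, rng_seed=7)
        result = psn.persistence_filter(ensemble, normalization="raw")
        assert result.communities
        for community in result.communities:
            assert community <= set(stable_nodes)

    def test_zero_threshold_equals_union_of_per_frame_cliques(self):
        base = syn.make_contact_base(
            8, syn.clique_edges([0, 2, 4]) + syn.clique_edges([3, 5, 7]))
        edges = syn.clique_edges([0, 2, 4]) + syn.clique_edges([3, 5, 7])
        rng = np.random.default_rng(11)
        schedule = rng.random((6, len(edges))) < 0.5
        ensemble = syn.make_scheduled_ensemble(base, edges, schedule)
        result = psn.persistence_filter(ensemble, min_fraction=0.0,
                                        normalization="raw")
        per_frame = set()
        for frame in ensemble.frames:
            net = psn.build_psn(frame, normalization="raw")
            per_frame |= set(psn.clique_communities(net, k=3).cliques)
        assert set(result.cliques) == per_frame

    def test_near_one_threshold_subset_of_intersection_cliques(self):
        base = syn.make_contact_base(
            8, syn.clique_edges([0, 2, 4]) + [(4, 6)])
        edges = syn.clique_edges([0, 2, 4]) + [(4, 6)]
        rng = np.random.default_rng(13)
        schedule = rng.random((8, len(edges))) < 0.9
        ensemble = syn.make_scheduled_ensemble(base, edges, schedule)
        result = psn.persistence_filter(ensemble, min_fraction=0.999,
                                        normalization="raw")
        intersection = nx.Graph()
        intersection.add_nodes_from(range(8))
        common = None
        for frame in ensemble.frames:
            net = psn.build_psn(frame, normalization="raw")
            edge_set = {frozenset(e) for e in net.graph.edges}
            common = edge_set if common is None else common & edge_set
        intersection.add_edges_from(tuple(e) for e in common)
        allowed = set(psn.clique_communities(
            _psn_from_graph(intersection), k=3).cliques)
        assert set(result.cliques) <= allowed

    def test_single_frame_rejected(self):
        base = syn.make_contact_base(6, [(0, 2)])
        ensemble = syn.make_scheduled_ensemble(
            base, [(0, 2)], np.array([[True]]))
        with pytest.raises(ValueError, match="frames"):
            psn.persistence_filter(ensemble)


class TestCountSummary:
    def test_edgeless_input_counts_zero(self):
        s = structure_from_coords([[0, 0, 0], [50, 0, 0], [100, 0, 0]])
        table = psn.count_summary({"bare": s}, normalization="raw")
        assert table.loc["bare", "n_cliques"] == 0
        assert table.loc["bare", "n_communities"] == 0

    def test_k4_counts(self):
        base = syn.make_contact_base(9, syn.clique_edges([0, 2, 4, 6]))
        table = psn.count_summary({"k4": base}, normalization="raw")
        assert table.loc["k4", "n_cliques"] == 4
        assert table.loc["k4", "n_communities"] == 1
        assert table.loc["k4", "mean_community_size"] == 4.0

    def test_contact_enriched_complex_counts_dominate(self):
        unbound = syn.make_contact_base(12, syn.clique_edges([0, 2, 4]))
        complex_ = syn.make_contact_base(
            12, syn.clique_edges([0, 2, 4]) + syn.clique_edges([6, 8, 10]))
        table = psn.count_summary({"unbound": unbound, "complex": complex_},
                                  normalization="raw")
        assert table.loc["complex", "n_cliques"] \
            >= table.loc["unbound", "n_cliques"]
        assert table.loc["complex", "n_communities"] \
            >= table.loc["unbound", "n_communities"]
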