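"""Interaction-strength graphs, shortest-path counting and betweenness."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kinnet import resnet
from kinnet import synthetic_data as sd
from kinnet.structio import CorrelationMatrix


from oracles import brute_force_betweenness, random_weighted_graph


class TestNormalization:
    def test_dataset_max_and_table_precedence(self, complex_pair):
        apo, _ = complex_pair
        table = resnet.normalization_factors([apo])
        assert table.get("LEU") > 0
        override = resnet.normalization_factors(
            [apo], table={"LEU": 99.0}
        )
        assert override.get("LEU") == 99.0

    def test_missing_type_errors(self, complex_pair):
        apo, _ = complex_pair
        table = resnet.normalization_factors([apo])
        with pytest.raises(KeyError):
            table.get("TRP")

    def test_positive_invariant(self):
        with pytest.raises(ValueError):
            resnet.NormalizationTable({"ALA": 0.0})


class TestInteractionStrength:
    def test_values(self):
        assert resnet.interaction_strength(0, 10, 10) == 0.0
        assert resnet.interaction_strength(4, 100, 100) == pytest.approx(4.0)
        assert resnet.interaction_strength(4, 100, 100) == resnet.interaction_strength(
            4, 100, 100
        )
        # product-normalized variant
        assert resnet.interaction_strength(4, 100, 100, geometric=False) == (
            pytest.approx(0.04)
        )

    def test_zero_normalization_errors(self):
        with pytest.raises(ValueError):
            resnet.interaction_strength(1, 0, 10)


class TestBuildGraph:
    def test_threshold_filters_edges(self, monkeypatch, complex_pair):
        """I = {4, 2, 5}% with I_min = 3% admits exactly 2 edges."""
        apo, _ = complex_pair
        sub_residues = apo.protein_residues()[:3]
        from kinnet.structio import Structure

        sub = Structure([r for r in apo.copy().residues[:3]])
        strengths = {("A:1", "A:2"): 4.0, ("A:1", "A:3"): 2.0, ("A:2", "A:3"): 5.0}

        monkeypatch.setattr(resnet, "count_contacts", lambda *a, **k: 1)
        monkeypatch.setattr(
            resnet,
            "interaction_strength",
            lambda n, ni, nj, geometric=True: 0.0,
        )

        def fake_strength(n, ni, nj, geometric=True):
            return fake_strength.values.pop(0)

        # deterministic pair order: (1,2), (1,3), (2,3); seq-adjacency off
        fake_strength.values = [4.0, 2.0, 5.0]
        monkeypatch.setattr(resnet, "interaction_strength", fake_strength)
        g = resnet.build_graph(
            sub,
            norm=resnet.NormalizationTable({"LEU": 1.0}),
            i_min=3.0,
            include_adjacent=True,
            include_ligand="off",
        )
        assert g.number_of_edges() == 2
        assert set(map(frozenset, g.edges)) == {
            frozenset({"A:1", "A:2"}),
            frozenset({"A:2", "A:3"}),
        }

    def test_correlation_weighting_limit(self, complex_pair):
        apo, _ = complex_pair
        keys = [r.key for r in apo.protein_residues()]
        values = np.full((len(keys), len(keys)), 1.0 - 1e-6)
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix(labels=keys, values=values)
        g = resnet.build_graph(apo, correlation=corr)
        weights = [d["weight"] for _, _, d in g.edges(data=True)]
        assert all(0 < w < 1e-5 for w in weights)

    def test_missing_correlation_entry_errors(self, complex_pair):
        apo, _ = complex_pair
        corr = CorrelationMatrix(labels=["A:1"], values=np.eye(1))
        with pytest.raises(ValueError, match="lacks"):
            resnet.build_graph(apo, correlation=corr)

    def test_bridge_zero_control_identical_protein_subgraph(self):
        apo, holo = sd.gen_complex(sd.ComplexSpec(bridge_strength=0, seed=2))
        norm = resnet.normalization_factors([apo])
        g_apo = resnet.build_graph(apo, norm=norm)
        g_holo = resnet.build_graph(holo, norm=norm)
        protein_edges = {
            frozenset(e) for e in g_holo.edges if not any("LIG" in v for v in e)
        }
        assert protein_edges == {frozenset(e) for e in g_apo.edges}
        assert not any("LIG" in v for e in g_holo.edges for v in e)


class TestShortestPaths:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        nodes, dist, sigma = resnet.shortest_paths(g)
        i = {v: k for k, v in enumerate(nodes)}
        assert dist[i["A"], i["C"]] == pytest.approx(2.0)
        assert sigma[i["A"], i["C"]] == 1
        assert sigma[i["A"], i["B"]] == 1

    def test_four_cycle_multiplicity(self):
        g = nx.cycle_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        nodes, dist, sigma = resnet.shortest_paths(g)
        assert dist[0, 2] == pytest.approx(2.0)
        assert sigma[0, 2] == 2  # two co-optimal routes
        assert sigma[0, 1] == 1

    def test_negative_weight_errors(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=-1.0)
        with pytest.raises(ValueError, match="negative"):
            resnet.shortest_paths(g)

    def test_distances_match_dijkstra_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = random_weighted_graph(rng)
            nodes, dist, _ = resnet.shortest_paths(g)
            ref = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
            for a, i in zip(nodes, range(len(nodes))):
                for b, j in zip(nodes, range(len(nodes))):
                    expected = ref[a].get(b, np.inf)
                    assert dist[i, j] == pytest.approx(expected, abs=1e-9)


class TestBetweenness:
    def test_path_star_cycle_closed_forms(self):
        p3 = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(p3, 1.0, "weight")
        cb = resnet.betweenness(p3).centrality
        assert cb["B"] == pytest.approx(1.0, abs=1e-12)
        assert cb["A"] == cb["C"] == 0.0

        star = nx.star_graph(4)
        nx.set_edge_attributes(star, 1.0, "weight")
        cb = resnet.betweenness(star).centrality
        assert cb[0] == pytest.approx(1.0, abs=1e-12)
        assert all(cb[k] == 0.0 for k in range(1, 5))

        c4 = nx.cycle_graph(4)
        nx.set_edge_attributes(c4, 1.0, "weight")
        cb = resnet.betweenness(c4).centrality
        assert np.allclose(cb.values, 0.5 / 3, atol=1e-12)

    def test_brute_force_oracle_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g = random_weighted_graph(rng)
            ours = resnet.betweenness(g).centrality
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-12)

    def test_matches_networkx_on_weighted_graphs(self):
        """Independent-library cross-check (component-wise normalization)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_weighted_graph(rng)
            if not nx.is_connected(g):
                continue
            ours = resnet.betweenness(g).centrality
            ref = nx.betweenness_centrality(g, weight="weight", normalized=True)
            for v in g.nodes:
                assert ours[v] == pytest.approx(ref[v], abs=1e-9)

    def test_uniform_weight_equals_topological(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_weighted_graph(rng)
            nx.set_edge_attributes(g, 1.0, "weight")
            ours = resnet.betweenness(g).centrality
            unweighted = nx.betweenness_centrality(g, normalized=True)
            # networkx normalizes by the full graph size; compare on
            # connected graphs only
            if nx.is_connected(g):
                for v in g.nodes:
                    assert ours[v] == pytest.approx(unweighted[v], abs=1e-9)

    def test_small_components_zero(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        cb = resnet.betweenness(g)
        assert (cb.centrality == 0).all()
        assert cb.component[0] == cb.component[1] != cb.component[2]


class TestDeltaCentrality:
    def test_identical_graphs_zero(self, complex_pair):
        apo, _ = complex_pair
        g = resnet.build_graph(apo)
        cb = resnet.betweenness(g)
        assert (resnet.delta_centrality(cb, cb) == 0).all()

    def test_ligand_bridging_gains_and_losses(self, complex_pair):
        apo, holo = complex_pair
        norm = resnet.normalization_factors([apo])
        cb_apo = resnet.betweenness(resnet.build_graph(apo, norm=norm))
        cb_holo = resnet.betweenness(resnet.build_graph(holo, norm=norm))
        delta = resnet.delta_centrality(cb_apo, cb_holo)
        # contacted termini gain, interior path residues lose
        assert delta["A:1"] > 0 and delta["A:12"] > 0
        interior = delta.drop(["A:1", "A:12", "A:3", "A:10"])
        assert (interior <= 0).all()
        assert not any("LIG" in str(k) for k in delta.index)

    def test_disjoint_keys_error(self):
        a = resnet.CentralityProfile(
            pd.Series({"A:1": 0.0}), pd.Series({"A:1": 0})
        )
        b = resnet.CentralityProfile(
            pd.Series({"B:9": 0.0}), pd.Series({"B:9": 0})
        )
        with pytest.raises(ValueError):
            resnet.delta_centrality(a, b)


class TestProperties:
    def test_ligand_bridge_never_decreases_connectivity(self):
        """Adding a 2-contact ligand node cannot disconnect its partners."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = random_weighted_graph(rng)
            nodes = list(g.nodes)
            a, b = rng.choice(nodes, size=2, replace=False)
            before = nx.has_path(g, a, b)
            g2 = g.copy()
            g2.add_edge(a, "LIG", weight=1.0)
            g2.add_edge(b, "LIG", weight=1.0)
            assert nx.has_path(g2, a, b)
            if before:
                d_before = nx.shortest_path_length(g, a, b, weight="weight")
                d_after = nx.shortest_path_length(g2, a, b, weight="weight")
                assert d_after <= d_before + 1e-12

    def test_removing_max_centrality_node_degrades_paths(self):
        """Hubs matter more than random nodes for network integrity."""
        margins = []
        for seed in range(20):
            _, holo = sd.gen_complex(sd.ComplexSpec(seed=seed))
            g = resnet.build_graph(holo)
            cb = resnet.betweenness(g).centrality
            hub = cb.idxmax()
            rng = np.random.default_rng(seed)
            rand = rng.choice([v for v in g.nodes if v != hub])

            def mean_path(graph):
                tot, cnt = 0.0, 0
                for comp in nx.connected_components(graph):
                    sub = graph.subgraph(comp)
                    for _, lengths in nx.all_pairs_dijkstra_path_length(
                        sub, weight="weight"
                    ):
                        tot += sum(lengths.values())
                        cnt += len(lengths) - 1
                return tot / max(cnt, 1)

            g_hub = g.copy()
            g_hub.remove_node(hub)
            g_rand = g.copy()
            g_rand.remove_node(rand)
            margins.append(mean_path(g_hub) - mean_path(g_rand))
        assert np.mean(margins) >= 0


class TestJointProfiles:
    def test_pass_through_and_missing_key(self):
        cent = pd.Series({"A:1": 0.5, "A:2": 0.1, "A:3": 0.0})
        b = pd.Series({"A:1": 10.0, "A:2": 20.0, "A:3": 30.0})
        r = pd.Series({"A:1": 0.2, "A:2": 0.9, "A:3": 0.4})
        df = resnet.joint_profiles(cent, b, r)
        assert list(df.index) == ["A:1", "A:2", "A:3"]
        assert df.loc["A:2", "bfactor"] == 20.0
        with pytest.warns(UserWarning):
            df2 = resnet.joint_profiles(cent, b, r.drop("A:3"))
        assert len(df2) == 2
        assert list(df.columns) == ["betweenness", "bfactor", "rsa"]
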