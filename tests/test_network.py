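import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microassembly import network, synth
from microassembly.network import (basis_variances, build_network,
                                   classify_roles, log_ratio_variance_matrix,
                                   mean_degree, network_summary, node_metrics,
                                   overlay_functions, prevalence_filter,
                                   sparcc_correlations, sparcc_pvalues)
from microassembly.synth import NeutralSimSpec
from microassembly.tables import relative_abundance

from conftest import make_table
from _oracles import brute_force_metrics


class TestPrevalenceFilter:
    @pytest.mark.parametrize("peak_counts,kept", [
        (5, False),    # 0.05% peak -> removed
        (10, False),   # exactly 0.1% -> removed (strict >)
        (20, True),    # 0.2% peak -> kept
    ])
    def test_threshold_strictness(self, peak_counts, kept):
        counts = np.full((3, 2), 0)
        counts[:, 0] = [peak_counts, 0, 0]
        counts[:, 1] = [10_000 - peak_counts, 10_000, 10_000]
        out = prevalence_filter(make_table(counts))
        assert ("O0" in out.otu_ids) is kept


class TestSparCCCore:
    def test_basis_variances_closed_form(self):
        # zero-correlation construction: t_ij = w_i^2 + w_j^2 has the exact
        # solution w^2 under the sparsity system
        w2 = np.array([1.0, 2.0, 3.0])
        t = w2[:, None] + w2[None, :]
        np.fill_diagonal(t, 0.0)
        np.testing.assert_allclose(basis_variances(t), w2, atol=1e-10)

    def test_rejects_underdetermined_or_zero_otus(self):
        with pytest.raises(ValueError, match="at least 4"):
            sparcc_correlations(make_table([[1, 2, 3], [2, 3, 4]]))
        t = make_table([[1, 2, 0, 3, 4], [2, 1, 0, 3, 4]])
        with pytest.raises(ValueError, match="all-zero"):
            sparcc_correlations(t)

    def test_taxon_reordering_invariance(self, rng):
        spec = NeutralSimSpec(n_taxa=20, n_samples=80, depth=2000, Nm=2000,
                              seed=0, shape_param=1.0)
        table = synth.simulate_neutral_table(spec)
        r1 = sparcc_correlations(table, seed=1)
        perm = rng.permutation(table.otu_ids)
        permuted = make_table(table.counts[perm].to_numpy(),
                              sample_ids=table.sample_ids,
                              otu_ids=list(perm))
        r2 = sparcc_correlations(permuted, seed=1)
        # equality is statistical: the Dirichlet draws differ, so bound the
        # mean discrepancy rather than demanding bitwise identity
        diff = np.abs(r1.loc[perm, perm].to_numpy() - r2.to_numpy())
        assert diff.mean() < 0.05 and diff.max() < 0.3

    def test_compositional_scale_invariance(self):
        spec = NeutralSimSpec(n_taxa=20, n_samples=80, depth=2000, Nm=2000,
                              seed=2, shape_param=1.0)
        table = synth.simulate_neutral_table(spec)
        scaled = make_table(table.counts.to_numpy() * 3,
                            sample_ids=table.sample_ids,
                            otu_ids=table.otu_ids)
        r1 = sparcc_correlations(table, seed=3)
        r2 = sparcc_correlations(scaled, seed=3)
        # equal up to Dirichlet-prior and Monte Carlo effects
        diff = np.abs(r1.to_numpy() - r2.to_numpy())
        assert diff.mean() < 0.05 and diff.max() < 0.3

    def test_agrees_with_clr_pearson_on_strong_signal(self):
        # debug oracle: Pearson on centered-log-ratio abundances should see
        # the same planted pair
        spec = NeutralSimSpec(n_taxa=50, n_samples=200, depth=5000, Nm=5000,
                              seed=4, shape_param=1.0)
        table = synth.simulate_neutral_table(spec)
        taxa = table.otu_ids[3:5]
        out = synth.plant_correlated_block(
            table, taxa, np.array([[1, 0.9], [0.9, 1]]), seed=4)
        r = sparcc_correlations(out, seed=4)
        logs = np.log(out.counts.to_numpy() + 1.0)
        clr = logs - logs.mean(axis=1, keepdims=True)
        i, j = out.otu_ids.index(taxa[0]), out.otu_ids.index(taxa[1])
        r_clr = np.corrcoef(clr[:, i], clr[:, j])[0, 1]
        assert abs(r.loc[taxa[0], taxa[1]] - r_clr) < 0.15


class TestSparCCPValues:
    def test_planted_pair_attains_minimum_p(self):
        spec = NeutralSimSpec(n_taxa=15, n_samples=120, depth=3000, Nm=3000,
                              seed=5, shape_param=1.0)
        table = synth.simulate_neutral_table(spec)
        taxa = table.otu_ids[1:3]
        out = synth.plant_correlated_block(
            table, taxa, np.array([[1, 0.95], [0.95, 1]]), seed=5)
        r = sparcc_correlations(out, seed=5)
        p = sparcc_pvalues(out, r, n_perm=20, seed=5)
        assert p.loc[taxa[0], taxa[1]] == pytest.approx(1.0 / 21.0)
        assert ((p.to_numpy() > 0) & (p.to_numpy() <= 1)).all()


class TestBuildNetwork:
    def _rp(self, r01, p01):
        ids = ["a", "b", "c", "d"]
        r = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((4, 4)), index=ids, columns=ids)
        r.iloc[0, 1] = r.iloc[1, 0] = r01
        p.iloc[0, 1] = p.iloc[1, 0] = p01
        return r, p

    def test_edge_kept_and_dropped(self):
        g = build_network(*self._rp(0.61, 0.01))
        assert g.has_edge("a", "b")
        g = build_network(*self._rp(0.61, 0.06))
        assert g.number_of_edges() == 0
        g = build_network(*self._rp(0.59, 0.01))
        assert g.number_of_edges() == 0

    def test_negative_edge_kept_with_sign(self):
        g = build_network(*self._rp(-0.7, 0.01))
        assert g.edges[("a", "b")]["sign"] == "-"
        g2 = build_network(*self._rp(-0.7, 0.01), positive_only=True)
        assert g2.number_of_edges() == 0


class TestNetworkSummary:
    def test_triangle(self):
        g = nx.complete_graph(3)
        s = network_summary(g)
        assert s["mean_degree"] == 2 and s["clustering_coefficient"] == 1
        assert s["diameter"] == 1

    def test_path_of_four(self):
        s = network_summary(nx.path_graph(4))
        assert s["diameter"] == 3
        assert s["mean_degree"] == pytest.approx(1.5)
        assert s["clustering_coefficient"] == 0

    def test_mean_degree_identity(self):
        assert round(mean_degree(110, 174), 3) == 3.164
        assert round(mean_degree(216, 629), 3) == 5.824


class TestGraphMetricOracle:
    def test_matches_brute_force_on_random_graphs(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 15))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2 ** 31)))
            metrics = node_metrics(g)
            oracle = brute_force_metrics(list(g.edges), list(g.nodes))
            for v in g.nodes:
                assert metrics.loc[v, "degree"] == oracle["degree"][v]
                assert metrics.loc[v, "betweenness"] == pytest.approx(
                    oracle["betweenness"][v], abs=1e-9)
                assert metrics.loc[v, "closeness"] == pytest.approx(
                    oracle["closeness"][v], abs=1e-9)
                assert metrics.loc[v, "clustering"] == pytest.approx(
                    oracle["clustering"][v], abs=1e-9)
            if g.number_of_nodes():
                assert network_summary(g)["diameter"] == oracle["diameter"]


class TestRoles:
    def test_star_center_is_hub_not_keystone(self):
        g = nx.star_graph(9)
        roles = classify_roles(node_metrics(g))
        assert roles.loc[0, "role"] == "hub"

    def test_keystone_on_constructed_graph(self):
        # two 5-cliques joined by a 2-node bridge chain: interior clique
        # members have high degree + closeness but zero betweenness ->
        # keystone; the clique gateways have top betweenness -> hub
        g = nx.Graph()
        g.add_edges_from([(a, b) for a in range(5) for b in range(a + 1, 5)])
        g.add_edges_from([(a, b) for a in range(5, 10) for b in range(a + 1, 10)])
        g.add_edges_from([(0, 10), (10, 11), (11, 5)])
        roles = classify_roles(node_metrics(g))
        assert set(roles.index[roles["role"] == "hub"]) == {0, 5}
        assert set(roles.index[roles["role"] == "keystone"]) == set(
            range(1, 5)) | set(range(6, 10))

    def test_roles_match_percentile_oracle_on_toy_graph(self):
        g = nx.Graph()
        g.add_edges_from([(a, b) for a in range(5) for b in range(a + 1, 5)])
        g.add_edges_from([(a, b) for a in range(5, 10) for b in range(a + 1, 10)])
        g.add_edges_from([(0, 10), (10, 5), (10, 11)])
        metrics = node_metrics(g)
        roles = classify_roles(metrics)

        # brute-force oracle: independent percentile computation
        import math
        def top_set(series, frac=0.3):
            k = math.ceil(frac * len(series))
            cut = sorted(series)[len(series) - k]
            return {v for v in series.index if series[v] >= cut}

        def bottom_set(series, frac=0.3):
            k = math.ceil(frac * len(series))
            cut = sorted(series)[k - 1]
            return {v for v in series.index if series[v] <= cut}

        hubs = top_set(metrics["degree"]) & top_set(metrics["betweenness"])
        keystones = (top_set(metrics["degree"]) & top_set(metrics["closeness"])
                     & bottom_set(metrics["betweenness"])) - hubs
        assert set(roles.index[roles["role"] == "hub"]) == hubs
        assert set(roles.index[roles["role"] == "keystone"]) == keystones

    def test_hub_keystone_disjoint_on_random_graphs(self, rng):
        for _ in range(25):
            g = nx.gnp_random_graph(int(rng.integers(5, 20)), 0.3,
                                    seed=int(rng.integers(2 ** 31)))
            if g.number_of_edges() == 0:
                continue
            roles = classify_roles(node_metrics(g))
            assert not ((roles["role"] == "hub")
                        & (roles["role"] == "keystone")).any()
            counts = roles["role"].value_counts()
            assert counts.get("hub", 0) + counts.get("keystone", 0) <= len(roles)

    def test_invariant_to_monotone_rescaling(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        metrics = node_metrics(g)
        rescaled = metrics.copy()
        for col in ("degree", "betweenness", "closeness"):
            rescaled[col] = np.exp(metrics[col])
        r1 = classify_roles(metrics)["role"]
        r2 = classify_roles(rescaled)["role"]
        assert (r1 == r2).all()


class TestOverlayFunctions:
    def test_fraction_counting(self):
        g = nx.path_graph(10)
        g = nx.relabel_nodes(g, {i: f"O{i}" for i in range(10)})
        fn = pd.DataFrame({
            "otu_id": [f"O{i}" for i in range(6)],
            "pathway": ["ASR"] * 6,
            "present": [True] * 6,
        })
        fractions = overlay_functions(g, fn)
        assert fractions["ASR"] == pytest.approx(0.6)
        assert g.nodes["O0"]["ASR"] and not g.nodes["O7"]["ASR"]

    def test_all_annotated_fraction_one(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"O{i}" for i in range(4)})
        fn = pd.DataFrame({"otu_id": [f"O{i}" for i in range(4)],
                           "pathway": ["DSR"] * 4, "present": [True] * 4})
        assert overlay_functions(g, fn)["DSR"] == 1.0

    def test_empty_table_warns_and_returns_nothing(self):
        assert overlay_functions(nx.path_graph(3), pd.DataFrame()) == {}
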