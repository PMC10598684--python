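"""Modular graphs, modularity, label baselines and expression simulation."""

import numpy as np
import pytest

import networkx as nx

from graphtexture.cooccurrence import count_cooccurrence, normalize
from graphtexture.graph import NodeWeightedGraph, summary_statistics
from graphtexture.synthetic import (
    ExpressionSimSpec,
    ModularGraphSpec,
    add_uniform_noise,
    assign_cluster_labels,
    benchmark_modular_graph,
    bootstrap_labels,
    expected_planted_modularity,
    modular_graph,
    newman_modularity,
    permute_labels,
    simulate_expression,
    solve_between_probability,
)
from graphtexture.texture import energy


def two_cliques():
    """Two disconnected 4-cliques: planted modularity exactly 0.5."""
    nodes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    edges = [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
    edges += [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
    partition = {n: 0 if n.startswith("a") else 1 for n in nodes}
    return NodeWeightedGraph(nodes, edges), partition


class TestModularity:
    def test_two_disconnected_cliques_is_half(self):
        g, part = two_cliques()
        assert newman_modularity(g, part) == pytest.approx(0.5)

    def test_single_module_partition_is_zero(self):
        g, _ = two_cliques()
        assert newman_modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_agrees_with_networkx_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            nxg = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            if nxg.number_of_edges() == 0:
                continue
            g = NodeWeightedGraph(
                [str(v) for v in nxg.nodes],
                [(str(u), str(v)) for u, v in nxg.edges],
            )
            labels = rng.integers(0, 3, size=n)
            part = {str(v): int(labels[k]) for k, v in enumerate(nxg.nodes)}
            communities = [
                {v for v in nxg.nodes if part[str(v)] == c} for c in range(3)
            ]
            communities = [c for c in communities if c]
            expected = nx.algorithms.community.modularity(nxg, communities)
            assert newman_modularity(g, part) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_rejected(self):
        g = NodeWeightedGraph(["a"], [])
        with pytest.raises(Exception):
            newman_modularity(g, {"a": 0})


class TestModularGraph:
    def test_two_planted_cliques_recovered(self):
        spec = ModularGraphSpec(
            n_modules=2, module_sizes=(4, 4), p_within=1.0, p_between=0.0, seed=0
        )
        g, part, q = modular_graph(spec)
        assert q == pytest.approx(0.5)

    def test_complete_graph_limit_has_no_structure(self):
        spec = ModularGraphSpec(
            n_modules=2, module_sizes=(5, 5), p_within=1.0, p_between=1.0, seed=0
        )
        _, _, q = modular_graph(spec)
        assert q <= 0.0 + 1e-12

    def test_default_spec_mean_modularity_at_least_half(self):
        qs = [modular_graph(ModularGraphSpec(seed=s))[2] for s in range(20)]
        assert np.mean(qs) >= 0.5

    def test_solver_hits_target_expected_modularity(self):
        p = solve_between_probability(0.7, 4, 16, 0.6)
        assert expected_planted_modularity(4, 16, 0.6, p) == pytest.approx(0.7)

    def test_benchmark_graph_levels_and_modularity(self):
        g, part, q = benchmark_modular_graph(seed=1)
        assert sorted(set(g.weights.values())) == [1.0, 2.0, 3.0, 4.0]
        assert 0.5 <= q <= 0.8
        assert summary_statistics(g).diameter is not None  # connected


class TestClusterLabels:
    def test_levels_follow_modules(self):
        g, part = two_cliques()
        labelled = assign_cluster_labels(g, part, {0: 1, 1: 2})
        assert all(
            labelled.weights[n] == (1 if n.startswith("a") else 2) for n in g.nodes
        )

    def test_missing_module_level_errors(self):
        g, part = two_cliques()
        with pytest.raises(Exception, match="module"):
            assign_cluster_labels(g, part, {0: 1})

    def test_no_same_cluster_neighbours_gives_zero_diagonal_high_energy(self):
        """A star-of-clusters where neighbours never share a cluster puts all
        co-occurrence mass off the diagonal."""
        nodes = ["hub"] + [f"leaf{i}" for i in range(6)]
        edges = [("hub", f"leaf{i}") for i in range(6)]
        g = NodeWeightedGraph(nodes, edges)
        part = {"hub": 0, **{f"leaf{i}": 1 for i in range(6)}}
        labelled = assign_cluster_labels(g, part, {0: 1, 1: 2})
        P = normalize(count_cooccurrence(labelled))
        assert np.trace(P.p) == 0.0
        assert energy(P) == pytest.approx(0.5)


class TestNoise:
    def test_zero_amplitude_is_identity(self):
        g, part = two_cliques()
        labelled = assign_cluster_labels(g, part, {0: 1, 1: 2})
        assert add_uniform_noise(labelled, 0.0, seed=1) is labelled

    def test_noise_bounded_by_amplitude_times_range(self):
        g, part = two_cliques()
        labelled = assign_cluster_labels(g, part, {0: 1, 1: 4})
        a = 0.5
        noisy = add_uniform_noise(labelled, a, seed=2)
        w = noisy.weight_array()
        assert w.min() >= 1 - a * 3 - 1e-12 and w.max() <= 4 + a * 3 + 1e-12

    def test_noise_is_zero_mean(self):
        nodes = [f"n{i}" for i in range(10**4)]
        g = NodeWeightedGraph(nodes, [(nodes[0], nodes[1])],
                              weights={n: 0.0 for n in nodes})
        g = g.with_weights({**g.weights, nodes[0]: 1.0})  # range R = 1
        noisy = add_uniform_noise(g, 1.0, seed=3)
        u = noisy.weight_array() - g.weight_array()
        se = 1.0 / np.sqrt(3 * len(u))  # sd of U(-1,1) is 1/sqrt(3)
        assert abs(u.mean()) < 3 * se


class TestLabelBaselines:
    def _labelled(self):
        g, part = two_cliques()
        return assign_cluster_labels(g, part, {0: 1, 1: 2})

    def test_permutation_preserves_weight_multiset(self):
        g = self._labelled()
        p = permute_labels(g, seed=4)
        assert sorted(p.weights.values()) == sorted(g.weights.values())

    def test_baselines_never_change_topology(self):
        g = self._labelled()
        for perturbed in (permute_labels(g, seed=5), bootstrap_labels(g, seed=5)):
            assert summary_statistics(perturbed) == summary_statistics(g)

    def test_bootstrap_draws_from_original_multiset(self):
        g = self._labelled()
        b = bootstrap_labels(g, seed=6)
        assert set(b.weights.values()) <= set(g.weights.values())

    def test_constant_graph_unchanged_by_either(self):
        g, part = two_cliques()
        const = assign_cluster_labels(g, part, {0: 3, 1: 3})
        assert permute_labels(const, seed=7).weights == const.weights
        assert bootstrap_labels(const, seed=7).weights == const.weights

    def test_bootstrap_frequencies_match_original(self):
        g = self._labelled()  # half weight-1, half weight-2
        rng = np.random.default_rng(8)
        ones = 0
        draws = 10_000
        for _ in range(draws // g.n_nodes):
            b = bootstrap_labels(g, seed=int(rng.integers(2**31)))
            ones += sum(1 for w in b.weights.values() if w == 1)
        frac = ones / (draws // g.n_nodes * g.n_nodes)
        assert abs(frac - 0.5) < 0.02

    def test_randomized_labels_lower_energy_on_benchmark(self):
        """Ordered module labels concentrate pair mass; permutation spreads it."""
        g, _, _ = benchmark_modular_graph(seed=9)
        orig = energy(normalize(count_cooccurrence(g, n_levels=4)))
        rng = np.random.default_rng(10)
        perm = [
            energy(
                normalize(
                    count_cooccurrence(
                        permute_labels(g, seed=int(rng.integers(2**31))), n_levels=4
                    )
                )
            )
            for _ in range(100)
        ]
        assert np.mean(perm) < orig


class TestExpressionSimulation:
    def _wiring(self):
        g, _, _ = benchmark_modular_graph(seed=21)
        return g

    def test_rho_bounds_enforced(self):
        g = self._wiring()
        with pytest.raises(ValueError):
            ExpressionSimSpec(graph=g, rho=1.2)

    def test_edge_correlation_matches_rho(self):
        g = self._wiring()
        draws, nodes = simulate_expression(
            ExpressionSimSpec(graph=g, rho=0.5, n_samples=10_000, seed=12)
        )
        idx = {n: k for k, n in enumerate(nodes)}
        errs = []
        for u, v in list(g.edges)[:40]:
            r = np.corrcoef(draws[:, idx[u]], draws[:, idx[v]])[0, 1]
            errs.append(r - 0.5)
        assert abs(np.mean(errs)) < 0.02

    def test_small_rho_decorrelates(self):
        g = self._wiring()
        draws, nodes = simulate_expression(
            ExpressionSimSpec(graph=g, rho=0.01, n_samples=10_000, seed=13)
        )
        idx = {n: k for k, n in enumerate(nodes)}
        u, v = g.edges[0]
        r = np.corrcoef(draws[:, idx[u]], draws[:, idx[v]])[0, 1]
        assert abs(r) < 0.05

    def test_disconnected_wiring_rejected(self):
        g = NodeWeightedGraph(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
        with pytest.raises(Exception, match="connected"):
            simulate_expression(ExpressionSimSpec(graph=g, rho=0.5, n_samples=2))

    def test_replicates_attach_as_weights(self):
        g = self._wiring()
        draws, nodes = simulate_expression(
            ExpressionSimSpec(graph=g, rho=0.4, n_samples=3, seed=14)
        )
        attached = g.with_weights(dict(zip(nodes, draws[0])))
        assert attached.weight_array(nodes) == pytest.approx(draws[0])
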