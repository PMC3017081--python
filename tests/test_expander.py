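import itertools

import networkx as nx
import numpy as np
import pytest

import _oracles as oracle
from pathexpand.expander import (
    ExtensionConfig,
    candidate_set,
    compact_score,
    evaluate_candidate,
    extend_collection,
    extend_set,
    first_filter,
)
from pathexpand.netio import GeneSet


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t1": 0.0},
            {"t2": 0.0},
            {"t2": 1.0},
            {"t3": 1.0},  # full coverage is the maximum, threshold must be below it
            {"min_set_size": 1},
            {"unreachable_penalty_mode": "bogus"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExtensionConfig(**kwargs)


class TestCandidateSet:
    def test_star_centre_in_set(self, star4):
        assert candidate_set(star4, {"hub"}) == {"l1", "l2", "l3"}

    def test_isolated_members(self):
        g = nx.Graph([("x", "y")])
        g.add_node("iso")
        assert candidate_set(g, {"iso"}) == set()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = oracle.random_graph(rng, max_nodes=10)
            nodes = sorted(g.nodes)
            members = set(nodes[: len(nodes) // 2])
            assert candidate_set(g, members) == oracle.brute_candidates(g, members)


def graph_with_candidate(in_links: int, out_links: int, set_size: int):
    """Candidate 'v' with the given link counts into/out of a mapped set."""
    g = nx.Graph()
    members = [f"m{i}" for i in range(set_size)]
    g.add_nodes_from(members)
    for m in members[:in_links]:
        g.add_edge("v", m)
    for i in range(out_links):
        g.add_edge("v", f"o{i}")
    return g, set(members)


class TestEvaluateCandidate:
    def test_condition2_pass(self):
        g, members = graph_with_candidate(3, 1, 5)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert 2 in stats.passed_conditions  # 3 > 1 * 1

    def test_condition2_strict_inequality(self):
        g, members = graph_with_candidate(2, 2, 5)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert 2 not in stats.passed_conditions  # 2 is not > 2

    def test_condition2_zero_outside_counts_as_pass(self):
        g, members = graph_with_candidate(2, 0, 5)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert 2 in stats.passed_conditions

    def test_condition4_node_coverage(self):
        g, members = graph_with_candidate(4, 0, 10)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert 4 in stats.passed_conditions  # 4/10 = 0.4 > 0.3
        g, members = graph_with_candidate(3, 0, 10)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert 4 not in stats.passed_conditions  # 0.3 is not > 0.3

    def test_condition3_single_realised_triangle(self):
        # v adjacent to set node u and candidate w; u-w edge closes the
        # only potential triangle, so the ratio is 1.0 > 0.1
        g = nx.Graph()
        g.add_edges_from([("v", "u"), ("v", "w"), ("u", "w"), ("u", "m2"), ("m2", "m3")])
        members = {"u", "m2", "m3"}
        pool = candidate_set(g, members)
        stats = evaluate_candidate(g, members, pool, "v")
        assert stats.triangle_links == 1 and stats.possible_triangles == 1
        assert 3 in stats.passed_conditions

    def test_link_count_partition(self):
        g, members = graph_with_candidate(3, 2, 6)
        stats = evaluate_candidate(g, members, candidate_set(g, members), "v")
        assert stats.process_links + stats.outside_links == stats.degree
        assert stats.triangle_links <= stats.possible_triangles

    def test_unknown_candidate_rejected(self):
        g, members = graph_with_candidate(2, 1, 4)
        with pytest.raises(ValueError):
            evaluate_candidate(g, members, candidate_set(g, members), "m0")


class TestFirstFilter:
    def test_degree_one_candidate_rejected(self):
        g = nx.Graph([("v", "m0"), ("m0", "m1")])
        admitted, diags = first_filter(g, {"m0", "m1"})
        assert admitted == []
        (stats,) = [d for d in diags if d.candidate == "v"]
        assert 1 not in stats.passed_conditions
        assert 2 in stats.passed_conditions  # would pass otherwise

    def test_condition3_alone_admits(self):
        g = nx.Graph()
        g.add_edges_from(
            [("v", "u"), ("v", "w"), ("u", "w"),
             ("u", "m2"), ("m2", "m3"), ("m3", "m4"), ("m4", "m5"),
             ("v", "o1"), ("v", "o2"), ("v", "o3")]
        )
        members = {"u", "m2", "m3", "m4", "m5"}
        admitted, _ = first_filter(g, members)
        (stats,) = [a for a in admitted if a.candidate == "v"]
        assert stats.passed_conditions & {2, 4} == set()
        assert 3 in stats.passed_conditions

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g = oracle.random_graph(rng, max_nodes=15)
            nodes = sorted(g.nodes)
            members = set(rng.choice(nodes, size=min(5, len(nodes) - 1), replace=False))
            admitted, _ = first_filter(g, members)
            assert {a.candidate for a in admitted} == oracle.brute_filter(
                g, members, 1.0, 0.1, 0.3
            )


class TestCompactScore:
    def test_clique_is_one(self):
        assert compact_score(nx.complete_graph(3), [0, 1, 2]) == 1.0

    def test_path_example(self, path_graph):
        assert compact_score(path_graph, {"a", "b", "c"}) == pytest.approx(4 / 3)

    def test_unreachable_pair_penalty_node_count(self):
        g = nx.Graph()
        nx.add_path(g, [f"p{i}" for i in range(18)])
        g.add_edge("x", "y")  # 20 nodes total, {p0, x} unreachable
        assert compact_score(g, {"p0", "x"}) == pytest.approx(20.0)

    def test_unreachable_pair_penalty_fixed(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        config = ExtensionConfig(unreachable_penalty_mode="fixed", fixed_penalty=99.0)
        assert compact_score(g, {"a", "x"}, config) == pytest.approx(99.0)

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError):
            compact_score(nx.complete_graph(3), [0])


class TestExtendSet:
    def test_clique_without_improving_candidate(self):
        g = nx.complete_graph(5)
        res = extend_set(g, set(range(5)))
        assert res.added == () and len(res.compactness_trajectory) == 1

    def test_bridging_hub_added_first(self):
        # two disconnected triangles plus a hub adjacent to all six members:
        # connecting the components is by far the largest compactness drop
        g = nx.Graph()
        for offset in (0, 3):
            for i, j in itertools.combinations(range(offset, offset + 3), 2):
                g.add_edge(f"m{i}", f"m{j}")
        members = {f"m{i}" for i in range(6)}
        for m in members:
            g.add_edge("hub", m)
        g.add_edge("hub", "outside")
        res = extend_set(g, members)
        assert res.added and res.added[0] == "hub"
        assert res.added == tuple(oracle.brute_greedy_extension(g, members))

    def test_trajectory_strictly_decreasing_and_added_pass_filter(self, planted):
        network, sets, _ = planted
        from pathexpand.netio import map_gene_set

        for gs in sets:
            res = extend_set(network, map_gene_set(network, gs))
            traj = res.compactness_trajectory
            assert all(b < a for a, b in zip(traj, traj[1:]))
            assert len(traj) == len(res.added) + 1
            admitted = {
                s.candidate for s in res.candidate_diagnostics if s.admitted
            }
            assert set(res.added) <= admitted
            assert set(res.added) <= candidate_set(network, res.original_mapped)
            assert not set(res.added) & res.original_mapped

    def test_deterministic(self, planted):
        network, sets, _ = planted
        from pathexpand.netio import map_gene_set

        mapped = map_gene_set(network, sets[0])
        assert extend_set(network, mapped) == extend_set(network, mapped)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            g = oracle.random_graph(rng, max_nodes=12)
            nodes = sorted(g.nodes)
            size = int(rng.integers(2, 6))
            members = set(rng.choice(nodes, size=min(size, len(nodes) - 1), replace=False))
            res = extend_set(g, members)
            assert list(res.added) == oracle.brute_greedy_extension(g, members)

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError):
            extend_set(nx.complete_graph(4), {0})


class TestExtendCollection:
    def test_min_size_skip(self):
        g = nx.complete_graph(6)
        gs = GeneSet("small", "s", frozenset(str(i) for i in range(5)))
        results, summary = extend_collection(g, [gs])
        assert summary.n_examined == 0 and results == []

    def test_unique_added_counting(self):
        # two 3-cliques sharing the bridging hub as their best extension
        g = nx.Graph()
        for offset, label in ((0, "a"), (3, "b")):
            for i, j in itertools.combinations(range(3), 2):
                g.add_edge(f"{label}{i}", f"{label}{j}")
        for n in [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]:
            g.add_edge("hub", n)
        g.add_edge("hub", "x")
        sets = [
            GeneSet("A", "A", frozenset({"a0", "a1", "a2", "x"})),
            GeneSet("B", "B", frozenset({"b0", "b1", "b2", "x"})),
        ]
        config = ExtensionConfig(min_set_size=3)
        results, summary = extend_collection(g, sets, config)
        added = [set(r.added) for r in results]
        assert all("hub" in a for a in added)
        assert summary.total_added == sum(len(a) for a in added)
        assert summary.unique_added == len(set().union(*added))

    def test_planted_summary(self, planted):
        network, sets, truth = planted
        results, summary = extend_collection(network, sets)
        assert summary.n_examined == 5
        assert summary.avg_size_before == pytest.approx(18.0)
        hidden = set().union(*truth.hidden_members.values())
        recovered = set().union(*(set(r.added) for r in results)) & hidden
        assert recovered  # planted communities are partially recovered
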