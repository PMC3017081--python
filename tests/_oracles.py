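"""Independent brute-force reference implementations used by the tests.

Everything here is written from first principles (exhaustive enumeration,
dense linear algebra, direct tail summation) and deliberately shares no code
with the package under test.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


# ---------------------------------------------------------------- topology


def brute_betweenness(graph: nx.Graph, v) -> float:
    """Sum over unordered pairs (s,t), s,t != v, of the fraction of shortest
    s-t paths passing through v, by explicit path enumeration."""
    total = 0.0
    nodes = [n for n in graph.nodes if n != v]
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


def brute_clustering(graph: nx.Graph, v) -> float:
    neigh = list(graph.neighbors(v))
    k = len(neigh)
    if k < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(neigh, 2) if graph.has_edge(a, b)
    )
    return 2.0 * links / (k * (k - 1))


def floyd_warshall_distances(graph: nx.Graph) -> dict:
    """All-pairs shortest paths by the Floyd-Warshall recurrence."""
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for a, b in graph.edges:
        d[idx[a]][idx[b]] = 1
        d[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return {
        (a, b): int(d[idx[a]][idx[b]])
        for a in nodes
        for b in nodes
        if d[idx[a]][idx[b]] < inf
    }


def dense_eigenvector(graph: nx.Graph) -> dict:
    """Per-component principal eigenvector via numpy dense eigendecomposition,
    non-negative, unit Euclidean norm per component."""
    scores = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            scores[comp[0]] = 1.0
            continue
        a = nx.to_numpy_array(graph, nodelist=comp)
        vals, vecs = np.linalg.eigh(a)
        vec = vecs[:, np.argmax(vals)]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)  # Perron vector is non-negative
        vec = vec / np.linalg.norm(vec)
        scores.update(dict(zip(comp, vec)))
    return scores


# ---------------------------------------------------------------- expander


def brute_candidates(graph: nx.Graph, members: set) -> set:
    return {
        n
        for n in graph.nodes
        if n not in members and any(graph.has_edge(n, m) for m in members)
    }


def brute_filter(graph: nx.Graph, members: set, t1: float, t2: float, t3: float) -> set:
    """Admitted candidate set by direct evaluation of the four conditions."""
    pool = brute_candidates(graph, members)
    admitted = set()
    for v in pool:
        neigh = set(graph.neighbors(v))
        degree = len(neigh)
        process = len(neigh & members)
        outside = degree - process
        in_neigh = neigh & members
        cand_neigh = (neigh & pool) - {v}
        tri = sum(
            1
            for u in in_neigh
            for w in cand_neigh
            if graph.has_edge(u, w)
        )
        possible = len(in_neigh) * len(cand_neigh)
        c1 = degree > 1
        c2 = process > t1 * outside if outside else process > 0
        c3 = possible > 0 and tri / possible > t2
        c4 = process / len(members) > t3
        if c1 and (c2 or c3 or c4):
            admitted.add(v)
    return admitted


def brute_compact_score(graph: nx.Graph, node_set: set, penalty: float) -> float:
    nodes = sorted(node_set)
    dist = floyd_warshall_distances(graph)
    total = sum(
        dist.get((a, b), penalty) for a, b in itertools.combinations(nodes, 2)
    )
    n = len(nodes)
    return total / comb(n, 2)


def brute_greedy_extension(
    graph: nx.Graph, members: set, t1=1.0, t2=0.1, t3=0.3
) -> list:
    """Full extension by exhaustive re-scoring of every remaining candidate."""
    penalty = graph.number_of_nodes()
    admitted = brute_filter(graph, members, t1, t2, t3)
    current = set(members)
    score = brute_compact_score(graph, current, penalty)
    added = []
    remaining = set(admitted)
    while remaining:
        scored = sorted(
            (brute_compact_score(graph, current | {v}, penalty), v)
            for v in remaining
        )
        best_score, best = scored[0]
        if not best_score < score:
            break
        current.add(best)
        score = best_score
        added.append(best)
        remaining.remove(best)
    return added


# ---------------------------------------------------------------- statistics


def tail_sum_hypergeom(universe: int, set_size: int, list_size: int, overlap: int) -> float:
    """P(X >= overlap) by direct summation of hypergeometric point masses."""
    total = 0.0
    upper = min(set_size, list_size)
    denom = comb(universe, list_size)
    for k in range(overlap, upper + 1):
        if universe - set_size >= list_size - k >= 0:
            total += comb(set_size, k) * comb(universe - set_size, list_size - k) / denom
    return total


def stepup_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------- ontology


def brute_jc(ontology, index_usage, namespace_totals, t1, t2) -> float:
    """Jiang-Conrath distance by enumerating every common ancestor."""
    from math import log

    def ic(t):
        ns = ontology.namespace[t]
        return -log(index_usage[t] / namespace_totals[ns])

    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    mica = max(ic(t) for t in common if index_usage.get(t, 0) > 0)
    return ic(t1) + ic(t2) - 2 * mica


def annotation_usage(ontology, annotations):
    """(usage counts, per-namespace totals) by explicit descendant closure."""
    usage = {}
    for term in ontology.terms:
        desc = ontology.descendants(term)
        usage[term] = sum(
            1 for _, terms in annotations.items() if terms & desc
        )
    totals = {}
    for protein, terms in annotations.items():
        for ns in {ontology.namespace[t] for t in terms}:
            totals.setdefault(ns, set()).add(protein)
    return usage, {ns: len(ps) for ns, ps in totals.items()}


# ---------------------------------------------------------------- generators


def random_graph(rng: np.random.Generator, max_nodes: int = 12, p: float | None = None) -> nx.Graph:
    """Erdos-Renyi graph with a random size and density, labelled n00, n01..."""
    n = int(rng.integers(4, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.7)) if p is None else p
    graph = nx.Graph()
    names = [f"n{i:02d}" for i in range(n)]
    graph.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(names[i], names[j])
    return graph
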