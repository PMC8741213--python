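"""Independent brute-force oracles used by the graph tests.

Everything here works by exhaustive enumeration of simple paths with plain
recursion -- deliberately sharing no code path with the implementations it
checks.
"""

from __future__ import annotations

import random

import networkx as nx

TIE_TOL = 1e-12


def enumerate_simple_paths(G: nx.Graph, source, sink):
    """All simple source->sink paths as (total_weight, node_tuple), via DFS."""
    results = []

    def dfs(node, visited, weight, path):
        if node == sink:
            results.append((weight, tuple(path)))
            return
        for nbr in G[node]:
            if nbr not in visited:
                visited.add(nbr)
                path.append(nbr)
                dfs(nbr, visited, weight + G[node][nbr]["weight"], path)
                path.pop()
                visited.remove(nbr)

    dfs(source, {source}, 0.0, [source])
    return results


def brute_shortest(G, source, sink):
    paths = enumerate_simple_paths(G, source, sink)
    if not paths:
        return None
    return min(paths, key=lambda t: (t[0], t[1]))


def brute_k_shortest(G, source, sink, k):
    paths = enumerate_simple_paths(G, source, sink)
    return sorted(paths, key=lambda t: (t[0], t[1]))[:k]


def brute_edge_betweenness(G):
    """Fractional shortest-path crossing counts per edge, all pairs."""
    eb = {tuple(sorted(e)): 0.0 for e in G.edges}
    nodes = sorted(G.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_simple_paths(G, s, t)
            if not paths:
                continue
            wmin = min(w for w, _ in paths)
            shortest = [p for w, p in paths if w <= wmin + TIE_TOL]
            for p in shortest:
                for u, v in zip(p[:-1], p[1:]):
                    eb[tuple(sorted((u, v)))] += 1.0 / len(shortest)
    return eb


def random_connected_graph(seed: int, max_nodes: int = 8,
                           integer_weights: bool = False) -> nx.Graph:
    """Small random connected weighted graph (spanning tree + extra edges)."""
    rng = random.Random(seed)
    n = rng.randint(3, max_nodes)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    order = list(range(n))
    rng.shuffle(order)
    for a, b in zip(order[:-1], order[1:]):
        G.add_edge(a, b)
    extra = rng.randint(0, n * (n - 1) // 2 - (n - 1))
    candidates = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if not G.has_edge(i, j)]
    rng.shuffle(candidates)
    for e in candidates[:extra]:
        G.add_edge(*e)
    for u, v in G.edges:
        w = rng.randint(1, 5) if integer_weights else rng.uniform(0.1, 3.0)
        G[u][v]["weight"] = float(w)
        G[u][v]["gc"] = 0.5
    return G
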