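"""Optimal and suboptimal communication pathways through the dynamic network.

Because edge weights are w_ij = -log GC_ij, a minimum-weight path maximizes
the product of generalized correlations along its edges: the Dijkstra optimum
is the single most efficient channel of correlated motion between a signal
source and sink, and the k lowest-weight loopless paths (Yen's algorithm) are
its most likely suboptimal alternatives.  Accumulated per-residue occupancy
over all source/sink pairs highlights the residues that carry the signal.

For the Cas9 HNH domain the canonical endpoints are the REC-interface
residues 789 and 794 (sources) and the RuvC-interface residues 841 and 858
(sinks), with the 10 shortest paths kept per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice, product

import networkx as nx
import numpy as np

from .corrnet import DynamicNetwork
from .errors import InputError

#: canonical HNH endpoints: REC-facing sources, RuvC-facing sinks
DEFAULT_SOURCES = (789, 794)
DEFAULT_SINKS = (841, 858)
DEFAULT_K = 10


@dataclass(frozen=True)
class Path:
    """A loopless path with its total weight and rank among the k shortest."""

    nodes: tuple[int, ...]
    weight: float
    rank: int = 0

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class PathEnsemble:
    """The k shortest loopless paths for one source/sink pair."""

    source: int
    sink: int
    paths: list[Path] = field(default_factory=list)
    exhausted: bool = False  # fewer than k simple paths exist

    @property
    def optimal(self) -> Path | None:
        return self.paths[0] if self.paths else None

    def occupancy(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for p in self.paths:
            for node in p.nodes:
                counts[node] = counts.get(node, 0) + 1
        return counts


def _path_weight(G: nx.Graph, nodes) -> float:
    return float(sum(G[u][v]["weight"] for u, v in zip(nodes[:-1], nodes[1:])))


def _check_endpoints(net: DynamicNetwork, source: int, sink: int) -> None:
    for node in (source, sink):
        if node not in net.graph:
            raise InputError(f"node {node} is not in the network")


def shortest_path(net: DynamicNetwork, source: int, sink: int) -> Path | None:
    """Minimum-total-weight path; ties broken lexicographically by node
    sequence for reproducibility.  Returns None when no path exists."""
    _check_endpoints(net, source, sink)
    try:
        candidates = list(nx.all_shortest_paths(net.graph, source, sink,
                                                weight="weight"))
    except nx.NetworkXNoPath:
        return None
    best = min(candidates, key=tuple)
    return Path(nodes=tuple(best), weight=_path_weight(net.graph, best), rank=0)


def k_shortest_paths(net: DynamicNetwork, source: int, sink: int,
                     k: int = DEFAULT_K) -> PathEnsemble:
    """The k lowest-weight loopless paths (Yen), in nondecreasing weight order.

    Equal-weight paths are ordered lexicographically by node sequence.  If
    fewer than k simple paths exist the ensemble is flagged ``exhausted``.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    _check_endpoints(net, source, sink)
    ens = PathEnsemble(source=source, sink=sink)
    try:
        gen = nx.shortest_simple_paths(net.graph, source, sink, weight="weight")
        raw = list(islice(gen, k + 1))
    except nx.NetworkXNoPath:
        ens.exhausted = True
        return ens
    ens.exhausted = len(raw) <= k
    raw = raw[:k]
    scored = sorted(((_path_weight(net.graph, p), tuple(p)) for p in raw),
                    key=lambda t: (round(t[0], 12), t[1]))
    ens.paths = [Path(nodes=nodes, weight=w, rank=r)
                 for r, (w, nodes) in enumerate(scored)]
    return ens


def communication_pathways(net: DynamicNetwork,
                           sources=DEFAULT_SOURCES, sinks=DEFAULT_SINKS,
                           k: int = DEFAULT_K) -> list[PathEnsemble]:
    """k-shortest ensembles for the Cartesian product of sources and sinks."""
    return [k_shortest_paths(net, s, t, k=k) for s, t in product(sources, sinks)]


def path_occupancy(ensembles: list[PathEnsemble],
                   nodes=None) -> dict[int, int]:
    """Accumulated per-residue path counts over a list of ensembles.

    ``nodes`` optionally fixes the universe (zero counts included); by default
    the union of all member nodes with nonzero count is returned.
    """
    counts: dict[int, int] = {int(n): 0 for n in nodes} if nodes is not None else {}
    for ens in ensembles:
        for node, c in ens.occupancy().items():
            counts[node] = counts.get(node, 0) + c
    return counts


def ensembles_to_json(ensembles: list[PathEnsemble]) -> list[dict]:
    return [
        {
            "source": e.source,
            "sink": e.sink,
            "exhausted": e.exhausted,
            "paths": [{"nodes": list(map(int, p.nodes)),
                       "weight": p.weight, "rank": p.rank} for p in e.paths],
        }
        for e in ensembles
    ]


def occupancy_to_csv(counts: dict[int, int], path) -> None:
    import pandas as pd
    items = sorted(counts.items())
    pd.DataFrame(items, columns=["residue", "path_count"]).to_csv(path, index=False)
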