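"""Community structure of the dynamic network and mutation-induced changes.

Communities -- groups of residues whose motions are tightly synchronized --
are found with the divisive Girvan-Newman procedure: the edge of highest
weighted edge betweenness (EB; the number of all-pairs shortest paths
crossing the edge, with equal-weight ties split fractionally) is removed and
EB recomputed, until the partition of maximum modularity (or a requested
community count) is reached.  Shortest paths use the information-transfer
weights w = -log GC, while modularity is evaluated with the GC itself as the
connection strength.

The communication strength between two communities is the total EB summed
over their connecting edges.  Comparing a variant against the wild type on
the *wild-type* partition gives the mutation-induced change

    dEB(A, B) = EB_variant(A, B) - EB_WT(A, B),

normalized by the maximum absolute change of that comparison so values lie
in [-1, 1]: negative means loss of communication upon mutation, positive a
gain.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corrnet import DynamicNetwork
from .errors import InputError


@dataclass
class CommunityPartition:
    """Residue -> community assignment; community ids are dense integers
    ordered by each community's smallest member node."""

    assignment: dict[int, int]
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> list[int]:
        return sorted(n for n, c in self.assignment.items() if c == community)

    def community_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def as_array(self, nodes) -> np.ndarray:
        return np.array([self.assignment[int(n)] for n in nodes])

    def checksum(self) -> str:
        payload = ",".join(f"{n}:{c}" for n, c in sorted(self.assignment.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def label_of(self, community: int) -> str:
        return self.labels.get(community, f"C{community}")

    def with_labels(self, labels: dict[int, str]) -> "CommunityPartition":
        missing = set(self.community_ids()) - set(labels)
        if missing:
            raise InputError(f"labels missing for communities {sorted(missing)}")
        return CommunityPartition(assignment=dict(self.assignment), labels=dict(labels))

    def to_csv(self, path) -> None:
        rows = [(n, c, self.label_of(c)) for n, c in sorted(self.assignment.items())]
        pd.DataFrame(rows, columns=["residue", "community", "label"]).to_csv(
            path, index=False)


@dataclass
class EBMatrix:
    """Total edge betweenness between community pairs (diagonal = intra)."""

    communities: list[int]
    matrix: np.ndarray
    partition_checksum: str

    def total(self) -> float:
        off = np.triu(self.matrix, k=1).sum()
        return float(off + np.trace(self.matrix))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.communities,
                     columns=self.communities).to_csv(path)


@dataclass
class DeltaEBNetwork:
    """Variant-minus-WT change in inter-community communication."""

    communities: list[int]
    raw: np.ndarray
    normalized: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)
    include_diagonal: bool = False

    def pair_value(self, a: int, b: int, normalized: bool = True) -> float:
        ia, ib = self.communities.index(a), self.communities.index(b)
        return float((self.normalized if normalized else self.raw)[ia, ib])

    def max_abs_normalized(self) -> float:
        mat = self.normalized.copy()
        if not self.include_diagonal:
            np.fill_diagonal(mat, 0.0)
        return float(np.abs(mat).max())


def edge_betweenness(net: DynamicNetwork | nx.Graph) -> dict[tuple[int, int], float]:
    """Weighted EB per edge: the number of all-pairs shortest paths crossing
    it, equal-weight ties split fractionally.  Disconnected components are
    handled independently (no path crosses between them)."""
    G = net.graph if isinstance(net, DynamicNetwork) else net
    eb = nx.edge_betweenness_centrality(G, weight="weight", normalized=False)
    return {(min(u, v), max(u, v)): val for (u, v), val in eb.items()}


def _partition_from_components(G: nx.Graph) -> CommunityPartition:
    comps = sorted((sorted(c) for c in nx.connected_components(G)),
                   key=lambda c: c[0])
    assignment = {int(n): cid for cid, comp in enumerate(comps) for n in comp}
    return CommunityPartition(assignment=assignment)


def girvan_newman(net: DynamicNetwork, n_communities: int | None = None,
                  quality_weight: str = "gc") -> CommunityPartition:
    """Girvan-Newman partition with weighted EB as the removal criterion.

    Stops at the modularity maximum by default (modularity evaluated on the
    original graph with ``quality_weight`` as connection strength), or at a
    requested ``n_communities``.  Ties in EB are broken on the
    lexicographically smallest edge for reproducibility.
    """
    G0 = net.graph
    if G0.number_of_nodes() < 2:
        raise InputError("community detection needs at least 2 nodes")
    if n_communities is not None and n_communities > G0.number_of_nodes():
        raise InputError(
            f"requested {n_communities} communities from {G0.number_of_nodes()} nodes")
    work = G0.copy()
    qw = quality_weight if quality_weight else None
    best_partition = _partition_from_components(work)
    if n_communities is not None and best_partition.n_communities >= n_communities:
        return best_partition
    best_q = _modularity(G0, best_partition, qw)
    current_count = best_partition.n_communities
    while work.number_of_edges() > 0:
        eb = edge_betweenness(work)
        max_eb = max(eb.values())
        edge = min(e for e, v in eb.items() if v >= max_eb - 1e-12)
        work.remove_edge(*edge)
        part = _partition_from_components(work)
        if part.n_communities == current_count:
            continue
        current_count = part.n_communities
        if n_communities is not None:
            if current_count >= n_communities:
                return part
            continue
        q = _modularity(G0, part, qw)
        if q > best_q:
            best_q, best_partition = q, part
    if n_communities is not None:
        # ran out of edges before reaching the requested count
        return _partition_from_components(work)
    return best_partition


def _modularity(G: nx.Graph, partition: CommunityPartition, weight) -> float:
    groups = [set(partition.members(c)) for c in partition.community_ids()]
    return nx.community.modularity(G, groups, weight=weight)


def intercommunity_eb(net: DynamicNetwork, partition: CommunityPartition) -> EBMatrix:
    """Sum per-edge EB into a community x community matrix (intra on the
    diagonal).  The grand total equals the total EB over all edges."""
    uncovered = [n for n in net.graph.nodes if int(n) not in partition.assignment]
    if uncovered:
        raise InputError(f"partition does not cover nodes {sorted(uncovered)[:10]}")
    comms = partition.community_ids()
    index = {c: i for i, c in enumerate(comms)}
    mat = np.zeros((len(comms), len(comms)))
    for (u, v), val in edge_betweenness(net).items():
        a, b = index[partition.assignment[u]], index[partition.assignment[v]]
        if a == b:
            mat[a, a] += val
        else:
            mat[a, b] += val
            mat[b, a] += val
    return EBMatrix(communities=comms, matrix=mat,
                    partition_checksum=partition.checksum())


def delta_eb(eb_variant: EBMatrix, eb_wt: EBMatrix,
             labels: dict[int, str] | None = None,
             include_diagonal: bool = False) -> DeltaEBNetwork:
    """Variant-minus-WT EB change per community pair, on the WT partition.

    Both matrices must have been aggregated on the same (wild-type) reference
    partition.  The normalized matrix divides by max |raw| over the compared
    pairs (off-diagonal by default), so entries lie in [-1, 1]; an all-zero
    comparison stays all-zero.
    """
    if eb_variant.partition_checksum != eb_wt.partition_checksum:
        raise InputError("EB matrices were aggregated on different partitions; "
                         "recompute the variant on the WT reference partition")
    raw = eb_variant.matrix - eb_wt.matrix
    scale_mat = raw.copy()
    if not include_diagonal:
        np.fill_diagonal(scale_mat, 0.0)
    denom = np.abs(scale_mat).max()
    normalized = raw / denom if denom > 0 else np.zeros_like(raw)
    if not include_diagonal:
        # intra-community changes are excluded from the comparison entirely
        normalized = normalized.copy()
        np.fill_diagonal(normalized, 0.0)
    return DeltaEBNetwork(communities=list(eb_wt.communities), raw=raw,
                          normalized=normalized, labels=labels or {},
                          include_diagonal=include_diagonal)


def circular_export(delta: DeltaEBNetwork, labels: dict[int, str] | None = None,
                    path=None, threshold: float = 0.0) -> pd.DataFrame:
    """Edge list for circular plots: one row per community pair with
    |normalized dEB| above ``threshold`` (community_a, community_b, delta_eb,
    thickness, sign)."""
    labels = labels or delta.labels
    missing = set(delta.communities) - set(labels)
    if labels and missing:
        raise InputError(f"labels missing for communities {sorted(missing)}")
    rows = []
    n = len(delta.communities)
    for i in range(n):
        j0 = i if delta.include_diagonal else i + 1
        for j in range(j0, n):
            val = float(delta.normalized[i, j])
            if abs(val) > threshold:
                a, b = delta.communities[i], delta.communities[j]
                rows.append({
                    "community_a": labels.get(a, f"C{a}"),
                    "community_b": labels.get(b, f"C{b}"),
                    "delta_eb": val,
                    "thickness": abs(val),
                    "sign": "loss" if val < 0 else "gain",
                })
    df = pd.DataFrame(rows, columns=["community_a", "community_b",
                                     "delta_eb", "thickness", "sign"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_circular(path, communities: list[int] | None = None,
                  labels: dict[int, str] | None = None) -> DeltaEBNetwork:
    """Rebuild a (normalized-only) DeltaEBNetwork from a circular export."""
    df = pd.read_csv(path)
    if labels:
        inverse = {v: k for k, v in labels.items()}
    else:
        names = sorted(set(df["community_a"]) | set(df["community_b"]))
        inverse = {name: i for i, name in enumerate(names)}
    comms = communities if communities is not None else sorted(inverse.values())
    index = {c: i for i, c in enumerate(comms)}
    mat = np.zeros((len(comms), len(comms)))
    for _, row in df.iterrows():
        a, b = inverse[row["community_a"]], inverse[row["community_b"]]
        mat[index[a], index[b]] = mat[index[b], index[a]] = row["delta_eb"]
    return DeltaEBNetwork(communities=list(comms), raw=mat.copy(),
                          normalized=mat, labels=labels or {})
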