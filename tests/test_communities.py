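"""Edge betweenness, Girvan-Newman partitioning and the dEB network."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from allonet import communities as comm
from allonet.errors import InputError
from allonet.synthetic import planted_network
from conftest import net_from_graph
from oracles import brute_edge_betweenness, random_connected_graph


def test_eb_three_node_path():
    G = nx.Graph()
    nx.add_path(G, "abc", weight=1.0)
    eb = comm.edge_betweenness(net_from_graph(G))
    assert eb[("a", "b")] == pytest.approx(2.0)
    assert eb[("b", "c")] == pytest.approx(2.0)


def test_eb_single_edge():
    G = nx.Graph()
    G.add_edge(1, 2, weight=1.0)
    assert comm.edge_betweenness(net_from_graph(G))[(1, 2)] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(100))
def test_eb_matches_brute_force(seed):
    # integer weights on even seeds exercise the fractional tie-splitting
    G = random_connected_graph(seed, integer_weights=(seed % 2 == 0))
    eb = comm.edge_betweenness(net_from_graph(G))
    expected = brute_edge_betweenness(G)
    for edge, val in expected.items():
        assert eb[edge] == pytest.approx(val), f"edge {edge} seed {seed}"


def two_cliques_with_bridge():
    G = nx.Graph()
    for offset in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                G.add_edge(offset + i, offset + j, weight=1.0, gc=0.5)
    G.add_edge(4, 5, weight=1.0, gc=0.5)  # the bridge
    return net_from_graph(G)


def test_girvan_newman_splits_bridged_cliques():
    net = two_cliques_with_bridge()
    part = comm.girvan_newman(net)
    truth = [0] * 5 + [1] * 5
    found = part.as_array(sorted(net.graph.nodes))
    assert adjusted_rand_score(truth, found) == 1.0
    assert part.n_communities == 2


def test_fixed_community_count():
    net, _ = planted_network(n_residues=30, n_blocks=3, seed=0)
    part = comm.girvan_newman(net, n_communities=7)
    assert part.n_communities == 7
    with pytest.raises(InputError):
        comm.girvan_newman(net, n_communities=31)


def test_planted_partition_recovery_many_seeds():
    """ARI >= 0.9 on 3-block planted networks over 20 seeds."""
    aris = []
    for seed in range(20):
        net, blocks = planted_network(n_residues=60, n_blocks=3,
                                      gc_intra=0.8, gc_inter=0.1, seed=seed)
        part = comm.girvan_newman(net)
        found = part.as_array(net.residue_ids)
        aris.append(adjusted_rand_score(blocks, found))
    assert min(aris) >= 0.9


def test_components_never_merged():
    G = nx.Graph()
    nx.add_path(G, [1, 2, 3], weight=1.0)
    nx.add_path(G, [10, 11, 12], weight=1.0)
    for u, v in G.edges:
        G[u][v]["gc"] = 0.5
    part = comm.girvan_newman(net_from_graph(G))
    a = {part.assignment[n] for n in (1, 2, 3)}
    b = {part.assignment[n] for n in (10, 11, 12)}
    assert a.isdisjoint(b)


def test_intercommunity_eb_single_community_and_conservation():
    net = two_cliques_with_bridge()
    nodes = sorted(net.graph.nodes)
    one = comm.CommunityPartition(assignment={n: 0 for n in nodes})
    ebm = comm.intercommunity_eb(net, one)
    eb_total = sum(comm.edge_betweenness(net).values())
    assert ebm.matrix.shape == (1, 1)
    assert ebm.matrix[0, 0] == pytest.approx(eb_total)


def test_bridge_eb_lands_on_the_off_diagonal():
    net = two_cliques_with_bridge()
    part = comm.CommunityPartition(
        assignment={n: (0 if n < 5 else 1) for n in net.graph.nodes})
    ebm = comm.intercommunity_eb(net, part)
    bridge_eb = comm.edge_betweenness(net)[(4, 5)]
    assert ebm.matrix[0, 1] == pytest.approx(bridge_eb)
    total = np.triu(ebm.matrix, 1).sum() + np.trace(ebm.matrix)
    assert total == pytest.approx(sum(comm.edge_betweenness(net).values()))


def test_uncovered_node_rejected():
    net = two_cliques_with_bridge()
    part = comm.CommunityPartition(assignment={0: 0})
    with pytest.raises(InputError):
        comm.intercommunity_eb(net, part)


def _delta_fixture(gc_bridge_variant):
    """Two-clique networks where only the bridge GC differs."""
    def build(gc_bridge):
        net = two_cliques_with_bridge()
        net.graph[4][5]["gc"] = gc_bridge
        net.graph[4][5]["weight"] = -np.log(gc_bridge)
        return net
    net_wt, net_var = build(0.9), build(gc_bridge_variant)
    part = comm.girvan_newman(net_wt)
    eb_wt = comm.intercommunity_eb(net_wt, part)
    eb_var = comm.intercommunity_eb(net_var, part)
    return comm.delta_eb(eb_var, eb_wt), part


def test_delta_eb_null_is_zero():
    delta, _ = _delta_fixture(0.9)
    assert np.allclose(delta.raw, 0.0)
    assert np.allclose(delta.normalized, 0.0)


def test_delta_eb_sign_and_hand_value():
    # weakening the bridge reroutes nothing (it is the only inter-clique
    # link) but doubling its weight cannot change counts; instead remove it
    net_wt = two_cliques_with_bridge()
    part = comm.girvan_newman(net_wt)
    net_var = two_cliques_with_bridge()
    net_var.graph.remove_edge(4, 5)
    eb_wt = comm.intercommunity_eb(net_wt, part)
    eb_var = comm.intercommunity_eb(net_var, part)
    delta = comm.delta_eb(eb_var, eb_wt)
    # hand value: the bridge carried one shortest path per cross pair = 25
    assert eb_wt.matrix[0, 1] == pytest.approx(25.0)
    assert delta.raw[0, 1] == pytest.approx(-25.0)
    assert delta.normalized[0, 1] == pytest.approx(-1.0)
    assert delta.max_abs_normalized() <= 1.0


def test_delta_eb_partition_mismatch_rejected():
    net = two_cliques_with_bridge()
    p1 = comm.CommunityPartition(
        assignment={n: (0 if n < 5 else 1) for n in net.graph.nodes})
    p2 = comm.CommunityPartition(
        assignment={n: (0 if n < 4 else 1) for n in net.graph.nodes})
    with pytest.raises(InputError, match="partition"):
        comm.delta_eb(comm.intercommunity_eb(net, p1),
                      comm.intercommunity_eb(net, p2))


def test_normalized_delta_bounded_on_random_fixtures():
    rng = np.random.default_rng(0)
    for seed in range(5):
        net_wt, _ = planted_network(n_residues=30, n_blocks=3, seed=seed)
        net_var, _ = planted_network(n_residues=30, n_blocks=3, seed=seed + 100,
                                     gc_inter=0.05)
        part = comm.girvan_newman(net_wt)
        delta = comm.delta_eb(comm.intercommunity_eb(net_var, part),
                              comm.intercommunity_eb(net_wt, part))
        assert np.abs(delta.normalized).max() <= 1.0 + 1e-12


def test_circular_export_round_trip(tmp_path):
    delta, part = _delta_fixture(0.9)
    delta.raw[0, 1] = delta.raw[1, 0] = -10.0
    delta.normalized[0, 1] = delta.normalized[1, 0] = -1.0
    labels = {0: "A1", 1: "NA1"}
    path = tmp_path / "circ.csv"
    df = comm.circular_export(delta, labels=labels, path=path)
    assert len(df) == 1
    assert df.iloc[0]["sign"] == "loss"
    back = comm.read_circular(path, communities=[0, 1],
                              labels=labels)
    assert back.normalized[0, 1] == pytest.approx(-1.0)


def test_circular_export_zero_network_empty():
    delta, _ = _delta_fixture(0.9)
    assert comm.circular_export(delta).empty


def test_circular_export_missing_label_rejected():
    delta, _ = _delta_fixture(0.9)
    with pytest.raises(InputError):
        comm.circular_export(delta, labels={0: "A1"})
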