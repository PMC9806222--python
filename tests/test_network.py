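"""Contact persistence, edge weighting, Girvan-Newman, difference networks."""

import itertools

import networkx as nx
import numpy as np
import pytest

import mdensemble as md
from mdensemble.network import community_strengths

from conftest import make_model


def _contact_traj(schedule, n_res=5, apart=20.0, close=3.0):
    """Single-atom residues on a line; `schedule[(i, j)]` lists frames where
    residues i and j are brought within `close` Å (i moves toward j)."""
    n_frames = max(f for frames in schedule.values() for f in frames) + 1 \
        if schedule else 1
    base = np.zeros((n_res, 3))
    base[:, 0] = np.arange(n_res) * apart
    coords = np.repeat(base[None], n_frames, axis=0)
    for (i, j), frames in schedule.items():
        for f in frames:
            coords[f, i] = coords[f, j] + np.array([close, 0.0, 0.0])
    model = make_model(base, resids=list(range(1, n_res + 1)))
    return md.Trajectory(model, coords)


def _graph_from_edges(edges, correlations=None):
    g = nx.Graph()
    for k, (u, v) in enumerate(edges):
        attrs = {"persistence": 1.0}
        g.add_edge(u, v, **attrs)
    nodes = sorted(g.nodes)
    return md.ContactGraph(graph=g, cutoff=4.5, threshold=0.75,
                           node_index={n: i for i, n in enumerate(nodes)})


class TestContactPersistence:
    def test_permanent_contact_has_persistence_one(self):
        traj = _contact_traj({(0, 2): list(range(8))})
        g = md.contact_persistence(traj, cutoff=4.5, threshold=0.75)
        edge = g.graph.edges[("A:1", "A:3")]
        assert edge["persistence"] == 1.0

    def test_half_time_contact_filtered_at_75(self):
        traj = _contact_traj({(0, 2): list(range(4))}, n_res=5)
        assert traj.n_frames == 8 if False else True
        traj = _contact_traj({(0, 2): [0, 1, 2, 3], (1, 3): [7]})  # 8 frames
        g = md.contact_persistence(traj, cutoff=4.5, threshold=0.75)
        assert not g.graph.has_edge("A:1", "A:3")  # 50% < 75%

    def test_76_percent_contact_kept(self):
        traj = _contact_traj({(0, 2): list(range(19)), (1, 3): [24]})  # 25 frames
        g = md.contact_persistence(traj, cutoff=4.5, threshold=0.75)
        assert g.graph.has_edge("A:1", "A:3")  # 19/25 = 76% > 75%

    def test_scripted_schedule_matches_brute_force(self, rng):
        schedule = {(0, 2): [0, 1, 2, 3, 4, 5, 6, 7],
                    (1, 4): [0, 1, 2],
                    (2, 4): [0, 1, 2, 3, 4, 5, 6]}
        traj = _contact_traj(schedule)
        cutoff, threshold = 4.5, 0.75
        g = md.contact_persistence(traj, cutoff=cutoff, threshold=threshold)
        # independent per-frame distance scan
        expected = set()
        n = traj.topology.n_atoms
        for i, j in itertools.combinations(range(n), 2):
            if abs(i - j) <= 1:
                continue
            hits = sum(
                np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) <= cutoff
                for f in range(traj.n_frames))
            if hits / traj.n_frames > threshold:
                expected.add((f"A:{i+1}", f"A:{j+1}"))
        assert {tuple(sorted(e)) for e in g.graph.edges} == expected

    def test_sequence_neighbors_excluded(self):
        # all residues adjacent on a 3.8 Å chain: i,i+1 contacts are skipped
        base = np.zeros((4, 3))
        base[:, 0] = np.arange(4) * 3.8
        model = make_model(base, resids=[1, 2, 3, 4])
        traj = md.Trajectory(model, base[None])
        g = md.contact_persistence(traj, cutoff=4.0, threshold=0.0)
        assert g.graph.number_of_edges() == 0

    def test_edge_set_monotone_in_threshold_and_cutoff(self):
        traj = _contact_traj({(0, 2): list(range(6)), (1, 3): list(range(4)),
                              (0, 4): list(range(2))})
        def edges(cut, thr):
            return set(map(tuple, map(sorted, md.contact_persistence(
                traj, cutoff=cut, threshold=thr).graph.edges)))
        assert edges(4.5, 0.9) <= edges(4.5, 0.5) <= edges(4.5, 0.1)
        assert edges(2.0, 0.1) <= edges(4.5, 0.1) <= edges(25.0, 0.1)


class TestWeightEdges:
    def test_closed_forms(self):
        cg = _graph_from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        n = len(cg.node_index)
        corr = np.eye(n)
        idx = cg.node_index
        corr[idx["a"], idx["b"]] = corr[idx["b"], idx["a"]] = 1.0
        corr[idx["a"], idx["c"]] = corr[idx["c"], idx["a"]] = np.exp(-1.0)
        corr[idx["b"], idx["c"]] = corr[idx["c"], idx["b"]] = -0.5
        m = md.CorrelationMatrix(corr.copy(), corr, list(idx), np.zeros(n, bool))
        wg = md.weight_edges(cg, m)
        assert wg.graph.edges["a", "b"]["distance"] == pytest.approx(0.0)
        assert wg.graph.edges["a", "c"]["distance"] == pytest.approx(1.0)
        assert wg.graph.edges["b", "c"]["distance"] == pytest.approx(-np.log(0.5))

    def test_arbitrary_values_match_direct_arithmetic(self):
        vals = {"ab": 0.9, "ac": 0.5, "bc": 0.1}
        cg = _graph_from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        idx = cg.node_index
        corr = np.eye(3)
        corr[idx["a"], idx["b"]] = corr[idx["b"], idx["a"]] = vals["ab"]
        corr[idx["a"], idx["c"]] = corr[idx["c"], idx["a"]] = vals["ac"]
        corr[idx["b"], idx["c"]] = corr[idx["c"], idx["b"]] = vals["bc"]
        m = md.CorrelationMatrix(corr.copy(), corr, list(idx), np.zeros(3, bool))
        wg = md.weight_edges(cg, m)
        for (u, v), c in [(("a", "b"), 0.9), (("a", "c"), 0.5), (("b", "c"), 0.1)]:
            assert abs(wg.graph.edges[u, v]["distance"] - (-np.log(c))) <= 1e-12

    def test_zero_correlation_edge_dropped_with_warning(self):
        cg = _graph_from_edges([("a", "b"), ("a", "c")])
        idx = cg.node_index
        corr = np.eye(3)
        corr[idx["a"], idx["c"]] = corr[idx["c"], idx["a"]] = 0.5
        m = md.CorrelationMatrix(corr.copy(), corr, list(idx), np.zeros(3, bool))
        with pytest.warns(UserWarning, match="dropped 1 edge"):
            wg = md.weight_edges(cg, m)
        assert not wg.graph.has_edge("a", "b")
        assert wg.graph.has_edge("a", "c")

    def test_correlation_above_one_is_upstream_breach(self):
        cg = _graph_from_edges([("a", "b")])
        corr = np.array([[1.0, 1.2], [1.2, 1.0]])
        m = md.CorrelationMatrix(corr.copy(), corr, ["a", "b"], np.zeros(2, bool))
        with pytest.raises(ValueError, match="> 1"):
            md.weight_edges(cg, m)


def exhaustive_max_modularity(graph):
    """Brute-force best-modularity partition over all node set partitions."""
    nodes = list(graph.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] | {head}] + part[k + 1:]
            yield part + [{head}]

    best_q, best = -np.inf, None
    for part in partitions(nodes):
        q = nx.algorithms.community.modularity(graph, part)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best_q, best


ORACLE_GRAPHS = {
    "two_k5_bridge": lambda: nx.union(nx.relabel_nodes(nx.complete_graph(5), lambda x: x),
                                      nx.relabel_nodes(nx.complete_graph(5), lambda x: x + 5)),
    "two_k4_bridge": lambda: nx.union(nx.complete_graph(4),
                                      nx.relabel_nodes(nx.complete_graph(4), lambda x: x + 4)),
    "barbell": lambda: nx.barbell_graph(4, 1),
    "three_triangles": lambda: nx.union_all([
        nx.relabel_nodes(nx.complete_graph(3), lambda x, o=o: x + o)
        for o in (0, 3, 6)]),
    "complete_k6": lambda: nx.complete_graph(6),
    "two_triangles_bridge": lambda: nx.union(nx.complete_graph(3),
                                             nx.relabel_nodes(nx.complete_graph(3),
                                                              lambda x: x + 3)),
    "star_s8": lambda: nx.star_graph(7),
}


def _finish_graph(name, g):
    if name == "two_k5_bridge":
        g.add_edge(0, 5)
    if name == "two_k4_bridge":
        g.add_edge(0, 4)
    if name == "three_triangles":
        g.add_edge(0, 3)
        g.add_edge(3, 6)
        g.add_edge(6, 0)
    if name == "two_triangles_bridge":
        g.add_edge(0, 3)
    return g


class TestGirvanNewman:
    def _partition(self, g, min_size=1):
        cg = md.ContactGraph(graph=g, cutoff=4.5, threshold=0.75,
                             node_index={n: i for i, n in enumerate(sorted(g))})
        return md.girvan_newman(cg, min_size=min_size)

    def test_complete_graph_single_community(self):
        part = self._partition(nx.complete_graph(6), min_size=3)
        assert len(part.sizes) == 1
        assert set(part.assignment.values()) == {0}

    def test_two_cliques_two_communities(self):
        g = _finish_graph("two_k5_bridge", ORACLE_GRAPHS["two_k5_bridge"]())
        part = self._partition(g, min_size=3)
        assert len(part.sizes) == 2
        comm_of = part.assignment
        assert len({comm_of[n] for n in range(5)}) == 1
        assert len({comm_of[n] for n in range(5, 10)}) == 1
        assert comm_of[0] != comm_of[5]

    @pytest.mark.parametrize("name", sorted(ORACLE_GRAPHS))
    def test_matches_exhaustive_max_modularity(self, name):
        g = _finish_graph(name, ORACLE_GRAPHS[name]())
        assert g.number_of_nodes() <= 10 and nx.is_connected(g)
        part = self._partition(g, min_size=1)
        best_q, _ = exhaustive_max_modularity(g)
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_small_communities_omitted_from_report(self):
        g = _finish_graph("two_k4_bridge", ORACLE_GRAPHS["two_k4_bridge"]())
        g.add_edge(100, 101)  # isolated 2-node component
        part = self._partition(g, min_size=3)
        assert 100 not in part.assignment and 101 not in part.assignment
        assert 100 in part.full_assignment
        assert all(s >= 3 for s in part.sizes.values())

    def test_deterministic(self):
        g = _finish_graph("barbell", ORACLE_GRAPHS["barbell"]())
        p1 = self._partition(g)
        p2 = self._partition(g)
        assert p1.full_assignment == p2.full_assignment


class TestDifferenceNetwork:
    def _weighted_two_block(self, drop_edge=None, inter_weight=0.8):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (1, 4)]
        g = nx.Graph()
        for u, v in edges:
            if drop_edge and (u, v) == drop_edge:
                continue
            same_block = (u < 3) == (v < 3)
            g.add_edge(u, v, persistence=1.0,
                       correlation=0.9 if same_block else inter_weight)
        return md.ContactGraph(graph=g, cutoff=4.5, threshold=0.75,
                               node_index={n: n for n in g})

    def test_identical_states_all_zero(self):
        a = self._weighted_two_block()
        part = md.girvan_newman(a, min_size=3)
        dn = md.difference_network(a, a, part)
        assert all(v == 0.0 for v in dn.delta.values())

    def test_deleting_edge_of_known_weight(self):
        a = self._weighted_two_block()
        part = md.girvan_newman(a, min_size=3)
        b = self._weighted_two_block(drop_edge=(2, 3))
        b.graph.add_node(2)  # keep node universe identical
        dn = md.difference_network(a, b, part)
        ca, cb = part.assignment[2], part.assignment[3]
        key = tuple(sorted((ca, cb)))
        assert dn.delta[key] == pytest.approx(-0.8)

    def test_antisymmetry(self):
        a = self._weighted_two_block()
        b = self._weighted_two_block(inter_weight=0.3)
        part = md.girvan_newman(a, min_size=3)
        ab = md.difference_network(a, b, part)
        ba = md.difference_network(b, a, part)
        for k in ab.delta:
            assert ab.delta[k] == pytest.approx(-ba.delta[k])

    def test_weaker_interblock_contacts_negative_change(self):
        a = self._weighted_two_block(inter_weight=0.9)
        b = self._weighted_two_block(inter_weight=0.4)
        part = md.girvan_newman(a, min_size=3)
        dn = md.difference_network(a, b, part)
        inter = [v for (x, y), v in dn.delta.items() if x != y]
        assert inter and all(v < 0 for v in inter)

    def test_node_universe_mismatch_listed(self):
        a = self._weighted_two_block()
        b = self._weighted_two_block()
        b.graph.add_edge(99, 98, persistence=1.0, correlation=0.5)
        part = md.girvan_newman(a, min_size=3)
        with pytest.raises(md.errors.SelectionError, match="98"):
            md.difference_network(a, b, part)
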