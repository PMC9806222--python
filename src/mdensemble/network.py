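"""Persistence-contact residue networks, communities, difference networks.

Nodes are residues (at their Cα); an edge joins residues whose heavy atoms
come within a distance cutoff (default 4.5 Å) in strictly more than a
persistence fraction of frames (default 75%).  Sequence neighbors (i, i±1 in
the same chain) are excluded so trivial backbone contacts do not dominate
betweenness.  Edges are weighted by the information-flow distance
``D_ij = -ln |C_ij|``: perfectly coupled residues are zero-distance, and the
magnitude is used so strongly anti-correlated pairs are also "close".

Communities come from the Girvan-Newman procedure — iteratively remove the
maximum-betweenness edge (ties broken lexicographically for determinism) and
keep the partition of maximum modularity.  Communities with fewer than three
residues are omitted from the reported partition.  Two states are compared
by holding one state's communities fixed and differencing the summed
inter-community connection strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .dccm import CorrelationMatrix
from .errors import SelectionError
from .structure_io import StructureModel, Trajectory


@dataclass
class ContactGraph:
    graph: nx.Graph           # nodes: residue labels; edge attrs: persistence, distance, correlation
    cutoff: float
    threshold: float
    node_index: dict = field(default_factory=dict)  # label -> DCCM matrix index

    @property
    def nodes(self):
        return list(self.graph.nodes)


@dataclass
class CommunityPartition:
    assignment: dict          # node -> community id, only communities >= min_size
    full_assignment: dict     # node -> community id, all communities
    sizes: dict               # community id -> size (reported communities)
    modularity: float
    min_size: int


@dataclass
class DifferenceNetwork:
    partition: CommunityPartition
    delta: dict               # (community a, community b) a<=b -> strength(B) - strength(A)
    strength_a: dict
    strength_b: dict


def _residue_label(model: StructureModel, atom_index: int) -> str:
    return f"{model.chain[atom_index]}:{model.resid[atom_index]}"


def contact_persistence(traj: Trajectory, topology: StructureModel | None = None,
                        cutoff: float = 4.5, threshold: float = 0.75,
                        exclude_neighbors: int = 1) -> ContactGraph:
    """Residue contact graph from per-frame heavy-atom distances.

    An edge (i, j) exists iff any heavy-atom pair of the two residues is
    within ``cutoff`` in strictly more than ``threshold`` of the frames.
    Hydrogens are ignored; residues within ``exclude_neighbors`` sequence
    positions on the same chain never form edges.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0.0 <= threshold < 1.0):
        raise ValueError("persistence threshold must be a fraction in [0, 1)")
    topo = topology if topology is not None else traj.topology
    heavy = np.flatnonzero(np.char.upper(topo.element.astype(str)) != "H")
    res_keys = topo.residue_keys()
    key_to_node = {k: f"{k[0]}:{k[1]}" for k in res_keys}
    atom_res = np.empty(topo.n_atoms, dtype=int)
    key_index = {k: i for i, k in enumerate(res_keys)}
    for a in range(topo.n_atoms):
        atom_res[a] = key_index[(str(topo.chain[a]), int(topo.resid[a]),
                                 str(topo.icode[a]), str(topo.resname[a]))]

    counts: dict[tuple[int, int], int] = {}
    for f in range(traj.n_frames):
        pos = traj.coords[f][heavy]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ra = atom_res[heavy[pairs[:, 0]]]
        rb = atom_res[heavy[pairs[:, 1]]]
        mask = ra != rb
        frame_pairs = {(min(a, b), max(a, b)) for a, b in zip(ra[mask], rb[mask])}
        for p in frame_pairs:
            counts[p] = counts.get(p, 0) + 1

    g = nx.Graph()
    for k in res_keys:
        g.add_node(key_to_node[k])
    nodes = [key_to_node[k] for k in res_keys]
    for (i, j), c in sorted(counts.items()):
        ki, kj = res_keys[i], res_keys[j]
        if ki[0] == kj[0] and abs(ki[1] - kj[1]) <= exclude_neighbors:
            continue
        persistence = c / traj.n_frames
        if persistence > threshold:
            g.add_edge(nodes[i], nodes[j], persistence=persistence)
    return ContactGraph(graph=g, cutoff=cutoff, threshold=threshold,
                        node_index={n: i for i, n in enumerate(nodes)})


def weight_edges(contact: ContactGraph, matrix: CorrelationMatrix,
                 node_index: dict | None = None) -> ContactGraph:
    """Attach D_ij = -ln|C_ij| edge distances from a correlation matrix.

    ``node_index`` maps node labels to matrix rows (defaults to the mapping
    recorded when the graph was built).  Edges with C_ij = 0 (or undefined)
    carry infinite distance and are dropped with a warning; |C| > 1 signals
    an upstream invariant breach and is an error.
    """
    index = node_index or contact.node_index
    g = contact.graph.copy()
    dropped = []
    for u, v in list(g.edges):
        c = matrix.correlation[index[u], index[v]]
        if np.isfinite(c) and abs(c) > 1.0 + 1e-12:
            raise ValueError(f"|C| = {abs(c)} > 1 for edge ({u}, {v})")
        if not np.isfinite(c) or c == 0.0:
            dropped.append((u, v))
            g.remove_edge(u, v)
            continue
        g.edges[u, v]["correlation"] = float(c)
        g.edges[u, v]["distance"] = float(-np.log(abs(c)))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} edge(s) with zero/undefined "
                      f"correlation: {dropped[:5]}...", stacklevel=2)
    return ContactGraph(graph=g, cutoff=contact.cutoff, threshold=contact.threshold,
                        node_index=dict(index))


def _partition_modularity(original: nx.Graph, communities) -> float:
    return nx.algorithms.community.modularity(original, communities, weight=None)


def girvan_newman(contact: ContactGraph, min_size: int = 3,
                  use_edge_distances: bool = True) -> CommunityPartition:
    """Maximum-modularity Girvan-Newman community decomposition.

    Edges are removed in order of maximum edge betweenness (shortest paths
    weighted by the D_ij edge distance when ``use_edge_distances`` and the
    distances are present); ties are broken by lexicographic edge id so the
    result is deterministic.  Of all partitions visited (including the
    initial connected components), the one with maximum (unweighted)
    modularity is returned; communities smaller than ``min_size`` are omitted
    from the reported assignment but retained in ``full_assignment``.
    """
    original = contact.graph
    if original.number_of_nodes() == 0:
        raise ValueError("empty graph")
    work = original.copy()
    weight_key = "distance" if (use_edge_distances and all(
        "distance" in d for _, _, d in original.edges(data=True))) else None

    # nodes with no edges at all never join a community
    connected_nodes = [n for n in original.nodes if original.degree(n) > 0]
    sub = original.subgraph(connected_nodes)
    work = sub.copy()

    best_partition = [set(c) for c in nx.connected_components(work)]
    best_q = _partition_modularity(sub, best_partition) if work.number_of_edges() else 0.0
    n_comp = len(best_partition)

    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, weight=weight_key)
        max_b = max(bc.values())
        candidates = sorted(
            tuple(sorted(e)) for e, b in bc.items() if b >= max_b - 1e-12
        )
        u, v = candidates[0]
        work.remove_edge(u, v)
        comps = [set(c) for c in nx.connected_components(work)]
        if len(comps) > n_comp:
            n_comp = len(comps)
            q = _partition_modularity(sub, comps)
            if q > best_q + 1e-12:
                best_q = q
                best_partition = comps

    full = {}
    for cid, comm in enumerate(sorted(best_partition, key=lambda c: (-len(c), sorted(c)))):
        for node in comm:
            full[node] = cid
    reported = {n: c for n, c in full.items()
                if sum(1 for x in full.values() if x == c) >= min_size}
    sizes: dict[int, int] = {}
    for c in reported.values():
        sizes[c] = sizes.get(c, 0) + 1
    return CommunityPartition(assignment=reported, full_assignment=full,
                              sizes=sizes, modularity=float(best_q),
                              min_size=min_size)


def community_strengths(contact: ContactGraph, partition: CommunityPartition,
                        weight: str = "correlation") -> dict:
    """Summed |edge weight| between (and within) communities.

    ``weight`` picks the edge attribute (correlation magnitude by default,
    persistence as fallback when correlations were never attached).
    """
    strengths: dict[tuple[int, int], float] = {}
    assign = partition.assignment
    for u, v, data in contact.graph.edges(data=True):
        if u not in assign or v not in assign:
            continue
        a, b = sorted((assign[u], assign[v]))
        w = abs(data.get(weight, data.get("persistence", 1.0)))
        strengths[(a, b)] = strengths.get((a, b), 0.0) + w
    return strengths


def difference_network(graph_a: ContactGraph, graph_b: ContactGraph,
                       partition: CommunityPartition,
                       weight: str = "correlation") -> DifferenceNetwork:
    """Signed per-community-pair change in connection strength, B minus A.

    The community frame (normally computed on the reference state) is held
    fixed; both graphs must live on the same node universe.
    """
    missing = set(graph_a.graph.nodes) ^ set(graph_b.graph.nodes)
    if missing:
        raise SelectionError(
            f"graphs do not share a node universe; differing nodes: {sorted(missing)[:10]}"
        )
    sa = community_strengths(graph_a, partition, weight)
    sb = community_strengths(graph_b, partition, weight)
    keys = set(sa) | set(sb)
    delta = {k: sb.get(k, 0.0) - sa.get(k, 0.0) for k in sorted(keys)}
    return DifferenceNetwork(partition=partition, delta=delta,
                             strength_a=sa, strength_b=sb)
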