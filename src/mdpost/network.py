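"""Correlation-based dynamic network analysis.

Pipeline: a dynamic cross-correlation matrix (DCCM) over node atoms,

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2> <dr_j^2>),

with dr the displacement from the time-mean position; a residue network
whose nodes are Cα atoms and whose edges join residue pairs that stay within
a contact cutoff (default 4.5 Å, minimum heavy-atom distance) for at least a
persistence fraction of frames (default 75%, inclusive), weighted by

    d_ij = -ln |C_ij|;

Girvan–Newman community detection with weighted-modularity model selection;
and optimal/suboptimal path enumeration between chosen source and sink
nodes, with all-pairs distances from Floyd–Warshall and a depth-first
suboptimal search pruned by distances-to-sink.

Anti-correlated motions carry information, so the weight uses |C_ij|; the
magnitude is floored at 1e-6 before the log to keep weights finite.
Sequence-adjacent residue pairs (|i-j| <= 1 within a chain) never receive an
edge — they are trivially in permanent contact through the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .errors import (
    ParameterError,
    SelectionError,
    UndefinedStatisticError,
    UnreachableError,
)
from .topology import AtomSelection
from .trajectory import Trajectory, residue_contact_fractions

CORRELATION_FLOOR = 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric cross-correlation matrix with a node -> residue mapping."""

    values: np.ndarray
    node_keys: list  # (chain, resid) per node

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ParameterError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ParameterError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dccm(traj: Trajectory, selection: AtomSelection | None = None) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the selected (node) atoms.

    The trajectory should be superposed first so rigid-body motion does not
    masquerade as correlation.  An atom with zero positional variance has no
    defined correlation and raises.
    """
    if traj.n_frames < 2:
        raise UndefinedStatisticError("DCCM needs at least 2 frames")
    if selection is None:
        idx = np.arange(traj.n_atoms)
    else:
        selection.validate(traj.topology)
        idx = selection.indices
    x = traj.coords[:, idx, :]
    dx = x - x.mean(axis=0)
    # cov[i, j] = <dr_i . dr_j> summed over the 3 Cartesian components
    cov = np.einsum("fic,fjc->ij", dx, dx) / x.shape[0]
    var = np.diag(cov)
    if np.any(var <= 0.0):
        bad = int(np.argmax(var <= 0.0))
        raise UndefinedStatisticError(
            f"atom id {traj.topology.ids[idx[bad]]} is immobile; "
            "correlation undefined"
        )
    c = cov / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    keys = [(str(traj.topology.chains[i]), int(traj.topology.resids[i])) for i in idx]
    return CorrelationMatrix(c, keys)


def mask_dccm(c: CorrelationMatrix, threshold: float = 0.3) -> np.ma.MaskedArray:
    """Display mask: entries with |C| strictly below the threshold are masked
    (shown white in the conventional rendering); |C| equal to the threshold
    survives."""
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("mask threshold must lie in [0, 1]")
    return np.ma.MaskedArray(c.values, mask=np.abs(c.values) < threshold)


# ---------------------------------------------------------------------------
# network construction

@dataclass
class DynamicNetwork:
    """Residue-level graph with persistence-gated, correlation-weighted edges.

    Edge attributes: ``persistence`` (contact fraction), ``correlation``
    (C_ij), ``weight`` (d_ij = -ln|C_ij|, the path length) and ``affinity``
    (|C_ij|, used for modularity).
    """

    graph: nx.Graph
    node_keys: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def edge_weight(correlation: float, floor: float = CORRELATION_FLOOR) -> float:
    """d_ij = -ln|C_ij| with the magnitude floored away from zero."""
    return float(-np.log(max(abs(correlation), floor)))


def build_network(
    traj: Trajectory,
    c: CorrelationMatrix,
    contact_cutoff: float = 4.5,
    persistence: float = 0.75,
) -> DynamicNetwork:
    """Build the dynamic network from a trajectory and its DCCM.

    Nodes are residues (positioned at their first node atom); an edge joins
    residues i, j when their minimum heavy-atom distance stays <= the contact
    cutoff in at least the persistence fraction of frames (both thresholds
    inclusive) and the residues are not sequence-adjacent.
    """
    frac, keys = residue_contact_fractions(traj, cutoff=contact_cutoff)
    if len(keys) != c.n:
        raise SelectionError(
            f"correlation matrix covers {c.n} nodes but the trajectory has "
            f"{len(keys)} residues"
        )
    g = nx.Graph()
    for node, key in enumerate(keys):
        g.add_node(node, chain=key[0], resid=key[1])
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            same_chain = keys[i][0] == keys[j][0]
            if same_chain and abs(keys[i][1] - keys[j][1]) <= 1:
                continue
            if frac[i, j] >= persistence:
                cij = float(c.values[i, j])
                g.add_edge(
                    i, j,
                    persistence=float(frac[i, j]),
                    correlation=cij,
                    weight=edge_weight(cij),
                    affinity=max(abs(cij), CORRELATION_FLOOR),
                )
    return DynamicNetwork(g, keys)


def network_from_edges(
    n_nodes: int, edges: list[tuple[int, int, float]]
) -> DynamicNetwork:
    """Assemble a DynamicNetwork directly from (i, j, correlation) triples.

    Convenience for tests and for graphs whose contact gating happened
    elsewhere; the persistence attribute is set to 1.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i, j, cij in edges:
        g.add_edge(
            i, j,
            persistence=1.0,
            correlation=float(cij),
            weight=edge_weight(cij),
            affinity=max(abs(float(cij)), CORRELATION_FLOOR),
        )
    return DynamicNetwork(g, list(range(n_nodes)))


# ---------------------------------------------------------------------------
# communities

@dataclass
class CommunityPartition:
    communities: list[list]        # node lists
    node_labels: dict              # node -> community index
    modularity: float
    connectivity: np.ndarray       # summed cross-community edge betweenness


def _most_valuable_edge(g: nx.Graph) -> tuple:
    """Highest weighted edge betweenness; ties broken lexicographically."""
    bet = nx.edge_betweenness_centrality(g, weight="weight")
    best = max(bet.values())
    candidates = [tuple(sorted(e)) for e, b in bet.items() if b >= best - 1e-15]
    return min(candidates)


def detect_communities(net: DynamicNetwork) -> CommunityPartition:
    """Girvan–Newman divisive clustering with modularity model selection.

    Edge betweenness treats d_ij as a length; modularity scores partitions
    with the affinity weight |C_ij|.  Among the divisive sequence of
    partitions (including the trivial one-community partition) the one with
    maximal modularity is returned.  A graph with no edges yields singleton
    communities.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ParameterError("empty network")
    if g.number_of_edges() == 0:
        parts = [[n] for n in sorted(g.nodes)]
        labels = {n: i for i, part in enumerate(parts) for n in part}
        return CommunityPartition(parts, labels, 0.0, np.zeros((len(parts), len(parts))))

    best = [sorted(cc) for cc in nx.connected_components(g)]
    best_q = nx.community.modularity(g, best, weight="affinity")
    for partition in nx.community.girvan_newman(
        g, most_valuable_edge=_most_valuable_edge
    ):
        parts = [sorted(p) for p in partition]
        q = nx.community.modularity(g, parts, weight="affinity")
        if q > best_q + 1e-12:
            best_q, best = q, parts
    best = sorted(best, key=lambda p: p[0])
    labels = {n: i for i, part in enumerate(best) for n in part}

    bet = nx.edge_betweenness_centrality(g, weight="weight")
    k = len(best)
    conn = np.zeros((k, k))
    for (u, v), b in bet.items():
        cu, cv = labels[u], labels[v]
        if cu != cv:
            conn[cu, cv] += b
            conn[cv, cu] += b
    return CommunityPartition(best, labels, float(best_q), conn)


# ---------------------------------------------------------------------------
# optimal / suboptimal paths

@dataclass
class PathSet:
    source: int
    sink: int
    optimal_length: float
    paths: list[tuple[float, tuple[int, ...]]]  # (length, nodes), ascending
    tolerance: float

    @property
    def optimal_path(self) -> tuple[int, ...]:
        return self.paths[0][1]

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def _all_pairs_shortest(net: DynamicNetwork) -> tuple[np.ndarray, list]:
    nodes = sorted(net.graph.nodes)
    mat = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight")
    dist = floyd_warshall(mat, directed=False)
    return dist, nodes


def paths(
    net: DynamicNetwork,
    source,
    sink,
    tolerance: float = 20.0,
) -> PathSet:
    """All simple paths within ``tolerance`` of the optimal length.

    All-pairs distances come from Floyd–Warshall on the -ln|C| weights; the
    suboptimal enumeration is a depth-first search over simple paths pruned
    with the exact distance-to-sink bound: a partial path is abandoned as
    soon as its length plus the shortest remaining distance exceeds
    L_opt + tolerance.  Paths are returned sorted by length (node sequence
    breaks ties), the optimal path first.
    """
    g = net.graph
    if source == sink:
        raise ParameterError("source and sink must differ")
    if source not in g or sink not in g:
        raise SelectionError("source or sink not in network")
    dist, nodes = _all_pairs_shortest(net)
    pos = {n: i for i, n in enumerate(nodes)}
    d_opt = dist[pos[source], pos[sink]]
    if not np.isfinite(d_opt):
        raise UnreachableError(
            f"nodes {source!r} and {sink!r} are in different components"
        )
    budget = d_opt + tolerance + 1e-12
    to_sink = dist[:, pos[sink]]

    found: list[tuple[float, tuple[int, ...]]] = []
    path: list = [source]
    on_path = {source}

    def dfs(node, length: float) -> None:
        if node == sink:
            found.append((length, tuple(path)))
            return
        for nbr in sorted(g.neighbors(node)):
            if nbr in on_path:
                continue
            new_len = length + g.edges[node, nbr]["weight"]
            if new_len + to_sink[pos[nbr]] > budget:
                continue
            path.append(nbr)
            on_path.add(nbr)
            dfs(nbr, new_len)
            path.pop()
            on_path.remove(nbr)

    dfs(source, 0.0)
    found.sort(key=lambda t: (t[0], t[1]))
    return PathSet(source, sink, float(d_opt), found, float(tolerance))
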