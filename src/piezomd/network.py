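"""Dynamical community networks from Cα motion.

Residues become graph nodes; an edge exists between residues in persistent
physical contact, weighted by the Pearson correlation of their Cα
displacement vectors.  Edges carry two weights: the affinity |C_ij| (used
for weighted modularity) and the distance −log|C_ij| (used for weighted
shortest-path betweenness), so tightly coupled pairs are 'close'.
Communities come from Girvan–Newman edge removal: iteratively delete the
edge of highest weighted betweenness and keep the partition along the
removal sequence that maximizes modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import Trajectory


def correlation_matrix(traj: Trajectory, selection="name CA") -> np.ndarray:
    """Pearson correlations of Cα displacement vectors.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) with Δr the displacement from
    the time-mean position (scalar dot-product convention).  The trajectory
    should already be superposed.  A zero-variance node gets zero
    off-diagonal entries (its correlations are undefined).
    """
    sel = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for correlations")
    D = traj.coords[:, sel] - traj.coords[:, sel].mean(axis=0, keepdims=True)
    num = np.einsum("fia,fja->ij", D, D) / traj.n_frames
    var = np.diag(num).copy()
    zero = var <= 0
    var[zero] = 1.0
    C = num / np.sqrt(np.outer(var, var))
    np.clip(C, -1.0, 1.0, out=C)
    if zero.any():
        C[zero, :] = 0.0
        C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def contact_mask(traj: Trajectory, residue_groups: list,
                 cutoff: float = 4.5, min_fraction: float = 0.75,
                 frames=None) -> np.ndarray:
    """Persistent-contact mask between residues.

    ``residue_groups`` is a list of heavy-atom index arrays, one per node
    (order defines node order).  mask[i, j] is True iff any heavy-atom pair
    of residues i and j is within ``cutoff`` Å in at least ``min_fraction``
    of the frames.
    """
    n = len(residue_groups)
    frames = range(traj.n_frames) if frames is None else list(frames)
    if len(frames) == 0:
        raise ValueError("empty frame interval")
    heavy = [np.asarray(g)[traj.topology.elements[np.asarray(g)] != "H"]
             for g in residue_groups]
    atom_node = np.concatenate([np.full(len(g), i) for i, g in enumerate(heavy)])
    atoms = np.concatenate(heavy)
    counts = np.zeros((n, n))
    for f in frames:
        pos = traj.coords[f, atoms]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs):
            ni, nj = atom_node[pairs[:, 0]], atom_node[pairs[:, 1]]
            touched = np.zeros((n, n), dtype=bool)
            touched[ni, nj] = True
            touched |= touched.T
            counts += touched
    mask = counts / len(frames) >= min_fraction
    np.fill_diagonal(mask, False)
    return mask


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    C: np.ndarray
    mask: np.ndarray
    nodes: list

    def edge_table(self):
        import pandas as pd

        rows = [{"i": u, "j": v, "abs_corr": d["correlation"],
                 "distance": d["distance"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows)


def build_graph(C: np.ndarray, mask: np.ndarray, nodes=None) -> CorrelationNetwork:
    """Graph with edges on masked pairs of nonzero correlation; each edge
    carries ``correlation`` = |C_ij| and ``distance`` = −log|C_ij|."""
    C = np.asarray(C, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if C.shape != mask.shape or C.shape[0] != C.shape[1]:
        raise ValueError("C and mask must be square with matching shapes")
    n = C.shape[0]
    nodes = list(range(n)) if nodes is None else list(nodes)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            a = abs(C[i, j])
            if mask[i, j] and a > 0:
                G.add_edge(nodes[i], nodes[j], correlation=a,
                           distance=-float(np.log(a)))
    return CorrelationNetwork(G, C, mask, nodes)


@dataclass
class CommunityPartition:
    membership: dict  # node -> community id
    modularity: float
    removal_history: list = field(default_factory=list)

    @property
    def communities(self) -> list:
        out: dict[int, set] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [out[k] for k in sorted(out)]


def _partition_of(G: nx.Graph) -> list:
    comps = [set(c) for c in nx.connected_components(G)]
    return sorted(comps, key=lambda c: min(c))


def detect_communities(net: CorrelationNetwork) -> CommunityPartition:
    """Girvan–Newman decomposition maximizing weighted modularity.

    Repeatedly removes the edge of highest betweenness (shortest paths
    weighted by the −log|C| distance); ties are broken deterministically by
    the lexicographically smallest node pair.  Among all partitions along
    the removal sequence (including the initial connected components), the
    one with the highest modularity — computed with |C| affinity weights on
    the original graph — is returned, together with the removal history.
    """
    G0 = net.graph
    if G0.number_of_nodes() == 0:
        raise ValueError("empty network")

    def q_of(partition):
        if G0.number_of_edges() == 0:
            return 0.0
        return nx.community.modularity(G0, partition, weight="correlation")

    work = G0.copy()
    best_partition = _partition_of(work)
    best_q = q_of(best_partition)
    history = []
    n_comp = len(best_partition)
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, weight="distance")
        maxv = max(bc.values())
        best_edge = min(tuple(sorted(e)) for e, v in bc.items() if v >= maxv - 1e-12)
        work.remove_edge(*best_edge)
        history.append(best_edge)
        parts = _partition_of(work)
        if len(parts) > n_comp:
            n_comp = len(parts)
            q = q_of(parts)
            if q > best_q:
                best_q = q
                best_partition = parts
    membership = {}
    for cid, comm in enumerate(best_partition):
        for node in comm:
            membership[node] = cid
    return CommunityPartition(membership, float(best_q), history)


@dataclass
class InterCommunityContact:
    edge_count: int
    total_abs_corr: float
    mean_distance: float
    connected: bool


def intercommunity_contact(partition: CommunityPartition,
                           net: CorrelationNetwork,
                           a: int, b: int) -> InterCommunityContact:
    """Aggregate the edges spanning communities ``a`` and ``b``; zero edges
    flags loss of direct contact."""
    ids = set(partition.membership.values())
    if a not in ids or b not in ids:
        raise ValueError(f"unknown community label(s) {a}, {b} (have {sorted(ids)})")
    count, total, dsum = 0, 0.0, 0.0
    for u, v, d in net.graph.edges(data=True):
        cu, cv = partition.membership[u], partition.membership[v]
        if {cu, cv} == {a, b}:
            count += 1
            total += d["correlation"]
            dsum += d["distance"]
    return InterCommunityContact(count, total,
                                 dsum / count if count else float("nan"),
                                 connected=count > 0)
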