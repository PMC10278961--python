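"""Dynamical contact-network analysis of trajectories.

Residues (their C-alpha or designated anchor atoms) are nodes.  Node pairs in
persistent spatial contact become edges weighted by

    d_ij = -ln |C_ij|,   C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)

where dr are displacement fluctuations about the mean structure after
least-squares superposition.  Communities come from Girvan-Newman divisive
clustering (partition of maximal modularity over the dendrogram) and
allosteric transmission chains from shortest paths on the d_ij weights.
A hydrogen-bond occupancy scanner supports the interaction-chain analyses.

Contact criterion: the default is the standard dynamical-network convention
(any heavy-atom pair of the two residues within the cutoff in at least
``occupancy_min`` of frames).  ``calpha_strict=True`` instead measures the
node-atom/node-atom distance itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import MolecularSystem, Trajectory, superpose

__all__ = ["ContactGraph", "CommunityPartition", "HBondSeries",
           "displacement_correlation", "contact_adjacency", "build_network",
           "girvan_newman", "optimal_path", "hbond_occupancy", "rand_index"]

#: floor on |C| before taking the logarithm
_C_FLOOR = 1e-12


@dataclass
class ContactGraph:
    graph: nx.Graph                    # nodes: residue ids; edge attrs: c, d, occupancy
    nodes: list                        # node order used for the matrices

    def edge_table(self):
        rows = []
        for u, v, data in self.graph.edges(data=True):
            rows.append((u, v, data["c"], data["d"], data.get("occupancy", 1.0)))
        return rows


@dataclass
class CommunityPartition:
    membership: dict                   # node -> community id (0-based)
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def labels(self, node_order) -> np.ndarray:
        return np.array([self.membership[n] for n in node_order])


@dataclass
class HBondSeries:
    donor: int                         # heavy donor atom index
    hydrogen: int
    acceptor: int
    per_frame: np.ndarray              # bool
    distances: np.ndarray              # donor-acceptor heavy distance per frame

    @property
    def occupancy(self) -> float:
        return float(self.per_frame.mean())

    @property
    def n_frames_detected(self) -> int:
        return int(self.per_frame.sum())


# ---------------------------------------------------------------------------

def displacement_correlation(trajectory: Trajectory, node_atoms,
                             fit: bool = True, fit_set=None) -> np.ndarray:
    """Normalized displacement cross-correlation matrix over node atoms.

    Frames are superposed onto the mean structure (one refinement pass) when
    ``fit`` is true; fluctuations are taken about the superposed mean.
    """
    node_atoms = list(node_atoms)
    frames = trajectory.frames
    if len(frames) < 10:
        raise ValueError("need at least 10 frames for correlations")
    if fit:
        fit_idx = sorted(fit_set) if fit_set is not None else node_atoms
        ref = frames[0]
        fitted = np.array([superpose(f, ref, fit_idx)[0] for f in frames])
        mean = fitted.mean(axis=0)
        fitted = np.array([superpose(f, mean, fit_idx)[0] for f in fitted])
        frames = fitted
    x = frames[:, node_atoms, :]                      # (F, M, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", dx, dx) / len(frames)
    var = np.diag(cov)
    if np.any(var <= 0):
        bad = [node_atoms[i] for i in np.where(var <= 0)[0]]
        raise ValueError(f"zero-variance node atom(s) {bad}")
    c = cov / np.sqrt(np.outer(var, var))
    np.fill_diagonal(c, 1.0)
    return c


def contact_adjacency(system: MolecularSystem, trajectory: Trajectory,
                      node_residues=None, cutoff: float = 4.5,
                      occupancy_min: float = 0.75,
                      exclude_sequential: bool = False,
                      calpha_strict: bool = False,
                      node_atoms: dict | None = None):
    """Residue adjacency + contact occupancies over a trajectory.

    Returns ``(adjacency bool matrix, occupancy matrix, node_residues)``.
    Default criterion: any heavy-atom/heavy-atom distance <= cutoff; with
    ``calpha_strict`` the node anchor atoms themselves must be within cutoff
    (the literal reading of a C-alpha contact network).
    """
    if node_residues is None:
        node_residues = system.residue_ids()
    heavy = system.heavy
    groups = []
    for rid in node_residues:
        if calpha_strict:
            if node_atoms and rid in node_atoms:
                groups.append([node_atoms[rid]])
            else:
                ca = [a.index for a in system.atoms
                      if a.residue_id == rid and a.name.upper() == "CA"]
                groups.append(ca or [system.residue_atoms(rid)[0]])
        else:
            groups.append([i for i in system.residue_atoms(rid) if heavy[i]])
    m = len(node_residues)
    hits = np.zeros((m, m))
    for frame in trajectory:
        for a, b in itertools.combinations(range(m), 2):
            da = frame[groups[a]][:, None, :] - frame[groups[b]][None, :, :]
            if np.min(np.sqrt((da ** 2).sum(-1))) <= cutoff:
                hits[a, b] += 1
    occ = (hits + hits.T) / max(len(trajectory), 1)
    adj = occ >= occupancy_min
    if exclude_sequential:
        for a in range(m - 1):
            adj[a, a + 1] = adj[a + 1, a] = False
    np.fill_diagonal(adj, False)
    return adj, occ, list(node_residues)


def build_network(C: np.ndarray, adjacency: np.ndarray, node_ids=None,
                  occupancy: np.ndarray | None = None) -> ContactGraph:
    """Weighted contact graph with ``d = -ln |C|`` on adjacent pairs.

    |C| is floored at 1e-12 before the log; negative correlations enter by
    magnitude (flagged via the edge's ``c`` attribute keeping its sign).
    """
    C = np.asarray(C, float)
    adjacency = np.asarray(adjacency, bool)
    if C.shape != adjacency.shape:
        raise ValueError("C and adjacency must be on the same node set")
    m = C.shape[0]
    nodes = list(node_ids) if node_ids is not None else list(range(m))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(m):
        for b in range(a + 1, m):
            if adjacency[a, b]:
                cab = float(C[a, b])
                d = float(-np.log(max(abs(cab), _C_FLOOR)))
                attrs = dict(c=cab, d=d)
                if occupancy is not None:
                    attrs["occupancy"] = float(occupancy[a, b])
                g.add_edge(nodes[a], nodes[b], **attrs)
    return ContactGraph(graph=g, nodes=nodes)


def _most_valuable_edge(g):
    """Max edge betweenness; deterministic tie-break by sorted edge ids.

    Betweenness is topological (unweighted), as in the original divisive
    algorithm; the d weights drive path extraction, not the division.
    """
    bw = nx.edge_betweenness_centrality(g)
    return max(bw, key=lambda e: (bw[e], tuple(sorted(map(str, e)))))


def girvan_newman(contact_graph: ContactGraph | nx.Graph) -> CommunityPartition:
    """Divisive community detection; best-modularity cut of the dendrogram."""
    g = contact_graph.graph if isinstance(contact_graph, ContactGraph) else contact_graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    base = [set(c) for c in nx.connected_components(g)]
    best = base
    best_q = nx.community.modularity(g, base) if g.number_of_edges() else 0.0
    if g.number_of_edges():
        for partition in nx.community.girvan_newman(
                g, most_valuable_edge=_most_valuable_edge):
            q = nx.community.modularity(g, partition)
            if q > best_q + 1e-12:
                best_q = q
                best = [set(c) for c in partition]
    membership = {}
    for cid, comm in enumerate(sorted(best, key=lambda c: min(map(str, c)))):
        for node in comm:
            membership[node] = cid
    return CommunityPartition(membership=membership, modularity=float(best_q))


@dataclass
class PathResult:
    nodes: list
    total_weight: float


def optimal_path(contact_graph: ContactGraph | nx.Graph, source, sink,
                 n_suboptimal: int = 0) -> list[PathResult]:
    """Minimum total-d path(s) between two nodes.

    Returns the optimal path plus up to ``n_suboptimal`` next-best simple
    paths; an unreachable sink yields an empty list.
    """
    g = contact_graph.graph if isinstance(contact_graph, ContactGraph) else contact_graph
    if source not in g or sink not in g:
        raise ValueError("source/sink not in graph")
    if source == sink:
        return [PathResult([source], 0.0)]
    if not nx.has_path(g, source, sink):
        return []
    gen = nx.shortest_simple_paths(g, source, sink, weight="d")
    out = []
    for path in itertools.islice(gen, 1 + n_suboptimal):
        w = sum(g[u][v]["d"] for u, v in zip(path, path[1:]))
        out.append(PathResult(list(path), float(w)))
    return out


def hbond_occupancy(system: MolecularSystem, trajectory: Trajectory,
                    donor_set, acceptor_set, d_cut: float = 3.0,
                    angle_cut: float = 135.0) -> list[HBondSeries]:
    """Geometric hydrogen bonds per frame.

    A bond exists in a frame iff donor-heavy to acceptor distance <= d_cut
    (A) and the donor-H...acceptor angle >= angle_cut (degrees).  Donors must
    have at least one bonded hydrogen.
    """
    donors = sorted(donor_set)
    acceptors = sorted(acceptor_set)
    hyd = {i: [] for i in donors}
    for b in system.bonds:
        for d, h in ((b.i, b.j), (b.j, b.i)):
            if d in hyd and system.atoms[h].element.upper() == "H":
                hyd[d].append(h)
    missing = [d for d in donors if not hyd[d]]
    if missing:
        raise ValueError(f"donor atom(s) {missing} have no bonded hydrogen")
    out = []
    nf = len(trajectory)
    for d in donors:
        for h in hyd[d]:
            for a in acceptors:
                if a in (d, h):
                    continue
                flags = np.zeros(nf, bool)
                dists = np.zeros(nf)
                for fi, frame in enumerate(trajectory):
                    rda = float(np.linalg.norm(frame[a] - frame[d]))
                    dists[fi] = rda
                    if rda > d_cut:
                        continue
                    v1 = frame[d] - frame[h]
                    v2 = frame[a] - frame[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    flags[fi] = ang >= angle_cut
                if flags.any():
                    out.append(HBondSeries(d, h, a, flags, dists))
    return out


def rand_index(labels_a, labels_b) -> float:
    """Rand index between two partitions of the same node set."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays differ in length")
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                agree += 1
    return agree / total if total else 1.0
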