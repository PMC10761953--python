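"""Allosteric pathway extraction over a residue interaction graph.

Residues become graph nodes, spatial CA contacts become edges, and edge
weights are derived from PRS coupling strengths: ``w_ij = -ln p_ij`` with
``p_ij`` the symmetrized normalized response (clipped to [epsilon, 1]), so
Dijkstra's minimum-weight path is the chain of contacts with maximal
multiplicative coupling.  Mediator residues are scored by how many
source-to-sink shortest paths pass through them as interior nodes.

Node indices are 1-based residue ordinals throughout.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .prs import PRSResult
from .structure_io import StructureModel

DEFAULT_CONTACT_CUTOFF = 10.0
DEFAULT_EPSILON = 1e-6


@dataclass
class ResidueGraph:
    """Undirected weighted residue contact graph."""

    n_nodes: int
    edges: list[tuple[int, int, float]]  # (i, j, weight) with i < j, 1-based
    contact_cutoff: float
    weighting: str = "unit"  # "unit" | "prs"

    def __post_init__(self):
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-edge at node {i}")
            if not (np.isfinite(w) and w >= 0):
                raise ValueError(f"edge ({i},{j}) has invalid weight {w}")

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(1, self.n_nodes + 1)}
        for i, j, w in self.edges:
            adj[i].append((j, w))
            adj[j].append((i, w))
        for lst in adj.values():
            lst.sort()
        return adj


@dataclass
class AllostericPath:
    """A minimum-weight residue chain from a source to a sink."""

    nodes: list[int]
    total_weight: float

    @property
    def source(self) -> int:
        return self.nodes[0]

    @property
    def sink(self) -> int:
        return self.nodes[-1]


@dataclass
class MediationProfile:
    """Interior-node traversal counts over a set of shortest paths."""

    counts: np.ndarray  # length N, counts[r-1] for residue r
    n_paths: int

    def top_residues(self) -> list[int]:
        """Residue(s) with the maximal mediation count (ties all listed)."""
        top = int(self.counts.max())
        if top == 0:
            return []
        return [int(r) + 1 for r in np.nonzero(self.counts == top)[0]]


def build_contact_graph(
    ca_model: StructureModel | np.ndarray, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> ResidueGraph:
    """Unit-weight graph with an edge wherever two CA atoms are within cutoff."""
    if contact_cutoff <= 0:
        raise ValueError(f"contact_cutoff must be positive, got {contact_cutoff}")
    coords = (
        ca_model.coords if isinstance(ca_model, StructureModel) else np.asarray(ca_model, float)
    )
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty model")
    dist = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    idx_i, idx_j = np.nonzero(np.triu(dist <= contact_cutoff, k=1))
    edges = [(int(i) + 1, int(j) + 1, 1.0) for i, j in zip(idx_i, idx_j)]
    return ResidueGraph(
        n_nodes=n, edges=edges, contact_cutoff=float(contact_cutoff), weighting="unit"
    )


def assign_edge_weights(
    graph: ResidueGraph, prs: PRSResult, epsilon: float = DEFAULT_EPSILON
) -> ResidueGraph:
    """Re-weight contacts by PRS coupling: ``w_ij = -ln p_ij``.

    ``p_ij = max(normalized[i,j], normalized[j,i])`` clipped to
    [epsilon, 1]: a strongly coupled contact is a cheap edge, and the sum
    of weights along a path is the negative log of the product of couplings.
    """
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    if prs.n_residues != graph.n_nodes:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but PRS result has {prs.n_residues} residues"
        )
    norm = prs.normalized
    edges = []
    for i, j, _ in graph.edges:
        p = max(norm[i - 1, j - 1], norm[j - 1, i - 1])
        p = min(max(p, epsilon), 1.0)
        edges.append((i, j, float(-np.log(p))))
    return ResidueGraph(
        n_nodes=graph.n_nodes,
        edges=edges,
        contact_cutoff=graph.contact_cutoff,
        weighting="prs",
    )


class DisconnectedError(ValueError):
    """Sink unreachable from source in the residue graph."""


def shortest_path(graph: ResidueGraph, source: int, sink: int) -> AllostericPath:
    """Dijkstra minimum-weight path with deterministic tie-breaking.

    Ties on total weight are broken by fewer nodes, then by the
    lexicographically smallest node sequence, so results are reproducible
    across platforms.
    """
    n = graph.n_nodes
    for node, label in ((source, "source"), (sink, "sink")):
        if not 1 <= node <= n:
            raise IndexError(f"{label} residue {node} outside 1..{n}")
    if source == sink:
        raise ValueError("source and sink must differ")
    adj = graph.adjacency()
    # heap entries: (distance, hops, node path); the tuple ordering itself
    # implements the tie-break, and path prefixes preserve lexicographic order
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 1, (source,))]
    done: set[int] = set()
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == sink:
            return AllostericPath(nodes=list(path), total_weight=float(dist))
        for nbr, w in adj[node]:
            if nbr not in done:
                heapq.heappush(heap, (dist + w, hops + 1, path + (nbr,)))
    raise DisconnectedError(f"residue {sink} is unreachable from residue {source}")


def all_pairs_paths(
    graph: ResidueGraph, sources: list[int], sinks: list[int]
) -> list[AllostericPath]:
    """One shortest path per (source, sink) pair, source-major order.

    Unreachable pairs are reported as warnings and skipped; computation
    continues for the remaining pairs.
    """
    if not sources or not sinks:
        raise ValueError("sources and sinks must be non-empty")
    if set(sources) & set(sinks):
        raise ValueError("sources and sinks must be disjoint as sets")
    paths = []
    for s in sources:
        for t in sinks:
            try:
                paths.append(shortest_path(graph, s, t))
            except DisconnectedError as exc:
                warnings.warn(str(exc))
    return paths


def mediation_profile(paths: list[AllostericPath], n_nodes: int) -> MediationProfile:
    """Count, per residue, the paths that traverse it strictly between endpoints."""
    if not paths:
        raise ValueError("no paths supplied")
    counts = np.zeros(n_nodes, dtype=int)
    for p in paths:
        for node in p.nodes[1:-1]:
            if not 1 <= node <= n_nodes:
                raise IndexError(f"path node {node} outside 1..{n_nodes}")
            counts[node - 1] += 1
    return MediationProfile(counts=counts, n_paths=len(paths))


def export_paths_json(
    paths: list[AllostericPath], path, model: StructureModel | None = None
) -> None:
    """Write paths as JSON records; residue names added when a model is given."""
    records = []
    for p in paths:
        rec = {
            "source": p.source,
            "sink": p.sink,
            "nodes": p.nodes,
            "total_weight": p.total_weight,
        }
        if model is not None:
            rec["residue_names"] = [model.atoms[i - 1].residue_name for i in p.nodes]
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def pymol_selection(path_obj: AllostericPath, object_name: str = "structure") -> str:
    """PyMOL selection string for a path's residues (visualization aid)."""
    resis = "+".join(str(r) for r in path_obj.nodes)
    return f"select path_{path_obj.source}_{path_obj.sink}, {object_name} and resi {resis}"
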