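"""Correlation-weighted residue networks: shortest-path maps, characteristic
path length and node-weakening analysis.

Residues become graph nodes; an edge joins residues that stay in contact
(mean-structure distance within a cutoff for a minimum fraction of frames)
and whose motions are correlated above a floor.  Edge length is −log|C_ij|,
so highly correlated contacts are short and path length accumulates
multiplicatively in correlation.  The shortest path map (SPM) scores each
edge by how often it is used by inter-residue shortest paths (Dijkstra,
deterministic lexicographic tie-break); the characteristic path length
(CPL) is the mean shortest-path length over reachable pairs, and node
weakening ranks residues by the CPL change their removal causes — a proxy
for their importance to allosteric communication.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ensemble import EnsembleTrajectory
from .trajstats import CorrelationMatrix

__all__ = [
    "NetworkError",
    "ResidueGraph",
    "ShortestPath",
    "SpmResult",
    "CplResult",
    "NodeWeakeningTable",
    "build_residue_graph",
    "shortest_path",
    "compute_spm",
    "characteristic_path_length",
    "node_weakening",
]

logger = logging.getLogger(__name__)

MIN_EDGE_LENGTH = 1e-6  # clamp for |C| = 1 exactly


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueGraph:
    """Undirected residue-contact graph with correlation-derived edge lengths.

    Edge attributes: ``occupancy`` (fraction of frames in contact),
    ``correlation`` (signed C_ij) and ``length`` (−log|C_ij| > 0).
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise NetworkError(f"self-edge on {u}")
            ln = data.get("length")
            if ln is None or not (ln > 0 and math.isfinite(ln)):
                raise NetworkError(f"edge ({u}, {v}) has invalid length {ln}")

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def subunit_of(self, node: str) -> str:
        """Chain tag of a chain-qualified label (text before the colon)."""
        return str(node).partition(":")[0]

    def to_edge_tsv(self, path, spm: "SpmResult | None" = None) -> None:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            row = {
                "node_i": u, "node_j": v,
                "occupancy": data.get("occupancy", np.nan),
                "correlation": data.get("correlation", np.nan),
                "length": data["length"],
            }
            if spm is not None:
                key = (u, v) if (u, v) in spm.edge_usage else (v, u)
                row["usage"] = spm.edge_usage.get(key, 0.0)
                row["in_spm"] = key in spm.spm_edges
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_residue_graph(
    traj: EnsembleTrajectory,
    dccm: CorrelationMatrix,
    contact_cutoff: float = 6.0,
    occupancy_min: float = 0.5,
    corr_min: float = 0.05,
) -> ResidueGraph:
    """Contact + correlation graph over the DCCM's labels.

    An edge (i, j) exists iff the i–j distance is ≤ ``contact_cutoff`` Å in
    at least ``occupancy_min`` of the frames and |C_ij| ≥ ``corr_min``.
    Edge length is −log|C_ij|, clamped at 1e-6 for perfectly correlated
    pairs (logged).
    """
    missing = [lb for lb in dccm.labels if lb not in traj.labels]
    if missing:
        raise NetworkError(f"DCCM labels absent from ensemble: {missing}")
    sub = traj.select(list(dccm.labels))
    n = len(dccm.labels)
    diff = sub.coords[:, :, None, :] - sub.coords[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)           # (frames, n, n)
    occupancy = (dist <= contact_cutoff).mean(axis=0)

    g = nx.Graph()
    g.add_nodes_from(dccm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            c = dccm.values[i, j]
            if occupancy[i, j] >= occupancy_min and abs(c) >= corr_min:
                length = -math.log(abs(c)) if abs(c) < 1.0 else 0.0
                if length < MIN_EDGE_LENGTH:
                    logger.info(
                        "edge (%s, %s): |C| = 1, length clamped to %g",
                        dccm.labels[i], dccm.labels[j], MIN_EDGE_LENGTH)
                    length = MIN_EDGE_LENGTH
                g.add_edge(dccm.labels[i], dccm.labels[j],
                           occupancy=float(occupancy[i, j]),
                           correlation=float(c), length=float(length))
    if g.number_of_edges() == 0:
        raise NetworkError(
            "no edges survive the contact/correlation thresholds "
            f"(cutoff {contact_cutoff} Å, occupancy {occupancy_min}, "
            f"|C| ≥ {corr_min})")
    return ResidueGraph(graph=g)


# ---------------------------------------------------------------------------
# deterministic Dijkstra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShortestPath:
    source: str
    target: str
    path: tuple | None        # None when the target is unreachable
    length: float             # inf when unreachable

    @property
    def reachable(self) -> bool:
        return self.path is not None


def _dijkstra_all(g: nx.Graph, source) -> dict:
    """Single-source Dijkstra returning, per node, (length, path tuple).

    Among exactly equal-length alternatives the lexicographically smallest
    node sequence wins, making shortest-path maps deterministic.
    """
    best: dict = {}
    heap = [(0.0, (source,))]
    while heap:
        d, path = heapq.heappop(heap)
        u = path[-1]
        if u in best and (d, path) >= best[u]:
            continue
        best[u] = (d, path)
        for v, data in g[u].items():
            nd = d + data["length"]
            if v not in best or (nd, path + (v,)) < best[v]:
                heapq.heappush(heap, (nd, path + (v,)))
    return best


def shortest_path(rg: ResidueGraph, source, target) -> ShortestPath:
    """Minimal-length path between two residues (explicit no-path result)."""
    g = rg.graph
    if source == target:
        raise NetworkError("source and target must differ")
    for node in (source, target):
        if node not in g:
            raise NetworkError(f"unknown node {node!r}")
    best = _dijkstra_all(g, source)
    if target not in best:
        return ShortestPath(source, target, None, math.inf)
    d, path = best[target]
    return ShortestPath(source, target, path, d)


@dataclass(frozen=True)
class SpmResult:
    """Shortest-path-map scores.

    ``edge_usage`` maps each edge (as a sorted node pair) to its usage
    normalized by the maximum; ``spm_edges`` are the edges at or above the
    display threshold; ``node_weight`` aggregates incident edge usage.
    """

    edge_usage: dict
    spm_edges: set
    node_weight: dict
    threshold: float
    n_components: int

    def to_csv(self, path) -> None:
        rows = [{"node_i": u, "node_j": v, "usage": usage,
                 "in_spm": (u, v) in self.spm_edges}
                for (u, v), usage in sorted(self.edge_usage.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


def compute_spm(
    rg: ResidueGraph, threshold: float = 0.3, pairs: str = "all"
) -> SpmResult:
    """Score every edge by shortest-path usage and keep the strongest.

    ``pairs="all"`` accumulates usage over shortest paths between all
    ordered node pairs (within each connected component); ``pairs="ends"``
    uses only the single path from the lexicographically first to the last
    node — an alternative reading of path-map construction kept behind this
    flag.  Usage is divided by its maximum so the strongest edge scores 1;
    ``spm_edges`` are those with usage ≥ ``threshold``.
    """
    g = rg.graph
    usage: dict = {tuple(sorted(e)): 0.0 for e in g.edges}
    components = list(nx.connected_components(g))
    if len(components) > 1:
        logger.warning("graph has %d components; SPM computed per component",
                       len(components))

    if pairs == "all":
        sources = sorted(g.nodes)
        for s in sources:
            best = _dijkstra_all(g, s)
            for t, (_, path) in best.items():
                if t == s:
                    continue
                for a, b in zip(path[:-1], path[1:]):
                    usage[tuple(sorted((a, b)))] += 1.0
    elif pairs == "ends":
        for comp in components:
            nodes = sorted(comp)
            if len(nodes) < 2:
                continue
            sp = shortest_path(rg, nodes[0], nodes[-1])
            for a, b in zip(sp.path[:-1], sp.path[1:]):
                usage[tuple(sorted((a, b)))] += 1.0
    else:
        raise NetworkError(f"unknown pairs policy {pairs!r}")

    max_usage = max(usage.values()) if usage else 0.0
    if max_usage > 0:
        usage = {e: u / max_usage for e, u in usage.items()}
    spm_edges = {e for e, u in usage.items() if u >= threshold and u > 0}
    node_weight: dict = {node: 0.0 for node in g.nodes}
    for (a, b), u in usage.items():
        node_weight[a] += u
        node_weight[b] += u
    return SpmResult(edge_usage=usage, spm_edges=spm_edges,
                     node_weight=node_weight, threshold=threshold,
                     n_components=len(components))


@dataclass(frozen=True)
class CplResult:
    cpl: float
    n_pairs: int              # reachable unordered pairs
    reachable_fraction: float


def characteristic_path_length(rg: ResidueGraph) -> CplResult:
    """Mean shortest-path length over all reachable unordered node pairs.

    On a disconnected graph the mean runs over reachable pairs only and
    the reachable fraction is reported alongside.
    """
    g = rg.graph
    n = g.number_of_nodes()
    if n < 2:
        raise NetworkError("need ≥ 2 nodes for a path length")
    total, pairs = 0.0, 0
    for s, dists in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for t, d in dists.items():
            if s < t:
                total += d
                pairs += 1
    all_pairs = n * (n - 1) // 2
    if pairs == 0:
        raise NetworkError("no reachable pairs in graph")
    return CplResult(cpl=total / pairs, n_pairs=pairs,
                     reachable_fraction=pairs / all_pairs)


@dataclass(frozen=True)
class NodeWeakeningTable:
    """CPL-change ranking for candidate node removals.

    ``table`` columns: node, cpl_without_node, delta_cpl, disconnects,
    reachable_fraction — sorted by |delta_cpl| descending.
    """

    baseline_cpl: float
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def node_weakening(rg: ResidueGraph, candidates=None) -> NodeWeakeningTable:
    """CPL of the graph with each candidate node removed, ranked by |ΔCPL|.

    Removal can disconnect the remainder; CPL is then computed over the
    remaining reachable pairs and the event is flagged.
    """
    g = rg.graph
    if candidates is None:
        candidates = sorted(g.nodes)
    unknown = [c for c in candidates if c not in g]
    if unknown:
        raise NetworkError(f"unknown candidate node(s): {unknown}")
    base = characteristic_path_length(rg)
    rows = []
    for node in candidates:
        h = g.copy()
        h.remove_node(node)
        if h.number_of_nodes() < 2:
            raise NetworkError("removal leaves fewer than 2 nodes")
        try:
            res = characteristic_path_length(ResidueGraph(graph=h))
            cpl_wo, frac = res.cpl, res.reachable_fraction
        except NetworkError:      # fully disconnected remainder
            cpl_wo, frac = math.nan, 0.0
        rows.append({
            "node": node,
            "cpl_without_node": cpl_wo,
            "delta_cpl": cpl_wo - base.cpl,
            "disconnects": frac < 1.0,
            "reachable_fraction": frac,
        })
    df = pd.DataFrame(rows)
    df = df.reindex(
        df["delta_cpl"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return NodeWeakeningTable(baseline_cpl=base.cpl, table=df)
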