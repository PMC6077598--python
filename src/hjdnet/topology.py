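"""NetworkAnalyzer-style topology metrics, centralities and hub screening.

Reproduces the parameter suite a Cytoscape NetworkAnalyzer run prints for an
undirected simple graph (node/edge counts, clustering, diameter, radius,
Freeman degree centralization, shortest-path bookkeeping, density, degree
heterogeneity), the per-node degree / betweenness / closeness centralities,
and the hub rule used in network pharmacology: a node is a *hub* when its
degree is at least ``hub_multiplier`` (conventionally 2) times the mean
degree of the graph.

Conventions, chosen to match NetworkAnalyzer:

* closeness is component-restricted: reachable count divided by the sum of
  distances to reachable nodes (no Wasserman-Faust rescaling);
* betweenness is normalized by (n-1)(n-2)/2;
* shortest-path count and characteristic path length run over ordered
  node pairs at finite distance;
* mean clustering includes degree-<2 nodes as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import DegenerateGraphError

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyReport",
    "CentralityRow",
    "topology_report",
    "freeman_centralization",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "rank_centralities",
    "hub_screen",
]


@dataclass(frozen=True)
class TopologyReport:
    """The full topology parameter suite for one undirected simple graph."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    connected_components: int
    diameter: int
    radius: int
    centralization: float
    shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float
    isolated_nodes: int
    self_loops: int = 0
    multiedge_pairs: int = 0

    def to_rows(self) -> list[tuple[str, float]]:
        """(parameter, value) rows in a NetworkAnalyzer-like layout."""
        return [(f.name, getattr(self, f.name)) for f in fields(self)]


@dataclass(frozen=True)
class CentralityRow:
    """Per-node centrality record (degree, betweenness, closeness)."""

    node: str
    degree: int
    betweenness: float
    closeness: float


def freeman_centralization(n_nodes: int, max_degree: int, n_edges: int) -> float:
    """Freeman degree centralization from graph-level bookkeeping.

    Point form ``(n/(n-2)) * (d_max/(n-1) - density)``, equivalent to the
    classical sum ``sum(d_max - d_i) / ((n-1)(n-2))``.  Defined as 0 for
    graphs with fewer than 3 nodes.
    """
    if n_nodes < 3:
        return 0.0
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    return (n_nodes / (n_nodes - 2.0)) * (max_degree / (n_nodes - 1.0) - density)


def topology_report(net: nx.Graph) -> TopologyReport:
    """Compute the full topology parameter suite of an undirected graph.

    Diameter and radius refer to the largest connected component when the
    graph is disconnected; path-length statistics run over all ordered node
    pairs at finite distance.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise DegenerateGraphError(f"topology analysis needs >= 2 nodes, got {n}")
    e = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)

    components = list(nx.connected_components(net))
    # path statistics over ordered finite pairs, component by component
    n_pairs = 0
    total_length = 0.0
    diameter = 0
    radius = 0
    largest = max(components, key=len)
    for comp in components:
        k = len(comp)
        if k < 2:
            continue
        sub = net.subgraph(comp)
        n_pairs += k * (k - 1)
        total_length += nx.average_shortest_path_length(sub) * k * (k - 1)
        if comp is largest:
            ecc = nx.eccentricity(sub)
            diameter = max(ecc.values())
            radius = min(ecc.values())

    mean_deg = degrees.mean()
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=float(nx.average_clustering(net, count_zeros=True)),
        connected_components=len(components),
        diameter=int(diameter),
        radius=int(radius),
        centralization=freeman_centralization(n, int(degrees.max()), e),
        shortest_paths=int(n_pairs),
        characteristic_path_length=(total_length / n_pairs) if n_pairs else 0.0,
        avg_neighbors=float(mean_deg),
        density=float(2.0 * e / (n * (n - 1))),
        heterogeneity=float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0,
        isolated_nodes=int((degrees == 0).sum()),
        # graphs are simple by construction; ingestion drops and logs any
        self_loops=0,
        multiedge_pairs=0,
    )


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw neighbor counts per node."""
    return {n: int(d) for n, d in net.degree()}


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Component-restricted closeness: reachable count / sum of distances."""
    return {n: float(v) for n, v in
            nx.closeness_centrality(net, wf_improved=False).items()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Brandes betweenness, normalized by (n-1)(n-2)/2."""
    return {n: float(v) for n, v in
            nx.betweenness_centrality(net, normalized=True).items()}


def _rank(values: Mapping[str, float], rows: Mapping[str, CentralityRow],
          k: int) -> list[CentralityRow]:
    order = sorted(values, key=lambda n: (-values[n], n))
    return [rows[n] for n in order[:k]]


def rank_centralities(net: nx.Graph, k: int) -> dict[str, list[CentralityRow]]:
    """Top-k nodes by each of the three centralities, independently ranked.

    Returns a mapping ``{"degree": [...], "betweenness": [...],
    "closeness": [...]}``; each list is descending in its own metric with
    ties broken by ascending node name.
    """
    n = net.number_of_nodes()
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    deg = degree_centrality(net)
    bet = betweenness_centrality(net)
    clo = closeness_centrality(net)
    rows = {v: CentralityRow(node=v, degree=deg[v], betweenness=bet[v],
                             closeness=clo[v]) for v in net.nodes}
    return {
        "degree": _rank({v: float(d) for v, d in deg.items()}, rows, k),
        "betweenness": _rank(bet, rows, k),
        "closeness": _rank(clo, rows, k),
    }


def hub_screen(degrees: Mapping[str, int], avg_neighbors: float) -> list[str]:
    """Nodes whose degree is at least twice the mean degree.

    ``avg_neighbors`` is the graph's mean degree; the threshold
    ``2 * avg_neighbors`` is applied inclusively.  Hubs are returned in
    descending degree order, ties broken by ascending name.
    """
    if avg_neighbors <= 0:
        raise ValueError("avg_neighbors must be positive")
    threshold = 2.0 * avg_neighbors
    hubs = [n for n, d in degrees.items() if d >= threshold]
    hubs.sort(key=lambda n: (-degrees[n], n))
    logger.info("hub_screen: %d hub(s) at degree >= %.3f", len(hubs), threshold)
    return hubs
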