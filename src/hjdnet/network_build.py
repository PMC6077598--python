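"""Compound-target and protein-protein interaction network assembly.

Builds the bipartite network linking active ingredients to their predicted
protein targets, intersects it with a disease-target gene list to obtain the
compound-cancer-target network, and reads/writes undirected edge lists
(Cytoscape SIF or two-column TSV).  Graphs are plain :class:`networkx.Graph`
objects: nodes carry a ``kind`` attribute (``"compound"`` or ``"target"``)
and edges a ``type`` label.  All graphs are kept simple — self-loops and
duplicate edges are dropped on ingestion with logged counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .compound_screen import Compound
from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "TargetPrediction",
    "COMPOUND", "TARGET",
    "filter_predictions",
    "build_compound_target_network",
    "map_to_disease_targets",
    "read_network", "write_network",
    "read_gene_list", "write_gene_list",
    "canonical_gene_list",
]

COMPOUND = "compound"
TARGET = "target"


@dataclass(frozen=True)
class TargetPrediction:
    """One compound-to-target prediction with its classifier confidence.

    ``score`` follows SVM-score semantics: predictions are accepted when the
    score strictly exceeds the chosen cutoff (0.7 by convention).
    """

    compound: str
    target: str
    score: float

    def __post_init__(self):
        if not self.compound or not self.target:
            raise ValueError("prediction compound and target must be nonempty")
        if self.score != self.score:  # NaN
            raise ValueError("prediction score must be finite")


def canonical_gene_list(symbols: Iterable[str]) -> list[str]:
    """Upper-case gene symbols, deduplicated, first-occurrence order."""
    seen: set[str] = set()
    out: list[str] = []
    for s in symbols:
        g = s.strip().upper()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def filter_predictions(
    preds: Sequence[TargetPrediction], score_min: float = 0.7
) -> list[TargetPrediction]:
    """Keep predictions whose score strictly exceeds ``score_min``."""
    kept = [p for p in preds if p.score > score_min]
    logger.info("prediction filter: %d in, %d kept at score > %g",
                len(preds), len(kept), score_min)
    return kept


def build_compound_target_network(
    compounds: Sequence[Compound], preds: Sequence[TargetPrediction]
) -> nx.Graph:
    """Assemble the bipartite compound-target network.

    Prediction rows referencing a compound absent from ``compounds`` are
    skipped with a warning (this supports reruns on a partial library).
    Duplicate associations collapse to a single edge; target symbols are
    canonicalized to upper case.
    """
    by_name = {c.name.strip().casefold(): c.name for c in compounds}
    net = nx.Graph()
    skipped = 0
    for p in preds:
        cname = by_name.get(p.compound.strip().casefold())
        if cname is None:
            skipped += 1
            continue
        tname = p.target.strip().upper()
        if cname == tname:
            continue  # keep the graph simple
        net.add_node(cname, kind=COMPOUND)
        net.add_node(tname, kind=TARGET)
        net.add_edge(cname, tname, type="compound-target")
    if skipped:
        logger.warning("build_compound_target_network: skipped %d prediction(s) "
                       "whose compound is not in the library", skipped)
    if net.number_of_edges() == 0:
        logger.warning("build_compound_target_network: no valid associations; "
                       "returning an empty network")
    return net


def map_to_disease_targets(
    net: nx.Graph, disease: Sequence[str]
) -> tuple[nx.Graph, list[str]]:
    """Intersect a compound-target network with a disease-target gene list.

    Returns the induced subnetwork keeping only target nodes found in
    ``disease`` (compounds retain membership only while they keep >= 1 edge)
    together with the retained targets, ordered as in ``disease``.
    """
    disease_set = set(canonical_gene_list(disease))
    keep = set()
    for node, data in net.nodes(data=True):
        if data.get("kind") == TARGET and node in disease_set:
            keep.add(node)
        elif data.get("kind") == COMPOUND:
            keep.add(node)
    sub = net.subgraph(keep).copy()
    sub.remove_nodes_from([
        n for n, d in sub.nodes(data=True)
        if d.get("kind") == COMPOUND and sub.degree(n) == 0
    ])
    retained = [g for g in canonical_gene_list(disease) if sub.has_node(g)]
    if not retained:
        logger.warning("map_to_disease_targets: empty intersection with the "
                       "disease-target list")
    logger.info("map_to_disease_targets: %d target(s) retained", len(retained))
    return sub, retained


def read_network(path: str | Path, dialect: str = "sif") -> nx.Graph:
    """Read an undirected edge list in SIF or two-column TSV form.

    Self-loops and duplicate edges are dropped; their counts are logged and
    stored on the graph as ``self_loops_dropped`` / ``duplicate_edges_dropped``.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = nx.Graph()
    self_loops = duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if dialect == "sif":
                if len(fields) != 3:
                    raise ParseError(
                        f"{path}: SIF record needs 3 tab-separated fields, "
                        f"got {len(fields)}", line=lineno)
                a, etype, b = fields
            else:
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}: TSV edge record needs 2 fields, got "
                        f"{len(fields)}", line=lineno)
                a, b = fields
                etype = "pp"
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise ParseError(f"{path}: empty endpoint", line=lineno)
            if a == b:
                self_loops += 1
                continue
            if net.has_edge(a, b):
                duplicates += 1
                continue
            net.add_edge(a, b, type=etype)
    if self_loops:
        logger.info("read_network(%s): dropped %d self-loop(s)", path, self_loops)
    if duplicates:
        logger.info("read_network(%s): dropped %d duplicate edge(s)", path, duplicates)
    net.graph["self_loops_dropped"] = self_loops
    net.graph["duplicate_edges_dropped"] = duplicates
    return net


def write_network(net: nx.Graph, path: str | Path, dialect: str = "sif") -> None:
    """Write an edge list; inverse of :func:`read_network` up to edge order."""
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for a, b, data in sorted(net.edges(data=True)):
            if dialect == "sif":
                fh.write(f"{a}\t{data.get('type', 'pp')}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; canonicalized to upper case."""
    with open(path) as fh:
        return canonical_gene_list(fh.readlines())


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
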