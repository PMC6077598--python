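"""Hypergeometric over-representation analysis of gene lists.

Given a query gene list (here: the cancer targets of a formula) and a
collection of category gene sets (e.g. KEGG pathways) defined over a
reference universe of ``N`` genes, each category of size ``C`` overlapping
the ``n``-gene query in ``O`` genes is scored with

* ``E = n * C / N`` — the overlap expected by chance,
* ``R = O / E`` — the ratio of enrichment,
* ``rawP = P(X >= O)`` for ``X ~ Hypergeometric(N, C, n)``,
* ``adjP`` — Benjamini-Hochberg step-up adjustment over the ``m`` tested
  categories.

This is the classic WebGestalt-style ORA statistics line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .errors import EmptyInputError, ParseError
from .network_build import canonical_gene_list

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "select_top",
    "pathway_overlap",
    "read_gmt",
    "write_gmt",
    "write_results",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's ORA statistics row (C, O, E, R, rawP, adjP, genes)."""

    category: str
    c: int
    o: int
    e: float
    r: float
    raw_p: float
    adj_p: float
    genes: tuple[str, ...]


class GeneSetCollection:
    """Category gene sets over a reference universe.

    Category genes outside the reference are dropped (with a debug log);
    ``m`` counts categories retaining at least one reference gene, and is
    the divisor pool for the BH adjustment.
    """

    def __init__(self, categories: Mapping[str, Sequence[str]],
                 reference: Sequence[str] | None = None):
        raw = {name: canonical_gene_list(genes) for name, genes in categories.items()}
        if reference is None:
            # default universe: the union of all category genes
            union: list[str] = []
            seen: set[str] = set()
            for genes in raw.values():
                for g in genes:
                    if g not in seen:
                        seen.add(g)
                        union.append(g)
            reference = union
        self.reference: tuple[str, ...] = tuple(canonical_gene_list(reference))
        ref_set = set(self.reference)
        self.categories: dict[str, tuple[str, ...]] = {}
        for name, genes in raw.items():
            kept = tuple(g for g in genes if g in ref_set)
            if len(kept) < len(genes):
                logger.debug("category %s: dropped %d gene(s) outside the "
                             "reference", name, len(genes) - len(kept))
            self.categories[name] = kept

    @property
    def n_reference(self) -> int:
        return len(self.reference)

    @property
    def m(self) -> int:
        """Number of tested categories (>= 1 reference gene)."""
        return sum(1 for genes in self.categories.values() if genes)


def read_gmt(path: str | Path, reference: Sequence[str] | None = None
             ) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...); description ignored."""
    categories: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: GMT record needs name, description "
                                 "and >= 1 gene", line=lineno)
            categories[fields[0]] = fields[2:]
    return GeneSetCollection(categories, reference=reference)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write the category sets as GMT (description column left as '-')."""
    with open(path, "w") as fh:
        for name, genes in collection.categories.items():
            fh.write("\t".join([name, "-", *genes]) + "\n")


def hypergeom_upper_tail(N: int, C: int, n: int, O: int) -> float:
    """Upper-tail probability ``P(X >= O)``, ``X ~ Hypergeometric(N, C, n)``.

    ``N`` is the universe size, ``C`` the category size, ``n`` the query
    size and ``O`` the observed overlap.  Inclusive upper tail, so ``O = 0``
    returns exactly 1.
    """
    if not (0 <= C <= N and 0 <= n <= N and 0 <= O <= min(C, n)):
        raise ValueError(
            f"invalid hypergeometric bounds: N={N}, C={C}, n={n}, O={O}")
    if O == 0:
        return 1.0
    return float(hypergeom.sf(O - 1, N, C, n))


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m`` is the number of tests adjusted for; it may exceed ``len(pvalues)``
    when only a subset of the tested categories is being reported.
    ``adjP_(i) = min_{j >= i} (m * p_(j) / j)``, clipped at 1.
    """
    k = len(pvalues)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m={m} smaller than number of p-values ({k})")
    for p in pvalues:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    order = sorted(range(k), key=lambda i: pvalues[i])
    adjusted = [0.0] * k
    running = 1.0
    for rank in range(k, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def enrich(query: Sequence[str], collection: GeneSetCollection
           ) -> list[EnrichmentResult]:
    """Score every category against the query gene list.

    Query genes outside the reference are dropped with a warning; ``n`` is
    the retained count.  Results are sorted ascending by rawP, ties by
    descending R then category name.
    """
    q = canonical_gene_list(query)
    ref_set = set(collection.reference)
    retained = [g for g in q if g in ref_set]
    dropped = len(q) - len(retained)
    if dropped:
        logger.warning("enrich: dropped %d query gene(s) outside the reference",
                       dropped)
    if not retained:
        raise EmptyInputError("no query genes map into the reference universe")
    n = len(retained)
    N = collection.n_reference
    m = collection.m
    qset = set(retained)

    results = []
    for name, genes in collection.categories.items():
        if not genes:
            continue
        C = len(genes)
        gene_set = set(genes)
        overlap = tuple(g for g in retained if g in gene_set)
        O = len(overlap)
        E = n * C / N
        R = (O / E) if O else 0.0
        results.append(EnrichmentResult(
            category=name, c=C, o=O, e=E, r=R,
            raw_p=hypergeom_upper_tail(N, C, n, O), adj_p=0.0, genes=overlap,
        ))
    adj = bh_adjust([r.raw_p for r in results], m=m)
    results = [EnrichmentResult(r.category, r.c, r.o, r.e, r.r, r.raw_p, a,
                                r.genes) for r, a in zip(results, adj)]
    results.sort(key=lambda r: (r.raw_p, -r.r, r.category))
    return results


def select_top(results: Sequence[EnrichmentResult], k: int,
               adjp_max: float = 0.01) -> list[EnrichmentResult]:
    """First ``k`` results with ``adjP`` strictly below ``adjp_max``."""
    return [r for r in results if r.adj_p < adjp_max][:k]


def pathway_overlap(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Case-folded intersection of two gene lists, ordered as in ``a``."""
    b_set = set(canonical_gene_list(b))
    return [g for g in canonical_gene_list(a) if g in b_set]


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write ORA results as TSV (category, C, O, E, R, rawP, adjP, genes)."""
    df = pd.DataFrame([{
        "category": r.category, "C": r.c, "O": r.o, "E": r.e, "R": r.r,
        "rawP": r.raw_p, "adjP": r.adj_p, "genes": ";".join(r.genes),
    } for r in results])
    df.to_csv(path, sep="\t", index=False)
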