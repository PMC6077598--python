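"""Curated reference tables for the HJD formula, distributed with the package.

Three small TSVs re-typed from the published HJD analysis are bundled so
that the desk-scale results can be recomputed offline:

* ``hjd_active_ingredients.tsv`` — the 60 active ingredients of the four
  herbs (Huanglian, Huangqin, Huangbo, Zhizi) with their OB (%) and DL;
* ``ppi_centrality_top30.tsv`` — the top-30 nodes of the 98-protein
  cancer-target interaction network under each of the three centralities;
* ``ppi_topology.tsv`` — the graph-level topology parameters of that
  network (98 nodes, 1027 edges, mean degree 20.959, ...);
* ``kegg_pathways_top10.tsv`` — the ten top-ranked KEGG pathways with
  their ORA statistics (C, O, E, R, rawP, adjP) and member genes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compound_screen import Compound

__all__ = [
    "load_active_ingredients",
    "load_ppi_centrality",
    "load_ppi_topology",
    "load_kegg_pathways",
    "kegg_gene_set",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hjdnet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_active_ingredients() -> list[Compound]:
    """The screened HJD active-ingredient table as Compound records."""
    df = _read("hjd_active_ingredients.tsv")
    return [Compound(name=r["name"], herb=r["herb"], ob=float(r["ob"]),
                     dl=float(r["dl"])) for _, r in df.iterrows()]


def load_ppi_centrality() -> pd.DataFrame:
    """Tidy top-30 centrality rankings: columns metric, rank, node, value."""
    return _read("ppi_centrality_top30.tsv")


def load_ppi_topology() -> dict[str, float]:
    """Graph-level topology parameters as a name -> value mapping."""
    df = _read("ppi_topology.tsv")
    return dict(zip(df["parameter"], df["value"].astype(float)))


def load_kegg_pathways() -> pd.DataFrame:
    """Top-10 KEGG ORA rows; ``genes`` column is semicolon-joined."""
    return _read("kegg_pathways_top10.tsv")


def kegg_gene_set(pathway: str) -> list[str]:
    """Member genes of one bundled KEGG pathway row."""
    df = load_kegg_pathways()
    row = df.loc[df["pathway"] == pathway]
    if row.empty:
        raise KeyError(f"no bundled pathway named {pathway!r}")
    return row.iloc[0]["genes"].split(";")
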