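"""End-to-end orchestration of the five analysis stages.

The workflow runs, in order: ADME compound screening; compound-target and
compound-cancer-target network assembly; topology and hub analysis of the
target interaction graph; KEGG-style over-representation analysis of the
cancer targets; and cancer-genomics mining (alteration summary, OncoPrint
ordering, pairwise mutual exclusivity, altered-vs-unaltered survival).
Stages with missing optional inputs are skipped with a logged notice;
filter bookkeeping (counts in/out at every threshold) is logged throughout
because those counts *are* the analysis narrative.

Everything is deterministic given the input files, so a rerun reproduces
the report byte for byte.  Provenance records the config hash and package
version; no wall-clock timestamp is stored, by design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .compound_screen import Compound, ScreenCriteria, read_compound_table, \
    screen_compounds, write_compound_table
from .enrichment import EnrichmentResult, enrich, read_gmt, select_top, \
    write_results
from .errors import ConfigError
from .genomics import MutexResult, SurvivalComparison, alteration_summary, \
    mutual_exclusivity, oncoprint_order, read_alteration_table, \
    read_survival_table, survival_by_alteration
from .network_build import TargetPrediction, build_compound_target_network, \
    filter_predictions, map_to_disease_targets, read_gene_list, read_network, \
    write_gene_list, write_network
from .topology import CentralityRow, TopologyReport, hub_screen, \
    rank_centralities, topology_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "export_report",
           "load_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths and thresholds for one pipeline run.

    Threshold defaults are the conventional ones: OB >= 30%, DL >= 0.18,
    prediction score > 0.7, hubs at 2x the mean degree, top 30 per
    centrality, top 10 pathways at adjusted P < 0.01.
    """

    compounds: str | Path
    predictions: str | Path
    disease_targets: str | Path
    ppi: str | Path | None = None
    gene_sets: str | Path | None = None
    reference: str | Path | None = None
    alterations: str | Path | None = None
    survival: str | Path | None = None
    genomics_genes: tuple[str, ...] | None = None

    ob_min: float = 30.0
    dl_min: float = 0.18
    score_min: float = 0.7
    hub_multiplier: float = 2.0
    top_k_centrality: int = 30
    top_k_pathways: int = 10
    adjp_max: float = 0.01

    def __post_init__(self):
        for name in ("compounds", "predictions", "disease_targets"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ConfigError(f"required input {name!r} missing: {p}")
        for name in ("ppi", "gene_sets", "reference", "alterations", "survival"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input {name!r} not found: {p}")
        if not (self.ob_min >= 0 and 0 <= self.dl_min <= 1):
            raise ConfigError("OB/DL thresholds out of range")
        if self.hub_multiplier <= 0 or self.top_k_centrality <= 0 \
                or self.top_k_pathways <= 0 or not 0 < self.adjp_max <= 1:
            raise ConfigError("threshold out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("compounds", "predictions", "disease_targets", "ppi",
                    "gene_sets", "reference", "alterations", "survival"):
            if data.get(key) is not None:
                p = Path(data[key])
                data[key] = str(p if p.is_absolute() else base / p)
        if data.get("genomics_genes") is not None:
            data["genomics_genes"] = tuple(data["genomics_genes"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def content_hash(self) -> str:
        """SHA-256 over thresholds and the contents of every input file."""
        h = hashlib.sha256()
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (str, Path)) and Path(v).exists():
                h.update(Path(v).read_bytes())
            else:
                h.update(repr(v).encode())
        return h.hexdigest()


@dataclass
class PipelineReport:
    """All stage outputs of one run, plus provenance."""

    retained: list[Compound]
    discarded: list[Compound]
    kept_predictions: list[TargetPrediction]
    compound_target_network: nx.Graph
    cancer_network: nx.Graph
    cancer_targets: list[str]
    ppi: nx.Graph | None = None
    topology: TopologyReport | None = None
    centralities: dict[str, list[CentralityRow]] | None = None
    hubs: list[str] | None = None
    enrichment: list[EnrichmentResult] | None = None
    top_pathways: list[EnrichmentResult] | None = None
    alteration_freq: dict[str, float] | None = None
    altered_fraction: float | None = None
    oncoprint: tuple[list[str], list[str]] | None = None
    mutex: list[MutexResult] | None = None
    survival: SurvivalComparison | None = None
    provenance: dict[str, Any] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the five stages in order; see the module docstring."""
    # stage 1: ADME screen
    library = read_compound_table(cfg.compounds)
    retained, discarded = screen_compounds(
        library, ScreenCriteria(cfg.ob_min, cfg.dl_min))

    # stage 2: network assembly
    pred_df = pd.read_csv(cfg.predictions, sep="\t")
    preds = [TargetPrediction(str(r["compound"]), str(r["target"]),
                              float(r["score"])) for _, r in pred_df.iterrows()]
    kept = filter_predictions(preds, cfg.score_min)
    ct_net = build_compound_target_network(retained, kept)
    disease = read_gene_list(cfg.disease_targets)
    cancer_net, cancer_targets = map_to_disease_targets(ct_net, disease)

    report = PipelineReport(
        retained=retained, discarded=discarded, kept_predictions=kept,
        compound_target_network=ct_net, cancer_network=cancer_net,
        cancer_targets=cancer_targets,
        provenance={
            "config_hash": cfg.content_hash(),
            "package_version": __version__,
            "thresholds": {
                "ob_min": cfg.ob_min, "dl_min": cfg.dl_min,
                "score_min": cfg.score_min,
                "hub_multiplier": cfg.hub_multiplier,
                "top_k_centrality": cfg.top_k_centrality,
                "top_k_pathways": cfg.top_k_pathways,
                "adjp_max": cfg.adjp_max,
            },
        },
    )

    # stage 3: topology + hubs
    if cfg.ppi is not None:
        ppi = read_network(cfg.ppi, dialect="sif")
        report.ppi = ppi
        report.topology = topology_report(ppi)
        k = min(cfg.top_k_centrality, ppi.number_of_nodes())
        report.centralities = rank_centralities(ppi, k)
        degrees = {n: int(d) for n, d in ppi.degree()}
        # hub rule generalized to `hub_multiplier` x mean degree
        threshold_avg = report.topology.avg_neighbors * cfg.hub_multiplier / 2.0
        report.hubs = hub_screen(degrees, threshold_avg)
    else:
        logger.info("pipeline: no PPI input; topology stage skipped")

    # stage 4: enrichment
    if cfg.gene_sets is not None:
        reference = read_gene_list(cfg.reference) if cfg.reference else None
        collection = read_gmt(cfg.gene_sets, reference=reference)
        results = enrich(cancer_targets, collection)
        report.enrichment = results
        report.top_pathways = select_top(results, cfg.top_k_pathways,
                                         cfg.adjp_max)
    else:
        logger.info("pipeline: no gene-set input; enrichment stage skipped")

    # stage 5: genomics
    if cfg.alterations is not None:
        mat = read_alteration_table(cfg.alterations)
        query = list(cfg.genomics_genes) if cfg.genomics_genes else \
            [g for g in (report.hubs or cancer_targets) if g in set(mat.genes)]
        if not query:
            logger.warning("pipeline: no query gene present in the alteration "
                           "matrix; genomics stage skipped")
        else:
            freq, frac, _ = alteration_summary(mat, query)
            report.alteration_freq = freq
            report.altered_fraction = frac
            report.oncoprint = oncoprint_order(mat, query)
            report.mutex = [mutual_exclusivity(mat, a, b)
                            for a, b in itertools.combinations(query, 2)]
            if cfg.survival is not None:
                records = read_survival_table(cfg.survival)
                report.survival = survival_by_alteration(mat, query, records)
            else:
                logger.info("pipeline: no survival input; survival analysis "
                            "skipped")
    else:
        logger.info("pipeline: no alteration input; genomics stage skipped")

    return report


def _km_rows(km) -> list[dict[str, float]]:
    return [{"time": t, "survival": s} for t, s in zip(km.times, km.survival)]


def report_to_dict(report: PipelineReport) -> dict[str, Any]:
    """Lossless JSON-serializable view of a report."""
    d: dict[str, Any] = {
        "provenance": report.provenance,
        "retained": [dataclasses.asdict(c) for c in report.retained],
        "n_discarded": len(report.discarded),
        "n_kept_predictions": len(report.kept_predictions),
        "compound_target_network": {
            "nodes": report.compound_target_network.number_of_nodes(),
            "edges": report.compound_target_network.number_of_edges(),
        },
        "cancer_network": {
            "nodes": report.cancer_network.number_of_nodes(),
            "edges": report.cancer_network.number_of_edges(),
        },
        "cancer_targets": report.cancer_targets,
    }
    if report.topology is not None:
        d["topology"] = dataclasses.asdict(report.topology)
    if report.centralities is not None:
        d["centralities"] = {
            metric: [dataclasses.asdict(r) for r in rows]
            for metric, rows in report.centralities.items()}
    if report.hubs is not None:
        d["hubs"] = report.hubs
    if report.enrichment is not None:
        d["enrichment"] = [dataclasses.asdict(r) for r in report.enrichment]
        d["top_pathways"] = [r.category for r in report.top_pathways or []]
    if report.alteration_freq is not None:
        d["alteration_freq"] = report.alteration_freq
        d["altered_fraction"] = report.altered_fraction
        d["oncoprint"] = {"genes": report.oncoprint[0],
                          "samples": report.oncoprint[1]}
        d["mutex"] = [dataclasses.asdict(m) for m in report.mutex or []]
    if report.survival is not None:
        s = report.survival
        d["survival"] = {
            "n_altered": s.n_altered, "n_unaltered": s.n_unaltered,
            "logrank": dataclasses.asdict(s.logrank) if s.logrank else None,
            "km_altered": _km_rows(s.km_altered) if s.km_altered else None,
            "km_unaltered": _km_rows(s.km_unaltered) if s.km_unaltered else None,
        }
    return d


def export_report(report: PipelineReport, out_dir: str | Path) -> list[Path]:
    """Write TSV stage outputs plus the machine-readable JSON report.

    Idempotent: re-export overwrites each file with identical bytes.
    Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path):
        written.append(path)
        return path

    write_compound_table(report.retained, _w(out / "active_ingredients.tsv"))
    write_network(report.cancer_network, _w(out / "compound_cancer_net.sif"))
    write_gene_list(report.cancer_targets, _w(out / "cancer_targets.txt"))
    if report.topology is not None:
        pd.DataFrame(report.topology.to_rows(),
                     columns=["parameter", "value"]).to_csv(
            _w(out / "topology.tsv"), sep="\t", index=False)
        for metric, rows in (report.centralities or {}).items():
            pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
                _w(out / f"centrality_{metric}.tsv"), sep="\t", index=False)
        write_gene_list(report.hubs or [], _w(out / "hubs.txt"))
    if report.enrichment is not None:
        write_results(report.enrichment, _w(out / "enrichment.tsv"))
        write_results(report.top_pathways or [],
                      _w(out / "enrichment_top.tsv"))
    if report.mutex is not None:
        pd.DataFrame([{
            "gene_a": m.gene_a, "gene_b": m.gene_b,
            "both": m.table[0][0], "a_only": m.table[0][1],
            "b_only": m.table[1][0], "neither": m.table[1][1],
            "log2_odds": m.log2_odds, "p": m.p, "direction": m.direction,
        } for m in report.mutex]).to_csv(_w(out / "mutex.tsv"), sep="\t",
                                         index=False)
    if report.survival is not None:
        for label, km in (("altered", report.survival.km_altered),
                          ("unaltered", report.survival.km_unaltered)):
            if km is not None:
                pd.DataFrame(_km_rows(km)).to_csv(
                    _w(out / f"km_{label}.tsv"), sep="\t", index=False)
    with open(_w(out / "report.json"), "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
    return written


def load_report(path: str | Path) -> dict[str, Any]:
    """Reload the machine-readable JSON report."""
    with open(path) as fh:
        return json.load(fh)
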