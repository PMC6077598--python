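"""Seeded generators for every input the analysis pipeline consumes.

The real inputs of a network-pharmacology study — curated compound tables,
classifier target predictions, STRING protein-interaction exports, pathway
gene sets and tumor-cohort alteration/survival profiles — all come from web
services.  This module produces statistically analogous inputs from a single
root seed so that the whole pipeline can be exercised, and its statistical
behavior calibrated, without any download.

What is emulated (and what is not):

* compound libraries with a right-skewed OB law (lognormal) and a bounded
  DL law (Beta) — no actual chemistry;
* bipartite compound-target maps whose target degrees are heavy-tailed, so
  that hub structure exists downstream — scores are uniform, not a real
  classifier's margins;
* connected simple interaction graphs with exact node and edge counts,
  uniform over connected m-edge graphs via rejection;
* gene-set universes with one planted enriched category;
* cohorts with Bernoulli per-gene alterations (optionally coupled through a
  latent per-sample factor), exponential survival with a hazard-ratio effect
  for altered cases and independent exponential censoring.

Each generator draws from its own deterministic substream of the root seed,
so regenerating one input never perturbs the others.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .compound_screen import Compound, ScreenCriteria, screen_compounds, \
    write_compound_table
from .enrichment import GeneSetCollection, write_gmt
from .errors import ConfigError
from .genomics import ALTERATION_TYPES, AlterationMatrix, SurvivalRecord, \
    write_alteration_table, write_survival_table
from .network_build import TargetPrediction, build_compound_target_network, \
    filter_predictions, map_to_disease_targets, write_gene_list, write_network

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "gen_compound_library",
    "gen_target_map",
    "gen_ppi",
    "gen_genesets",
    "gen_cohort",
    "write_fixtures",
]

# substream indices: one per generator, so streams never collide
_STREAMS = {
    "compounds": 1,
    "targets": 2,
    "ppi": 3,
    "genesets": 4,
    "cohort": 5,
    "fixtures": 6,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-input generators, with study-scale defaults.

    Defaults mirror the scale of the HJD study: four herbs contributing
    48/143/140/98 compounds, ~1/5 of which pass the OB>=30 / DL>=0.18
    screen; a 98-node, 1027-edge interaction graph; a gene-set universe in
    the low thousands with ~300 tested categories of KEGG-like sizes; and
    ~100-sample cohorts with a 7-gene query.
    """

    seed: int = 0
    # compound library
    compounds_per_herb: dict[str, int] = field(default_factory=lambda: {
        "Huanglian": 48, "Huangqin": 143, "Huangbo": 140, "Zhizi": 98})
    ob_log_median: float = 20.0    # lognormal median of OB in percent
    ob_log_sigma: float = 0.75
    dl_alpha: float = 1.2          # Beta law for DL on [0, 1]
    dl_beta: float = 3.5
    screen_ob_min: float = 30.0
    screen_dl_min: float = 0.18
    # compound-target map
    n_targets: int = 200
    mean_targets_per_compound: float = 5.0
    target_degree_exponent: float = 2.5   # power-law pdf exponent of target degree
    disease_target_fraction: float = 0.6
    # interaction graph
    ppi_nodes: int = 98
    ppi_edges: int = 1027
    # gene-set universe
    universe_size: int = 2000
    n_categories: int = 300
    category_size_range: tuple[int, int] = (50, 400)
    query_size: int = 98
    planted_enrichment_fold: float = 5.0
    # cohort
    n_samples: int = 100
    n_query_genes: int = 7
    per_gene_alteration_rate: float = 0.15
    planted_log_odds: float = 0.0
    baseline_hazard: float = 0.02      # per month
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.3

    def __post_init__(self):
        counts = [*self.compounds_per_herb.values(), self.n_targets,
                  self.ppi_nodes, self.ppi_edges, self.universe_size,
                  self.n_categories, self.query_size, self.n_samples]
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if self.ppi_edges > self.ppi_nodes * (self.ppi_nodes - 1) // 2:
            raise ConfigError("ppi_edges exceeds the simple-graph maximum")
        for rate in (self.per_gene_alteration_rate, self.censoring_rate,
                     self.disease_target_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        if self.ob_log_sigma <= 0 or self.dl_alpha <= 0 or self.dl_beta <= 0:
            raise ConfigError("distribution parameters must be positive")
        if self.target_degree_exponent <= 1.0:
            raise ConfigError("target_degree_exponent must exceed 1")
        lo, hi = self.category_size_range
        if not (0 < lo <= hi <= self.universe_size):
            raise ConfigError("invalid category_size_range")
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ConfigError("hazard parameters must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream generator for one named generator."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "category_size_range" in data:
            data["category_size_range"] = tuple(data["category_size_range"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["category_size_range"] = list(self.category_size_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def gen_compound_library(cfg: GeneratorConfig
                         ) -> tuple[list[Compound], dict[tuple[str, str], bool]]:
    """Synthesize a per-herb compound library with OB/DL draws.

    Returns the library and ground-truth pass/fail labels at the config's
    screening thresholds; the labels agree exactly with
    :func:`~hjdnet.compound_screen.screen_compounds` on the same thresholds.
    """
    rng = cfg.rng("compounds")
    compounds: list[Compound] = []
    labels: dict[tuple[str, str], bool] = {}
    for herb in sorted(cfg.compounds_per_herb):
        for i in range(cfg.compounds_per_herb[herb]):
            ob = float(np.exp(rng.normal(math.log(cfg.ob_log_median),
                                         cfg.ob_log_sigma)))
            dl = float(rng.beta(cfg.dl_alpha, cfg.dl_beta))
            c = Compound(name=f"{herb.lower()}_cpd{i:03d}", herb=herb,
                         ob=ob, dl=dl)
            compounds.append(c)
            labels[c.key] = (ob >= cfg.screen_ob_min and dl >= cfg.screen_dl_min)
    return compounds, labels


def gen_target_map(cfg: GeneratorConfig, compounds: Sequence[Compound]
                   ) -> list[TargetPrediction]:
    """Predicted compound-target links with heavy-tailed target degrees.

    Target sampling weights follow a Zipf law ``w_r ~ r^(-1/(gamma-1))`` so
    that the resulting target-degree distribution has a power-law tail with
    pdf exponent approximately ``gamma = target_degree_exponent``.  Scores
    are uniform on [0, 1], so a score > 0.7 cut retains ~30%.
    """
    rng = cfg.rng("targets")
    targets = [f"T{j + 1:04d}" for j in range(cfg.n_targets)]
    alpha = 1.0 / (cfg.target_degree_exponent - 1.0)
    weights = np.arange(1, cfg.n_targets + 1, dtype=float) ** (-alpha)
    weights /= weights.sum()
    preds: list[TargetPrediction] = []
    for c in compounds:
        k = 1 + rng.poisson(max(cfg.mean_targets_per_compound - 1.0, 0.0))
        k = min(k, cfg.n_targets)
        chosen = rng.choice(cfg.n_targets, size=k, replace=False, p=weights)
        for j in sorted(chosen):
            preds.append(TargetPrediction(
                compound=c.name, target=targets[j],
                score=float(rng.uniform())))
    return preds


def gen_ppi(cfg: GeneratorConfig, nodes: Sequence[str] | None = None,
            n_edges: int | None = None) -> nx.Graph:
    """A connected simple graph with exact node and edge counts.

    Edges are an m-subset drawn uniformly from all node pairs; disconnected
    draws are rejected, so conditional on success the graph is uniform over
    connected m-edge graphs on the labeled nodes.
    """
    rng = cfg.rng("ppi")
    names = list(nodes) if nodes is not None \
        else [f"T{j + 1:04d}" for j in range(cfg.ppi_nodes)]
    n = len(names)
    m = cfg.ppi_edges if n_edges is None else n_edges
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ConfigError(f"cannot place {m} edges on {n} nodes")
    if m < n - 1:
        raise ConfigError(f"{m} edges cannot connect {n} nodes")
    pairs = list(itertools.combinations(range(n), 2))
    for _ in range(1000):
        idx = rng.choice(len(pairs), size=m, replace=False)
        g = nx.Graph()
        g.add_nodes_from(names)
        g.add_edges_from((names[pairs[i][0]], names[pairs[i][1]]) for i in idx)
        nx.set_edge_attributes(g, "pp", "type")
        if nx.is_connected(g):
            return g
    raise ConfigError("could not draw a connected graph; edge count too "
                      "sparse for rejection sampling")


def gen_genesets(cfg: GeneratorConfig, query: Sequence[str] | None = None
                 ) -> tuple[GeneSetCollection, list[str], str]:
    """Gene-set universe with one planted enriched category.

    Category members are drawn uniformly from the universe, except for the
    planted category, whose sampling weight for query genes is multiplied by
    ``planted_enrichment_fold`` — equivalently, its genes are over-sampled
    into the query at that fold.  With ``fold = 1`` the construction is an
    exact hypergeometric null.  Returns the collection, the query list and
    the planted category's name.
    """
    rng = cfg.rng("genesets")
    if query is not None:
        query = list(query)
        if len(query) > cfg.universe_size:
            raise ConfigError("query larger than the universe")
        filler = [f"G{j + 1:05d}" for j in range(cfg.universe_size - len(query))]
        universe = query + filler
    else:
        universe = [f"G{j + 1:05d}" for j in range(cfg.universe_size)]
        qidx = rng.choice(cfg.universe_size, size=cfg.query_size, replace=False)
        query = [universe[i] for i in sorted(qidx)]
    n_univ = len(universe)
    in_query = np.zeros(n_univ, dtype=bool)
    qset = set(query)
    for i, g in enumerate(universe):
        if g in qset:
            in_query[i] = True

    lo, hi = cfg.category_size_range
    planted_idx = int(rng.integers(cfg.n_categories))
    categories: dict[str, list[str]] = {}
    planted_name = ""
    for k in range(cfg.n_categories):
        size = int(rng.integers(lo, hi + 1))
        name = f"category_{k + 1:03d}"
        if k == planted_idx:
            w = np.where(in_query, cfg.planted_enrichment_fold, 1.0)
            w = w / w.sum()
            idx = rng.choice(n_univ, size=size, replace=False, p=w)
            planted_name = name
        else:
            idx = rng.choice(n_univ, size=size, replace=False)
        categories[name] = [universe[i] for i in sorted(idx)]
    collection = GeneSetCollection(categories, reference=universe)
    return collection, list(query), planted_name


def _latent_rate_split(rate: float, log_odds: float) -> tuple[float, float]:
    """Solve the latent-factor rate split reproducing a pairwise log odds.

    With a fair latent Bernoulli factor and conditional alteration rates
    ``rate + d`` / ``rate - d``, two aligned genes have odds ratio
    ``P11 * P00 / (P10 * P01)``; ``d`` is solved so that its log equals
    ``|log_odds|`` (natural log).
    """
    target = abs(log_odds)
    if target == 0.0:
        return rate, rate

    def f(d: float) -> float:
        p11 = 0.5 * ((rate + d) ** 2 + (rate - d) ** 2)
        p10 = rate - p11
        p00 = 1.0 - 2.0 * rate + p11
        return math.log(p11 * p00 / (p10 * p10)) - target

    d_max = min(rate, 1.0 - rate) - 1e-9
    if f(d_max) < 0:
        raise ConfigError(f"planted_log_odds {log_odds} unattainable at "
                          f"alteration rate {rate}")
    d = brentq(f, 1e-12, d_max)
    return rate + d, rate - d


def gen_cohort(cfg: GeneratorConfig, query: Sequence[str]
               ) -> tuple[AlterationMatrix, list[SurvivalRecord]]:
    """Synthetic tumor cohort: alteration matrix plus overall survival.

    Per-gene alterations are Bernoulli at ``per_gene_alteration_rate``;
    a nonzero ``planted_log_odds`` couples genes through a fair latent
    per-sample factor (positive: all genes aligned, co-occurrence; negative:
    alternating genes anti-aligned, exclusivity between neighbors).
    Survival is exponential with hazard ``baseline_hazard`` multiplied by
    ``hazard_ratio`` for samples altered in >= 1 query gene; censoring is an
    independent exponential calibrated so that a fraction
    ``censoring_rate`` of baseline-hazard samples is censored.
    """
    rng = cfg.rng("cohort")
    genes = list(query)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    rate = cfg.per_gene_alteration_rate
    p_hi, p_lo = _latent_rate_split(rate, cfg.planted_log_odds)

    events: dict[tuple[str, str], frozenset[str]] = {}
    type_probs = np.array([0.2, 0.15, 0.5, 0.15])
    for s in samples:
        z = bool(rng.uniform() < 0.5)
        for j, g in enumerate(genes):
            if cfg.planted_log_odds == 0.0:
                p = rate
            elif cfg.planted_log_odds > 0:
                # co-occurrence: every gene elevated on the same latent state
                p = p_hi if z else p_lo
            else:
                # exclusivity: alternating genes anti-aligned on the factor
                follows = z if j % 2 == 0 else (not z)
                p = p_hi if follows else p_lo
            if rng.uniform() < p:
                t = str(rng.choice(ALTERATION_TYPES, p=type_probs))
                events[(s, g)] = frozenset([t])
    mat = AlterationMatrix(samples=samples, genes=genes, events=events)

    altered = set(mat.altered_samples(genes))
    lam0 = cfg.baseline_hazard
    lam_c = lam0 * cfg.censoring_rate / (1.0 - cfg.censoring_rate) \
        if cfg.censoring_rate > 0 else 0.0
    records: list[SurvivalRecord] = []
    for s in samples:
        lam = lam0 * (cfg.hazard_ratio if s in altered else 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / lam_c) if lam_c > 0 else math.inf
        records.append(SurvivalRecord(
            sample=s, time=float(min(t_event, t_cens)),
            event=int(t_event <= t_cens)))
    return mat, records


def write_fixtures(cfg: GeneratorConfig, out_dir: str | Path) -> dict:
    """Emit every pipeline input file plus a ground-truth JSON.

    Runs the screening/build stages internally so that the interaction
    graph, gene sets and cohort are generated over the gene symbols the
    pipeline will actually reach.  Returns the ground truth (also written
    to ``truth.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng("fixtures")

    compounds, labels = gen_compound_library(cfg)
    preds = gen_target_map(cfg, compounds)
    all_targets = sorted({p.target for p in preds})
    n_disease = max(1, int(round(cfg.disease_target_fraction * len(all_targets))))
    disease_idx = rng.choice(len(all_targets), size=n_disease, replace=False)
    disease = [all_targets[i] for i in sorted(disease_idx)]

    criteria = ScreenCriteria(cfg.screen_ob_min, cfg.screen_dl_min)
    retained, _ = screen_compounds(compounds, criteria)
    kept_preds = filter_predictions(preds, 0.7)
    ct_net = build_compound_target_network(retained, kept_preds)
    mapped, cancer_targets = map_to_disease_targets(ct_net, disease)

    # keep the configured graph density when the realized target count
    # differs from ppi_nodes (edge count scales with the pair count)
    n_t = len(cancer_targets)
    max_edges = n_t * (n_t - 1) // 2
    cfg_density = cfg.ppi_edges / (cfg.ppi_nodes * (cfg.ppi_nodes - 1) / 2)
    ppi_edges = min(max_edges, max(n_t - 1, round(cfg_density * max_edges)))
    if ppi_edges != cfg.ppi_edges:
        logger.info("write_fixtures: using %d ppi edges for %d targets",
                    ppi_edges, n_t)
    ppi = gen_ppi(cfg, nodes=cancer_targets, n_edges=ppi_edges)

    collection, query, planted = gen_genesets(cfg, query=cancer_targets)
    cohort_genes = cancer_targets[:cfg.n_query_genes]
    mat, records = gen_cohort(cfg, cohort_genes)

    write_compound_table(compounds, out / "compounds.tsv")
    pd_rows = [(p.compound, p.target, p.score) for p in preds]
    pd.DataFrame(pd_rows, columns=["compound", "target", "score"]).to_csv(
        out / "predictions.tsv", sep="\t", index=False)
    write_gene_list(disease, out / "disease_targets.txt")
    write_network(ppi, out / "ppi.sif", dialect="sif")
    write_gmt(collection, out / "pathways.gmt")
    write_gene_list(collection.reference, out / "reference.txt")
    write_alteration_table(mat, out / "alterations.tsv")
    write_survival_table(records, out / "survival.tsv")

    truth = {
        "seed": cfg.seed,
        "n_compounds": len(compounds),
        "n_pass_screen": int(sum(labels.values())),
        "n_predictions": len(preds),
        "n_kept_predictions": len(kept_preds),
        "n_disease_targets": len(disease),
        "n_cancer_targets": len(cancer_targets),
        "ppi_nodes": ppi.number_of_nodes(),
        "ppi_edges": ppi.number_of_edges(),
        "planted_category": planted,
        "cohort_genes": cohort_genes,
        "n_altered_samples": len(mat.altered_samples(cohort_genes)),
        "hazard_ratio": cfg.hazard_ratio,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
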