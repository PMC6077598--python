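"""Determinism, calibration and parameter recovery of the input generators."""

import dataclasses
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from hjdnet.compound_screen import ScreenCriteria, screen_compounds
from hjdnet.errors import ConfigError
from hjdnet.genomics import mutual_exclusivity
from hjdnet.synthetic_data import (
    GeneratorConfig,
    gen_cohort,
    gen_compound_library,
    gen_genesets,
    gen_ppi,
    gen_target_map,
    write_fixtures,
)


class TestConfig:
    def test_invalid_edge_count_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(ppi_nodes=5, ppi_edges=11)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(censoring_rate=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=3, n_samples=50)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert GeneratorConfig.from_yaml(p) == cfg


class TestCompoundLibrary:
    def test_deterministic_across_runs(self):
        cfg = GeneratorConfig(seed=1)
        c1, l1 = gen_compound_library(cfg)
        c2, l2 = gen_compound_library(cfg)
        assert c1 == c2 and l1 == l2

    def test_labels_agree_with_screen(self):
        cfg = GeneratorConfig(seed=2)
        comps, labels = gen_compound_library(cfg)
        kept, _ = screen_compounds(
            comps, ScreenCriteria(cfg.screen_ob_min, cfg.screen_dl_min))
        assert {c.key for c in kept} == {k for k, v in labels.items() if v}

    def test_degenerate_dl_all_pass_dl_criterion(self):
        # Beta(a, a) with huge a concentrates at 0.5 > 0.18
        cfg = GeneratorConfig(seed=3, dl_alpha=5e5, dl_beta=5e5)
        comps, _ = gen_compound_library(cfg)
        assert all(abs(c.dl - 0.5) < 0.01 for c in comps)
        kept, _ = screen_compounds(comps, ScreenCriteria(0.0, 0.18))
        assert len(kept) == len(comps)


class TestTargetMap:
    def test_deterministic(self):
        cfg = GeneratorConfig(seed=5)
        comps, _ = gen_compound_library(cfg)
        assert gen_target_map(cfg, comps) == gen_target_map(cfg, comps)

    def test_score_filter_retention_near_30_percent(self):
        cfg = GeneratorConfig(seed=6, mean_targets_per_compound=12.0)
        comps, _ = gen_compound_library(cfg)
        preds = gen_target_map(cfg, comps)
        frac = np.mean([p.score > 0.7 for p in preds])
        n = len(preds)
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_degree_tail_exponent_recovered(self):
        """Log degree vs log rank slope recovers the configured power law."""
        cfg = GeneratorConfig(seed=3, mean_targets_per_compound=12.0)
        comps, _ = gen_compound_library(cfg)
        preds = gen_target_map(cfg, comps)
        assert len(preds) > 4500
        deg = np.array(sorted(Counter(p.target for p in preds).values(),
                              reverse=True), float)
        r = np.arange(1, 51)
        slope = np.polyfit(np.log(r), np.log(deg[:50]), 1)[0]
        gamma_hat = 1.0 + 1.0 / (-slope)
        assert abs(gamma_hat - cfg.target_degree_exponent) < 0.3


class TestPpi:
    def test_exact_counts_across_seeds(self):
        for seed in range(5):
            g = gen_ppi(GeneratorConfig(seed=seed))
            assert g.number_of_nodes() == 98
            assert g.number_of_edges() == 1027
            assert nx.is_connected(g)
            assert nx.number_of_selfloops(g) == 0

    def test_minimal_triangle(self):
        g = gen_ppi(GeneratorConfig(seed=0, ppi_nodes=3, ppi_edges=3))
        assert nx.is_isomorphic(g, nx.complete_graph(3))

    def test_too_few_edges_rejected(self):
        with pytest.raises(ConfigError):
            gen_ppi(GeneratorConfig(seed=0), nodes=list("abcdefgh"), n_edges=3)


class TestGenesets:
    def test_deterministic(self):
        cfg = GeneratorConfig(seed=8, n_categories=20)
        c1, q1, p1 = gen_genesets(cfg)
        c2, q2, p2 = gen_genesets(cfg)
        assert q1 == q2 and p1 == p2 and c1.categories == c2.categories

    def test_supplied_query_enters_universe(self):
        cfg = GeneratorConfig(seed=9, n_categories=10)
        query = [f"T{i:04d}" for i in range(40)]
        coll, q, planted = gen_genesets(cfg, query=query)
        assert q == query
        assert set(query) <= set(coll.reference)
        assert len(coll.reference) == cfg.universe_size
        assert planted in coll.categories


class TestCohort:
    def test_deterministic(self):
        cfg = GeneratorConfig(seed=10)
        genes = [f"G{i}" for i in range(7)]
        m1, r1 = gen_cohort(cfg, genes)
        m2, r2 = gen_cohort(cfg, genes)
        assert m1.events == m2.events and r1 == r2

    def test_alteration_rate_recovered_at_large_n(self):
        cfg = GeneratorConfig(seed=11, n_samples=2000)
        genes = [f"G{i}" for i in range(7)]
        mat, _ = gen_cohort(cfg, genes)
        rate = len(mat.events) / (2000 * 7)
        se = np.sqrt(0.15 * 0.85 / (2000 * 7))
        assert abs(rate - cfg.per_gene_alteration_rate) < 4 * se

    def test_hazard_ratio_recovered_at_large_n(self):
        """Exponential-rate MLE per arm recovers the configured ratio."""
        cfg = GeneratorConfig(seed=12, n_samples=2000, hazard_ratio=3.0)
        genes = [f"G{i}" for i in range(7)]
        mat, recs = gen_cohort(cfg, genes)
        altered = set(mat.altered_samples(genes))
        def rate(group):
            events = sum(r.event for r in group)
            return events / sum(r.time for r in group)
        hr_hat = rate([r for r in recs if r.sample in altered]) \
            / rate([r for r in recs if r.sample not in altered])
        assert 0.75 * 3.0 < hr_hat < 1.35 * 3.0

    def test_null_mutex_calibration(self):
        """No planted dependence: Fisher p well-calibrated (conservative)."""
        ps = []
        for seed in range(40):
            cfg = GeneratorConfig(seed=seed, planted_log_odds=0.0)
            mat, _ = gen_cohort(cfg, ["GA", "GB"])
            ps.append(mutual_exclusivity(mat, "GA", "GB").p)
        assert np.mean(np.array(ps) < 0.05) <= 0.075
        assert np.median(ps) > 0.3

    def test_planted_cooccurrence_detected(self):
        # the fair-latent-factor coupling caps the attainable odds ratio at
        # low alteration rates, so plant at rate 0.3
        cfg = GeneratorConfig(seed=13, n_samples=1500, planted_log_odds=1.0,
                              per_gene_alteration_rate=0.3)
        mat, _ = gen_cohort(cfg, ["GA", "GB"])
        res = mutual_exclusivity(mat, "GA", "GB")
        assert res.direction == "co-occurrence"

    def test_planted_exclusivity_detected(self):
        cfg = GeneratorConfig(seed=14, n_samples=1500, planted_log_odds=-1.0,
                              per_gene_alteration_rate=0.3)
        mat, _ = gen_cohort(cfg, ["GA", "GB"])
        res = mutual_exclusivity(mat, "GA", "GB")
        assert res.direction == "exclusivity"

    def test_unattainable_coupling_rejected(self):
        cfg = GeneratorConfig(seed=15, planted_log_odds=2.0)  # rate 0.15
        with pytest.raises(ConfigError):
            gen_cohort(cfg, ["GA", "GB"])


class TestFixtures:
    def test_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = GeneratorConfig(seed=1, n_categories=20)
        t1 = write_fixtures(cfg, tmp_path / "a")
        t2 = write_fixtures(cfg, tmp_path / "b")
        assert t1 == t2
        for name in ("compounds.tsv", "predictions.tsv", "ppi.sif",
                     "pathways.gmt", "alterations.tsv", "survival.tsv"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_substreams_are_independent(self):
        """Changing the cohort size must not perturb the compound stream."""
        base = GeneratorConfig(seed=2)
        other = dataclasses.replace(base, n_samples=37)
        assert gen_compound_library(base) == gen_compound_library(other)
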