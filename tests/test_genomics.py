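"""Alteration summaries, OncoPrint ordering, Fisher mutual exclusivity,
Kaplan-Meier estimation and the log-rank test."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from hjdnet.errors import EmptyInputError
from hjdnet.genomics import (
    AlterationMatrix,
    SurvivalRecord,
    alteration_summary,
    km_curve,
    logrank_test,
    mutual_exclusivity,
    oncoprint_order,
    read_alteration_table,
    read_survival_table,
    survival_by_alteration,
    write_alteration_table,
    write_survival_table,
)
from tests.conftest import exponential_arm


def fisher_two_sided_oracle(table) -> float:
    """Exhaustive enumeration over the hypergeometric family with fixed
    margins: sum of probabilities of tables no more likely than observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def logrank_oracle(group_a, group_b):
    """Hand tabulation of the log-rank O-E/V sums at each event time."""
    times = sorted({r.time for r in group_a + group_b if r.event})
    u = v = 0.0
    for t in times:
        na = sum(1 for r in group_a if r.time >= t)
        nb = sum(1 for r in group_b if r.time >= t)
        n = na + nb
        d = sum(1 for r in group_a + group_b if r.event and r.time == t)
        oa = sum(1 for r in group_a if r.event and r.time == t)
        u += oa - d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    stat = u * u / v
    return stat, chi2.sf(stat, 1)


class TestAlterationSummary:
    def test_worked_example(self, small_matrix):
        freq, frac, altered = alteration_summary(small_matrix, ["A", "B", "C"])
        assert freq == {"A": 0.5, "B": 0.25, "C": 0.0}
        assert frac == 0.5
        assert altered == ["s1", "s2"]

    def test_empty_events(self):
        mat = AlterationMatrix(samples=["s1", "s2"], genes=["G"], events={})
        freq, frac, altered = alteration_summary(mat, ["G"])
        assert freq == {"G": 0.0} and frac == 0.0 and altered == []

    def test_saturated(self):
        mat = AlterationMatrix(
            samples=["s1", "s2"], genes=["G", "H"],
            events={(s, g): frozenset({"missense_mutation"})
                    for s in ("s1", "s2") for g in ("G", "H")})
        freq, frac, _ = alteration_summary(mat, ["G", "H"])
        assert set(freq.values()) == {1.0} and frac == 1.0

    def test_unknown_gene_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            alteration_summary(small_matrix, ["NOPE"])

    def test_invariant_to_reordering(self, small_matrix):
        shuffled = AlterationMatrix(
            samples=list(reversed(small_matrix.samples)),
            genes=list(reversed(small_matrix.genes)),
            events=dict(small_matrix.events))
        f1, a1, _ = alteration_summary(small_matrix, ["A", "B", "C"])
        f2, a2, _ = alteration_summary(shuffled, ["A", "B", "C"])
        assert f1 == f2 and a1 == a2


class TestOncoprintOrder:
    def test_worked_memo_sort(self, small_matrix):
        genes, samples = oncoprint_order(small_matrix, ["A", "B", "C"])
        assert genes == ["A", "B", "C"]
        assert samples == ["s2", "s1", "s3", "s4"]

    def test_single_gene_altered_first(self, small_matrix):
        _, samples = oncoprint_order(small_matrix, ["B"])
        assert samples[0] == "s2"

    def test_deterministic_under_input_permutation(self, small_matrix):
        permuted = AlterationMatrix(
            samples=["s4", "s2", "s1", "s3"], genes=["A", "B", "C"],
            events=dict(small_matrix.events))
        assert oncoprint_order(permuted, ["A", "B", "C"]) \
            == oncoprint_order(small_matrix, ["A", "B", "C"])


def _pair_matrix(a_cells):
    """Matrix with prescribed 2x2 counts (both, a_only, b_only, neither)."""
    both, a_only, b_only, neither = a_cells
    samples, events = [], {}
    i = 0
    for count, (ia, ib) in [(both, (1, 1)), (a_only, (1, 0)),
                            (b_only, (0, 1)), (neither, (0, 0))]:
        for _ in range(count):
            s = f"s{i}"; i += 1
            samples.append(s)
            if ia:
                events[(s, "GA")] = frozenset({"missense_mutation"})
            if ib:
                events[(s, "GB")] = frozenset({"amplification"})
    return AlterationMatrix(samples=samples, genes=["GA", "GB"], events=events)


class TestMutualExclusivity:
    def test_balanced_table(self):
        res = mutual_exclusivity(_pair_matrix((1, 1, 1, 1)), "GA", "GB")
        assert res.p == pytest.approx(1.0)
        assert res.direction == "none"

    def test_perfect_exclusivity_small(self):
        # [[0,3],[3,0]] as (both, a_only, b_only, neither)=(0,3,3,0): p = 2/20
        res = mutual_exclusivity(_pair_matrix((0, 3, 3, 0)), "GA", "GB")
        assert res.p == pytest.approx(0.1)
        assert res.log2_odds < 0

    def test_gene_against_itself_cooccurs(self):
        mat = _pair_matrix((4, 0, 0, 8))
        res = mutual_exclusivity(mat, "GA", "GA")
        assert res.table[0][0] == 4 and res.log2_odds > 0
        assert res.direction == "co-occurrence"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cells = tuple(int(x) for x in rng.integers(0, 11, size=4))
        if sum(cells) == 0:
            cells = (1, 0, 0, 1)
        res = mutual_exclusivity(_pair_matrix(cells), "GA", "GB")
        assert res.p == pytest.approx(fisher_two_sided_oracle(res.table),
                                      rel=1e-6)
        assert sum(sum(row) for row in res.table) == sum(cells)


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        recs = [SurvivalRecord(f"s{i}", float(i + 1), 0) for i in range(5)]
        km = km_curve(recs)
        assert all(s == 1.0 for s in km.survival)

    def test_two_deaths_product_limit(self):
        km = km_curve([SurvivalRecord("a", 1.0, 1), SurvivalRecord("b", 2.0, 1)])
        assert km(1.0) == pytest.approx(0.5)
        assert km(2.0) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        km = km_curve([SurvivalRecord("a", 1.0, 0), SurvivalRecord("b", 2.0, 1)])
        assert km(1.5) == pytest.approx(1.0)
        assert km(2.0) == pytest.approx(0.0)  # 1 - 1/1 with risk set 1

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", -1.0, 1)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            km_curve([])

    @pytest.mark.parametrize("seed", range(5))
    def test_step_function_bounded_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        recs = exponential_arm(rng, 40, 0.1, 0.05, "s")
        km = km_curve(recs)
        assert km.survival[0] == 1.0
        assert all(0.0 <= s <= 1.0 for s in km.survival)
        assert all(a >= b for a, b in zip(km.survival, km.survival[1:]))


class TestLogrank:
    def test_identical_groups(self):
        recs = [SurvivalRecord(f"s{i}", float(i + 1), 1) for i in range(4)]
        res = logrank_test(recs, list(recs))
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_toy_data_against_hand_tabulation(self):
        a = [SurvivalRecord("a1", 1.0, 1), SurvivalRecord("a2", 2.0, 1)]
        b = [SurvivalRecord("b1", 3.0, 1), SurvivalRecord("b2", 4.0, 1)]
        stat, p = logrank_oracle(a, b)
        res = logrank_test(a, b)
        assert res.chi_square == pytest.approx(stat, rel=1e-6)
        assert res.p == pytest.approx(p, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_data_against_hand_tabulation(self, seed):
        rng = np.random.default_rng(seed)
        a = exponential_arm(rng, 25, 0.1, 0.03, "a")
        b = exponential_arm(rng, 20, 0.2, 0.03, "b")
        stat, p = logrank_oracle(a, b)
        res = logrank_test(a, b)
        assert res.chi_square == pytest.approx(stat, rel=1e-6)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_symmetric_under_label_exchange(self):
        rng = np.random.default_rng(9)
        a = exponential_arm(rng, 30, 0.1, 0.03, "a")
        b = exponential_arm(rng, 30, 0.3, 0.03, "b")
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p == pytest.approx(r2.p)

    def test_no_events_warns_p_one(self, caplog):
        a = [SurvivalRecord("a", 1.0, 0)]
        b = [SurvivalRecord("b", 2.0, 0)]
        with caplog.at_level("WARNING"):
            res = logrank_test(a, b)
        assert res.p == 1.0
        assert any("no events" in r.message for r in caplog.records)


class TestSurvivalByAlteration:
    def test_all_samples_altered_single_curve(self, caplog):
        mat = _pair_matrix((2, 1, 1, 0))
        recs = [SurvivalRecord(s, float(i + 1), 1)
                for i, s in enumerate(mat.samples)]
        with caplog.at_level("WARNING"):
            comp = survival_by_alteration(mat, ["GA", "GB"], recs)
        assert comp.km_unaltered is None and comp.logrank is None
        assert any("partition" in r.message for r in caplog.records)

    def test_planted_hazard_separates_medians(self):
        from hjdnet.synthetic_data import GeneratorConfig, gen_cohort
        cfg = GeneratorConfig(seed=15, n_samples=400, hazard_ratio=4.0)
        mat, recs = gen_cohort(cfg, [f"G{i}" for i in range(5)])
        comp = survival_by_alteration(mat, mat.genes, recs)
        assert comp.km_altered.median < comp.km_unaltered.median
        assert comp.logrank.p < 0.01

    def test_missing_survival_excluded_with_log(self, caplog, small_matrix):
        recs = [SurvivalRecord("s1", 5.0, 1), SurvivalRecord("s2", 3.0, 0)]
        with caplog.at_level("INFO"):
            comp = survival_by_alteration(small_matrix, ["A"], recs)
        assert comp.n_altered + comp.n_unaltered == 2
        assert any("lack survival" in r.message for r in caplog.records)


def test_alteration_and_survival_round_trip(tmp_path, small_matrix):
    ap = tmp_path / "alt.tsv"
    write_alteration_table(small_matrix, ap)
    back = read_alteration_table(ap)
    assert set(back.samples) == set(small_matrix.samples)
    assert back.events == small_matrix.events

    recs = [SurvivalRecord(s, float(i + 1), i % 2)
            for i, s in enumerate(small_matrix.samples)]
    sp = tmp_path / "surv.tsv"
    write_survival_table(recs, sp)
    assert read_survival_table(sp) == recs
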