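"""Cancer-genomics mining of alteration matrices and survival data.

Implements the cBioPortal-style summaries used to interrogate a gene set in
a tumor cohort: per-gene and per-cohort alteration frequencies, OncoPrint
row/column ordering (memo-sort), pairwise mutual-exclusivity /
co-occurrence testing by Fisher's exact test with a log2 odds ratio, and
Kaplan-Meier + log-rank comparison of overall survival between altered and
unaltered cases.

Alteration types follow the OncoPrint vocabulary: ``amplification``,
``deep_deletion``, ``missense_mutation``, ``truncating_mutation``.  A sample
counts as *altered* when it has at least one event of any type in any query
gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import fisher_exact

from .errors import DegenerateGraphError, EmptyInputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ALTERATION_TYPES",
    "AlterationMatrix",
    "SurvivalRecord",
    "MutexResult",
    "KMCurve",
    "LogrankResult",
    "SurvivalComparison",
    "alteration_summary",
    "oncoprint_order",
    "mutual_exclusivity",
    "km_curve",
    "logrank_test",
    "survival_by_alteration",
    "read_alteration_table",
    "write_alteration_table",
    "read_survival_table",
]

ALTERATION_TYPES = (
    "amplification", "deep_deletion", "missense_mutation", "truncating_mutation",
)

# one-glyph-per-cell display precedence
_DISPLAY_PRECEDENCE = (
    "amplification", "deep_deletion", "truncating_mutation", "missense_mutation",
)


@dataclass
class AlterationMatrix:
    """Sample-by-gene alteration events (sparse dict-of-sets storage)."""

    samples: list[str]
    genes: list[str]
    events: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        sset, gset = set(self.samples), set(self.genes)
        for (s, g), types in self.events.items():
            if s not in sset:
                raise ValueError(f"event references unknown sample {s!r}")
            if g not in gset:
                raise ValueError(f"event references unknown gene {g!r}")
            if not types:
                raise ValueError(f"empty event set for ({s}, {g})")
            bad = set(types) - set(ALTERATION_TYPES)
            if bad:
                raise ValueError(f"unknown alteration type(s) {sorted(bad)}")

    def is_altered(self, sample: str, gene: str) -> bool:
        return (sample, gene) in self.events

    def altered_samples(self, genes: Sequence[str]) -> list[str]:
        """Samples with >= 1 event in any of ``genes``, in sample order."""
        gs = list(genes)
        return [s for s in self.samples if any(self.is_altered(s, g) for g in gs)]


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-sample overall survival: time in months, event=1 means death."""

    sample: str
    time: float
    event: int

    def __post_init__(self):
        if self.time < 0 or not np.isfinite(self.time):
            raise ValueError(f"{self.sample}: survival time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample}: event indicator must be 0 or 1")


@dataclass(frozen=True)
class MutexResult:
    """Pairwise co-occurrence / mutual-exclusivity test for two genes.

    ``table`` is ((both, a_only), (b_only, neither)); ``log2_odds`` uses a
    Haldane 0.5 correction when any cell is zero; ``direction`` is called
    only at p < 0.05.
    """

    gene_a: str
    gene_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    log2_odds: float
    p: float
    direction: str  # "co-occurrence" | "exclusivity" | "none"


def _check_query(mat: AlterationMatrix, query: Sequence[str]) -> list[str]:
    unknown = [g for g in query if g not in set(mat.genes)]
    if unknown:
        raise KeyError(f"gene(s) not in the alteration matrix: {unknown}")
    return list(query)


def alteration_summary(
    mat: AlterationMatrix, query: Sequence[str]
) -> tuple[dict[str, float], float, list[str]]:
    """Per-gene alteration frequencies and the fraction of altered samples.

    Returns ``(per_gene_freq, altered_fraction, altered_samples)`` where
    ``altered_fraction`` is the share of samples carrying >= 1 event across
    the query genes.
    """
    genes = _check_query(mat, query)
    total = len(mat.samples)
    if total == 0:
        raise EmptyInputError("alteration matrix has no samples")
    per_gene = {
        g: sum(mat.is_altered(s, g) for s in mat.samples) / total for g in genes
    }
    altered = mat.altered_samples(genes)
    return per_gene, len(altered) / total, altered


def oncoprint_order(
    mat: AlterationMatrix, query: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Deterministic OncoPrint gene and sample ordering (memo-sort).

    Genes sort by descending alteration frequency (ties keep query order);
    samples sort by their altered/unaltered profile over the ordered genes,
    read as a binary string, descending (ties by ascending sample ID).
    """
    genes = _check_query(mat, query)
    per_gene, _, _ = alteration_summary(mat, genes)
    gene_order = sorted(genes, key=lambda g: (-per_gene[g], genes.index(g)))
    def profile(s: str):
        return tuple(-int(mat.is_altered(s, g)) for g in gene_order)
    sample_order = sorted(mat.samples, key=lambda s: (profile(s), s))
    return gene_order, sample_order


def mutual_exclusivity(mat: AlterationMatrix, gene_a: str, gene_b: str
                       ) -> MutexResult:
    """Two-sided Fisher exact test on the 2x2 altered/unaltered table.

    Follows the cBioPortal convention: co-occurrence when the odds ratio is
    above 1, exclusivity when below, called only at p < 0.05.
    """
    _check_query(mat, [gene_a, gene_b])
    if not mat.samples:
        raise DegenerateGraphError("alteration matrix has no samples")
    both = a_only = b_only = neither = 0
    for s in mat.samples:
        ia, ib = mat.is_altered(s, gene_a), mat.is_altered(s, gene_b)
        if ia and ib:
            both += 1
        elif ia:
            a_only += 1
        elif ib:
            b_only += 1
        else:
            neither += 1
    table = ((both, a_only), (b_only, neither))
    _, p = fisher_exact([[both, a_only], [b_only, neither]],
                        alternative="two-sided")
    cells = (both, a_only, b_only, neither)
    if 0 in cells:
        both_, a_, b_, n_ = (c + 0.5 for c in cells)
    else:
        both_, a_, b_, n_ = cells
    log2_odds = math.log2((both_ * n_) / (a_ * b_))
    if p < 0.05:
        direction = "co-occurrence" if log2_odds > 0 else "exclusivity"
    else:
        direction = "none"
    return MutexResult(gene_a=gene_a, gene_b=gene_b, table=table,
                       log2_odds=log2_odds, p=float(p), direction=direction)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous step function."""

    times: tuple[float, ...]      # ascending, starting at 0
    survival: tuple[float, ...]   # S(t) on [times[i], times[i+1])
    n: int
    n_events: int

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[max(idx, 0)]

    @property
    def median(self) -> float:
        """Smallest time with S(t) <= 0.5 (inf if never reached)."""
        for t, s in zip(self.times, self.survival):
            if s <= 0.5:
                return t
        return math.inf


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate over distinct event times.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``; censored samples leave the
    risk set without contributing a factor.
    """
    if not records:
        raise EmptyInputError("km_curve needs at least one record")
    durations = [r.time for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = tuple(float(t) for t in sf.index)
    surv = tuple(float(v) for v in sf.iloc[:, 0])
    if not times or times[0] != 0.0:
        times = (0.0,) + times
        surv = (1.0,) + surv
    return KMCurve(times=times, survival=surv, n=len(records),
                   n_events=int(sum(events)))


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    n_a: int
    n_b: int


def logrank_test(group_a: Sequence[SurvivalRecord],
                 group_b: Sequence[SurvivalRecord]) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df, two-sided p).

    At each distinct event time the observed deaths in group A are compared
    with their hypergeometric expectation given the pooled risk set.  If
    neither group has any events the test is undefined; the function warns
    and returns p = 1.
    """
    if not group_a or not group_b:
        raise EmptyInputError("both groups must be nonempty")
    ev_a = sum(r.event for r in group_a)
    ev_b = sum(r.event for r in group_b)
    if ev_a == 0 and ev_b == 0:
        logger.warning("logrank_test: no events in either group; p = 1")
        return LogrankResult(chi_square=0.0, p=1.0, n_a=len(group_a),
                             n_b=len(group_b))
    res = _ll_logrank(
        [r.time for r in group_a], [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return LogrankResult(chi_square=float(res.test_statistic),
                         p=float(res.p_value), n_a=len(group_a),
                         n_b=len(group_b))


@dataclass(frozen=True)
class SurvivalComparison:
    km_altered: KMCurve | None
    km_unaltered: KMCurve | None
    logrank: LogrankResult | None
    n_altered: int
    n_unaltered: int


def survival_by_alteration(mat: AlterationMatrix, query: Sequence[str],
                           records: Sequence[SurvivalRecord]
                           ) -> SurvivalComparison:
    """KM + log-rank comparison of altered vs. unaltered cases.

    Samples lacking survival data are excluded with a logged count; if one
    partition is empty a single curve is returned with a warning and no
    log-rank result.
    """
    genes = _check_query(mat, query)
    by_sample = {r.sample: r for r in records}
    unknown = [s for s in by_sample if s not in set(mat.samples)]
    if unknown:
        raise KeyError(f"survival record(s) for unknown sample(s): {unknown[:5]}")
    missing = [s for s in mat.samples if s not in by_sample]
    if missing:
        logger.info("survival_by_alteration: %d sample(s) lack survival data "
                    "and are excluded", len(missing))
    altered_set = set(mat.altered_samples(genes))
    rec_a = [by_sample[s] for s in mat.samples
             if s in by_sample and s in altered_set]
    rec_u = [by_sample[s] for s in mat.samples
             if s in by_sample and s not in altered_set]
    km_a = km_curve(rec_a) if rec_a else None
    km_u = km_curve(rec_u) if rec_u else None
    if not rec_a or not rec_u:
        logger.warning("survival_by_alteration: one partition is empty "
                       "(altered=%d, unaltered=%d); log-rank skipped",
                       len(rec_a), len(rec_u))
        lr = None
    else:
        lr = logrank_test(rec_a, rec_u)
    return SurvivalComparison(km_altered=km_a, km_unaltered=km_u, logrank=lr,
                              n_altered=len(rec_a), n_unaltered=len(rec_u))


def read_alteration_table(path: str | Path) -> AlterationMatrix:
    """Read a MAF-like TSV with columns sample, gene, alteration_type.

    The format lists events, so a row with ``alteration_type`` equal to
    ``none`` registers its sample (and gene) in the cohort without recording
    an event — this is how event-free samples enter the matrix.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample", "gene", "alteration_type"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}", line=1)
    samples: list[str] = []
    genes: list[str] = []
    events: dict[tuple[str, str], set[str]] = {}
    for idx, row in df.iterrows():
        s, g, t = row["sample"].strip(), row["gene"].strip().upper(), \
            row["alteration_type"].strip()
        if t != "none" and t not in ALTERATION_TYPES:
            raise ParseError(f"unknown alteration type {t!r}", line=idx + 2)
        if s not in samples:
            samples.append(s)
        if g not in genes:
            genes.append(g)
        if t != "none":
            events.setdefault((s, g), set()).add(t)
    return AlterationMatrix(
        samples=samples, genes=genes,
        events={k: frozenset(v) for k, v in events.items()},
    )


def write_alteration_table(mat: AlterationMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_alteration_table`; event-free samples are
    registered with a single ``none`` row."""
    rows = []
    for s in mat.samples:
        wrote_any = False
        for g in mat.genes:
            types = mat.events.get((s, g))
            if types:
                wrote_any = True
                for t in sorted(types):
                    rows.append({"sample": s, "gene": g, "alteration_type": t})
        if not wrote_any:
            rows.append({"sample": s, "gene": mat.genes[0] if mat.genes else "",
                         "alteration_type": "none"})
    pd.DataFrame(rows, columns=["sample", "gene", "alteration_type"]).to_csv(
        path, sep="\t", index=False)


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival TSV with columns sample, os_months, os_event."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample", "os_months", "os_event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}", line=1)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(SurvivalRecord(
                sample=row["sample"].strip(),
                time=float(row["os_months"]),
                event=int(row["os_event"]),
            ))
        except ValueError as exc:
            raise ParseError(str(exc), line=idx + 2) from None
    return records


def write_survival_table(records: Sequence[SurvivalRecord],
                         path: str | Path) -> None:
    pd.DataFrame([{"sample": r.sample, "os_months": r.time, "os_event": r.event}
                  for r in records]).to_csv(path, sep="\t", index=False)
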