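# Methods

This note records the statistical models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the known limitations.

## ADME screening

Oral bioavailability (OB, in percent) and drug-likeness (DL, unitless in
[0, 1]) are consumed as inputs; the package does not predict them.  DL may
alternatively be derived from a molecular-descriptor vector via the
Tanimoto index against a supplied reference (average-drug) vector,
`f(A,B) = A·B / (‖A‖² + ‖B‖² − A·B)`.  When both a supplied and a
descriptor-derived DL exist and disagree by more than 1e-6, the supplied
value wins and a warning is logged — curated tables are treated as more
authoritative than recomputation from possibly different descriptor sets.

Both screening thresholds (OB ≥ 30 %, DL ≥ 0.18) are **inclusive**; the
equivalent exclusion phrasing ("remove DL < 0.18") implies the same
boundary behavior.  Compound identity is the (name, herb) pair after
trimming and case-folding — the same sterol can legitimately appear under
several herbs and is kept as distinct records, but a literal duplicate
within one herb is a data error and is rejected at parse time with the
offending line number.

## Network assembly

The prediction-score filter is **strict** (`score > 0.7`), unlike the
inclusive OB/DL thresholds: the two conventions are deliberately different
because that is how each cutoff is conventionally stated.  Gene symbols are
canonicalized to upper case for all matching.  Graphs are simple undirected
`networkx.Graph` objects; ingestion drops self-loops and duplicate edges
and logs their counts (the topology report then legitimately shows zeros
for both).  Predictions referencing compounds absent from the screened
library are skipped with a warning rather than failing, so a partial
library rerun degrades gracefully.

Disease mapping keeps target nodes present in the disease list and then
drops compounds left without edges; the operation is idempotent.
Confidence filtering of PPI edges is *not* applied by default — the edge
list is taken as exported.

## Topology conventions

All conventions follow Cytoscape's NetworkAnalyzer, so that the report is
comparable with the widely published parameter suite:

* **closeness** is component-restricted: `reachable / Σ distances` within
  the node's connected component (no Wasserman–Faust rescaling, no
  harmonic closeness);
* **betweenness** is Brandes pair-dependency, normalized by
  `(n−1)(n−2)/2`;
* **shortest paths** counts *ordered* node pairs at finite distance
  (`n(n−1)` for a connected graph), and the characteristic path length is
  the mean over those pairs;
* **clustering coefficient** is the unweighted mean of local coefficients
  with degree-<2 nodes contributing zero *and* counted in the mean;
* **centralization** is the Freeman point form
  `(n/(n−2))(d_max/(n−1) − density)`, identical to the classical sum form
  (property-tested); defined as 0 below 3 nodes;
* **heterogeneity** is the coefficient of variation of degree
  (population variance).

Diameter and radius refer to the largest component when the graph is
disconnected.  The hub rule `degree ≥ 2 × mean degree` is inclusive; on the
bundled degree table the threshold (41.918) is non-integral, so inclusive
versus exclusive cannot change the result there.  All rankings break ties
by ascending node name for reproducibility.

## Over-representation analysis

`rawP = P(X ≥ O)` with `X ~ Hypergeometric(N, C, n)` — the inclusive upper
tail, computed through `scipy.stats.hypergeom.sf` (stable in log space
internally) and property-tested against exhaustive pmf enumeration for all
universes up to N = 25.  `R` is reported at full precision in machine
output and rounded to two decimals for display; `R = 0` when `O = 0`.

The reference universe defaults to the union of all category genes when not
supplied.  The BH adjustment pool `m` is the number of *tested* categories
(those with ≥ 1 reference gene), which may exceed the number of reported
rows — `bh_adjust` therefore accepts `m ≥ len(p)` explicitly, which is why
it is implemented directly (it is cross-checked against statsmodels where
`m = len(p)`).  Results sort by ascending rawP with ties broken by
descending R then name; top-k selection applies a *strict* adjP cutoff.

## Cancer genomics

Mutual exclusivity / co-occurrence uses the two-sided Fisher exact test on
the 2×2 altered/unaltered table (the convention of cBioPortal), with a
Haldane 0.5 correction for the log₂ odds ratio when any cell is zero, and a
direction call only at p < 0.05.  A sample is *altered* when it carries at
least one event of any type in at least one query gene.  For one-glyph
displays, alteration types take precedence amplification > deep deletion >
truncating > missense; the underlying data keep all types.

The Kaplan–Meier estimator and the two-group log-rank test are provided by
`lifelines`; both are verified in the test suite against hand-tabulated
product-limit and O−E/V computations.  The log-rank p-value is the
chi-square(1) upper tail without continuity correction.  Samples missing
survival data are excluded with a logged count; an empty partition yields a
single curve and no test.

The MAF-like alteration TSV lists events, so event-free samples are
registered with an explicit `alteration_type = none` row — otherwise a
cohort's denominator would silently shrink to the altered samples.

## Synthetic-data generators

Each generator draws from its own `SeedSequence([seed, stream])` substream,
so regenerating one input never perturbs another and all outputs are pure
functions of the config.  Defaults describe a study-scale scenario:

| parameter | default | rationale |
|---|---|---|
| compounds per herb | 48 / 143 / 140 / 98 | the four-herb library sizes |
| OB | lognormal, median 20 %, σ = 0.75 | right-skewed positive law; ~1/5 of compounds pass both screens |
| DL | Beta(1.2, 3.5) | bounded on [0, 1], mass below 0.18 |
| targets | 200, Zipf weights, pdf tail exponent 2.5 | heavy-tailed target degrees create downstream hubs |
| scores | Uniform(0, 1) | a 0.7 cutoff retains ~30 % |
| PPI | 98 nodes, 1027 edges | the published interaction-network scale; uniform over connected m-edge graphs via rejection |
| universe / categories | 2 000 genes; 300 categories of 50–400 | KEGG-like annotated universe and category sizes; ~300 tested categories |
| query / planted fold | 98 genes; 5× | planted category's sampling odds for query genes |
| cohort | 100 samples, 7 genes, rate 0.15 | portal-study scale |
| survival | exponential, hazard 0.02 /month; HR 2; 30 % censoring | median ~35 months at baseline |

When fixtures are written end-to-end, the interaction graph is generated
over the targets the pipeline actually reaches, and its edge count is
scaled to preserve the configured graph *density* if the realized target
count differs from `ppi_nodes`.

**Alteration coupling.** A nonzero `planted_log_odds` couples genes through
a fair latent per-sample factor with conditional rates `rate ± d`, `d`
solved numerically (Brent) so two aligned genes have the requested log odds
ratio; negative values anti-align alternating genes.  This mechanism caps
the attainable |log OR| (≈ 1.1 at rate 0.15); an unattainable request
raises a configuration error rather than silently under-delivering.

**Censoring.** Independent exponential with hazard `λ₀ r/(1−r)`, so a
fraction `r` of baseline-hazard samples is censored; the altered arm is
censored slightly less often, as in real cohorts with uniform follow-up.

**What the generators do not emulate:** real chemistry or descriptor
correlations, classifier score calibration, the degree correlations and
clustering of real PPI networks (the uniform connected graph is
deliberately structureless, so hub screens on synthetic graphs find few or
no hubs), pathway overlap structure, and non-exponential survival.
Passing tests on synthetic data therefore demonstrate correctness and
statistical calibration of the machinery, not biological validity on any
real cohort.

## Calibration checks and problem sizes

The test suite and the acceptance script verify, at sizes chosen to keep a
full run in tens of seconds: hypergeometric and Fisher results against
exhaustive enumeration (universes ≤ 25; tables with n ≤ 40); centralities
against brute-force all-pairs path enumeration (graphs ≤ 12 nodes, plus one
30-node spot check); the enrichment null false-positive rate (100
replicates × 50 categories; the hypergeometric test's discreteness makes
the achievable level slightly below the nominal 5 %); planted-category
detection at fold 5 (100 replicates, ≥ 95 % expected); log-rank type-I at
hazard ratio 1 (n = 100/arm) and power at hazard ratio 3 (n = 200/arm,
≥ 95 % expected).

## Design choices and limitations

* The pipeline report stores a config content hash and the package version
  but **no timestamp**, so that reruns are byte-identical; run time belongs
  in logs, not in the artifact.
* Clustering coefficient, heterogeneity and characteristic path length of
  the published interaction network depend on the unpublished edge list and
  cannot be recomputed from bookkeeping alone; only the closed-form
  parameters (mean degree, density, pair count, centralization) are
  reproduced.
* Some published enrichment ratios are internally inconsistent with their
  rounded expected counts at the second decimal (e.g. 18/1.87 = 9.63 vs a
  printed 9.62); ratios are asserted to one unit in the last printed
  decimal and reported at the package's own full precision elsewhere.
* Set-level mutual-exclusivity summaries (a single p-value for a whole gene
  set) are not implemented; only pairwise tests are, as the set-level
  statistic is not well defined without the underlying method.
* Fisher's exact p is conservative and strongly discrete in ~100-sample
  cohorts at moderate alteration rates: under the null its median sits well
  above 0.5 and its false-positive rate below nominal.  The calibration
  tests assert those (correct) properties rather than uniformity.
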