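# Methods

## Expressed-surfaceome inference

The pipeline operates strictly downstream of normalization: expression
matrices enter on a log-like scale (SST-RMA, RMA, vst or similar) and are
never re-normalized. Three preparation steps precede the statistics:

1. **Replicate collapse.** Technical duplicates (samples sharing a
   `replicate_group`) are averaged column-wise; a group mixing HPV
   statuses is rejected as a metadata error rather than averaged.
2. **Symbol consolidation.** When a matrix is reporter-level, each gene
   symbol keeps the single reporter with the highest median expression
   across samples; median ties break toward the lexicographically
   smallest reporter id so the choice is deterministic. Unmapped
   reporters are dropped with a logged count.
3. **Rank/quantile summaries.** Per sample, genes receive ascending
   ranks (average ranks at ties) and empirical-CDF quantiles
   `P(X ≤ x)` — computed as maximal rank over n, so tied genes share the
   upper value and every sample attains quantile 1 exactly. Per gene,
   the median across samples of ranks and of quantiles is taken; with an
   even number of samples the median is the midpoint of the two central
   values. Because the entire construction is rank-based, the summaries
   are invariant under any strictly increasing per-sample transform —
   datasets on different normalization scales remain comparable.

The median quantile is binned into quartiles with half-open-left,
closed-right boundaries: (0, .25] → Q1, …, (.75, 1] → Q4; a median
quantile of exactly 0.75 is Q3. The **expressed surfaceome** of a dataset
is the intersection of its Q4 genes with the catalogue's surfaceome
members. Quartiles are always computed over *all* genes of the dataset
and surfaceome genes binned afterwards — this is why the surfaceome tier
sizes are unequal — and the alternative (quartiles within the surfaceome
only) is deliberately not offered.

Cross-dataset comparison is plain symbol intersection after each
dataset's own consolidation. Platforms differ in transcript coverage; a
gene absent from a platform simply cannot enter that dataset's Q4, and
no imputation is attempted. `multi_overlap` reports the full Venn
decomposition so any reading of a multi-cohort overlap (global
intersection, stepwise intersections) can be assembled from one report.

## Statistical conventions

* **Motif enrichment between tiers** uses Pearson's χ² on the 2×2
  tier × motif-presence table *without* continuity correction (df = 1,
  two-sided). The uncorrected variant is what reproduces published
  quartile comparisons computed from the same counts; Yates' correction
  would roughly double the borderline p-values. A zero marginal raises
  with a pointer to the Fisher variant. "Motif present" is a collapsed
  boolean: ≥1 predicted site of that class.
* **HPV screening** uses the two-sided Welch (unequal-variance) t-test
  per gene at an unadjusted α = 0.05 (a config knob recorded with each
  result set). No multiple-testing correction is applied because the
  per-class summaries are descriptive screen fractions, not confirmatory
  calls. Genes with zero variance in both groups report t = 0, p = 1
  (with a warning) instead of being dropped, so class denominators match
  the tested set.
* **Fisher tests.** The 2×2 case delegates to the exact hypergeometric
  two-sided rule (sum of table probabilities ≤ the observed one); a zero
  margin gives p = 1 with a warning. The 2×k case is enumerated directly
  over all tables with the observed margins using multivariate
  hypergeometric probabilities; above ~2×10⁶ candidate tables it falls
  back to Monte-Carlo sampling of the null (flagged in the result, seeded
  through the caller).
* **Wilcoxon rank-sum** uses the exact null distribution when both
  samples are ≤25 and tie-free; otherwise a normal approximation with
  tie-corrected variance and a continuity correction applied toward the
  null mean — chosen so identical samples give exactly p = 1.
* **Survival.** Patients are dichotomized at the median expression of a
  marker gene, ties-at-median assigned to "low" (with an even cohort of
  distinct values this is the standard half-split). Kaplan–Meier curves
  come from the product-limit estimator; the group median OS is the
  earliest time the curve reaches 0.5 or below, `None`/`null` when never
  ("not reached", `NR` in TSV output). Groups are compared with the
  two-sided log-rank test (1 df).
* **IHC comparison** of membrane vs nuclear percent-positive is an
  *unpaired* rank-sum test by default, matching the presentation of the
  compartments as independent box groups; a paired signed-rank variant
  is available behind a flag. Percent-positive bins are ≤25% → 1,
  >25–60% → 2, >60% → 3.
* **Druggability.** A "target–drug hit" is a gene with ≥1 mapped
  compound; additional compounds per target raise only the compound
  total and mean. Per-target compound sets are summed without
  cross-target deduplication — that convention reproduces the internal
  ratios of the reference per-class table (85/115 = 0.74;
  27/115 = 23.47%). Display rounding is 2 d.p. for means and percents.

## Synthetic-data generator

The generator emulates the study conditions the analysis was designed
for: a small translatome panel of HPV-negative cell lines arrayed in
duplicate, an 18-tumor RNA-seq cohort with 8 HPV-negative / 10
HPV-positive patients, a SURFY-sized catalogue (2886 surfaceome members
among 20000 genes), and 12 IHC samples × 3 markers × 2 compartments.

Expression is drawn directly on the normalized log scale — per-gene
baselines N(7, 1.5²), per-cell-line biological effects N(0, 0.5²) shared
by the duplicate columns, technical noise N(0, 0.3²) for arrays (giving
duplicate correlations ≈0.96 across genes) and biological noise
N(0, 1²) between tumors. Counts are deliberately not modeled; every
pipeline stage operates post-normalization, and the rank/quantile step
is scale-free anyway.

Planted structure, with defaults chosen once as a realistic regime:

* **High-expression subset**: 25% of surfaceome genes (always including
  the markers BSG, FGFR1, SLC16A1) are shifted up by 2.5 baseline-SD
  units, putting ≈95% of them in the top expression quartile.
* **HPV effects**: 20% of surfaceome genes receive a ±2 tumor-SD shift
  in HPV-positive samples — large enough that an 8-vs-10 Welch screen
  detects them with power >0.8, so the per-class difference fractions
  are informative rather than noise.
* **Motif rates**: O-motif 22% (planted-high) vs 10% (others), C-motif
  20% vs 19%, N-X-S/T 97% vs 94% — anchored at the reference tier
  proportions, so a tier comparison on simulated data shows the same
  qualitative pattern (strong O enrichment, marginal N, null C).
* **Drug rates** per class (Receptors 23%, Transporters 22%, Enzymes
  21%, Unclassified 6%, Miscellaneous 1%) with 1 + Poisson(2) compounds
  per hit, matching the reference hit proportions and ≈3 compounds per
  drugged receptor.
* **Survival**: exponential event times with baseline hazard
  ln 2 / 54.5 per month (anchoring the cohort median OS) multiplied by
  exp(log 4) for patients in the marker gene's high-expression half;
  independent exponential censoring at hazard 0.005/month. p16 is
  Positive for every HPV-positive patient; HPV-negative patients are
  Negative/Positive/Unknown with probabilities 0.75/0.10/0.15.

All randomness flows from a single seed through named `SeedSequence`
substreams (catalogue, planted set, baselines, cell lines, tumors,
clinical, drugs, IHC, HPV effects), so each generator is a pure function
of the config and adding one never perturbs another. Identical configs
produce byte-identical TSV bundles.

What the generator does **not** emulate: platform-specific probe
effects, tumor purity and stromal admixture, HPV genotype diversity,
count-level mean–variance structure, and correlated gene modules
(genes are independent given their baselines). Passing tests therefore
demonstrate that the machinery recovers planted structure under clean
conditions, not that real cohorts of this size would yield equally
crisp results.

Alongside the simulators, `fixture_reference_tables()` builds deterministic
gene-/patient-level tables whose marginals equal published summary
tables (motif counts by quartile, the p16 × HPV cross-tab, per-class
druggability counts). These let the reference statistics be *recomputed*
from reconstructed inputs; dataset-dependent results that require the
original expression matrices (absolute expressed-surfaceome sizes,
cohort median survival times) are out of reach by construction and are
not asserted anywhere.

## Numerical and design notes

* Problem sizes in the test suite are scaled to keep the full run fast:
  property oracles use 200-gene columns, power checks 200 replicates,
  null calibrations 2000 replicates, and the planted-recovery check 50
  replicates at the full 20000-gene scale (the cheapest stage of the
  pipeline dominates there).
* Catalogue identity is the trimmed, case-sensitive gene symbol. ID
  translation (Ensembl ↔ symbol) is out of scope; a column-name dialect
  map on read covers files with different headers or yes/no booleans.
* Drug-map symbols with no catalogue entry are ignored with a logged
  count; matching is by symbol (protein-accession matching would need
  an external mapping resource and is out of scope).
* `class_breakdown` and the per-class summaries bucket missing
  annotations as `Unclassified` at both levels so counts always sum to
  the query size.
* The pipeline's stages are exposed individually (library functions and
  CLI subcommands) and `run_all` is their composition; the end-to-end
  report is byte-deterministic given inputs and seed.

## Known limitations

* Transcript-level quartiles are a proxy for surface protein abundance;
  the IHC module exists precisely because the proxy can fail
  post-transcriptionally.
* The exact 2×k Fisher enumeration is exponential in k; very wide
  categorical variables trip the Monte-Carlo fallback, whose p-values
  carry sampling error (~1/√B).
* The log-rank test and KM medians are unstable in cohorts this small
  (n = 18); the survival output reports group sizes and event counts so
  users can judge support.
* With heavy ties at the median, `dichotomize_by_median` can produce
  strongly unbalanced groups (ties all go to "low"); it refuses only the
  fully degenerate constant case.
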