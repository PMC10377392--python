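# surfaceomics

Profiling the **expressed surfaceome** — the cell-surface proteins a tumor
actually transcribes at high levels — from normalized gene-expression
matrices. The package was built around the surfaceome of penile squamous
cell carcinoma (PSCC), a rare cancer where cell-surface biomarkers and drug
targets are essentially uncharted, but the machinery is generic: any
annotation catalogue of surface proteins plus any normalized expression
matrix (microarray translatome, RNA-seq vst values, ...) will do.

## What it computes

**Expressed surfaceome.** For each sample, genes are rank-ordered and each
gene receives its empirical-CDF quantile

&nbsp;&nbsp;&nbsp;&nbsp;*q(g, s)* = #{genes in *s* with expression ≤ expression of *g*} / #genes,

then per gene the median quantile across samples is binned into quartiles
Q1–Q4 (boundaries (0, .25], (.25, .5], (.5, .75], (.75, 1]). The expressed
surfaceome of a dataset is the set of catalogue surfaceome genes in Q4 of
*whole-transcriptome* expression; expressed surfaceomes from several
cohorts are compared by symbol intersection. Upstream conveniences are
included: technical-duplicate averaging and reporter→symbol consolidation
(keeping the reporter with the highest median expression).

**Annotation layers.** Functional-class breakdowns (Almén main classes and
subclasses), glycosylation-motif enrichment between expression tiers
(uncorrected Pearson χ² on the 2×2 tier × motif-presence table), and
druggability per class from a drug–target map (targets, total compounds,
mean compounds/target, targets with ≥1 compound).

**HPV and clinical statistics.** Per-gene Welch *t*-tests between
HPV-negative and HPV-positive tumors with per-class difference summaries;
cohort characteristic tables with exact Fisher (2×k by enumeration) and
Wilcoxon rank-sum tests; membrane-vs-nuclear IHC comparisons; and
overall-survival analysis where patients are dichotomized at the median
expression of a marker gene and compared by Kaplan–Meier curves with a
log-rank test.

**Synthetic data.** `surfaceomics.synthetic` generates every input — the
catalogue, cell-line and tumor matrices, drug map, clinical and IHC
tables — with planted structure (high-expression surfaceome subset, HPV
effects, tier-dependent motif rates, class-dependent drug rates, a marker
gene driving hazard), so the whole pipeline is testable end to end without
any restricted patient data.

## Worked example

```python
import surfaceomics as sx

config = sx.SimulationConfig(seed=11, n_genes=5000, n_surfaceome=700)
catalogue = sx.simulate_catalogue(config)
cells = sx.collapse_replicates(sx.simulate_cell_lines(config))
tumors, clinical = sx.simulate_tumors(config)

cell_summary = sx.summarize_genes(cells)
tumor_summary = sx.summarize_genes(tumors)
cell_surf = sx.expressed_surfaceome(cell_summary, catalogue, "cell_lines")
tumor_surf = sx.expressed_surfaceome(tumor_summary, catalogue, "tumors")
core = sx.intersect_expressed(cell_surf, tumor_surf)
print(f"expressed surfaceome: {len(cell_surf.genes)} (cell lines), "
      f"{len(tumor_surf.genes)} (tumors), {len(core)} shared")
```

```
expressed surfaceome: 269 (cell lines), 251 (tumors), 232 shared
```

269 of the 700 simulated surface genes sit in the top expression quartile
of the cell lines, 251 in the tumors, and 232 are shared — the "expressed
surfaceome" this cohort pair supports. Its functional composition:

```python
print(sx.class_breakdown(core, catalogue, "main").to_string(index=False))
```

```
        label  count   percent  percent_display
 Unclassified     92 39.655172               40
    Receptors     51 21.982759               22
Miscellaneous     38 16.379310               16
 Transporters     33 14.224138               14
      Enzymes     18  7.758621                8
```

HPV screening and marker-gene survival:

```python
screen = sx.hpv_screen(tumors, core, alpha=0.05)
print(f"HPV-independent fraction: {100 * (1 - screen['significant'].mean()):.0f}%")

groups = sx.dichotomize_by_median(tumors.values.loc["BSG"])
comparison = sx.km_logrank(clinical, groups.to_dict())
for g in comparison.groups:
    m = "not reached" if g.median_os is None else f"{g.median_os:.1f} months"
    print(f"BSG {g.label}: n={g.n}, events={g.events}, median OS {m}")
print(f"log-rank p = {comparison.logrank_p:.4f}")
```

```
HPV-independent fraction: 75%
BSG high: n=9, events=8, median OS 4.6 months
BSG low: n=9, events=7, median OS 41.6 months
log-rank p = 0.0003
```

Most of the expressed surfaceome is independent of HPV status at the
unadjusted 0.05 level, and the simulated cohort's planted BSG hazard
(log HR = log 4) is recovered as a clear survival split. A `surfaceomics`
command-line interface wraps the same stages (`simulate`, `summarize`,
`expressed`, `intersect`, `diff`, `drugs`, `clinical`, `fixtures`, `run`);
`surfaceomics run config.yaml` executes everything and writes intermediate
TSVs plus a machine-readable `report.json`.

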