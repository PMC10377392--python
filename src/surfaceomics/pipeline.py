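"""End-to-end orchestration: inputs in, intermediate TSVs and a JSON report out.

Stage order follows the method: summarize each expression dataset
(collapse technical duplicates, consolidate reporters to symbols,
rank/quantile summaries), derive each dataset's expressed surfaceome
(Q4), intersect across datasets, break the sets down by functional
class, test motif enrichment between the first dataset's Q1 and Q4
tiers, screen the tumor dataset for HPV-dependent expression, summarize
druggability of the cross-dataset surfaceome, and run the clinical
statistics (cohort table, p16-by-HPV exact test, IHC compartment
comparisons, median-dichotomized survival for the marker genes).

A stage failure aborts the run with the stage name attached; outputs
written before the failure are retained for inspection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import differential as diff
from . import druggability as drug
from . import expressed as expr
from . import reference as ref
from . import summarize as summ

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetPaths:
    dataset_id: str
    matrix: str
    samples: str


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    catalogue: str
    datasets: tuple[DatasetPaths, ...]
    outdir: str
    drugs: Optional[str] = None
    clinical: Optional[str] = None
    ihc: Optional[str] = None
    alpha: float = 0.05
    expressed_quartile: str = "Q4"
    marker_genes: tuple[str, ...] = ("BSG", "FGFR1", "SLC16A1")
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = tuple(DatasetPaths(**d) for d in raw.pop("datasets"))
        if "marker_genes" in raw:
            raw["marker_genes"] = tuple(raw["marker_genes"])
        return RunConfig(datasets=datasets, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report; returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "alpha": config.alpha,
        "expressed_quartile": config.expressed_quartile,
        "seed": config.seed,
    }

    catalogue = _stage("read_catalogue")(ref.read_catalogue)(config.catalogue)
    drugs = (
        _stage("read_drug_table")(ref.read_drug_table)(config.drugs)
        if config.drugs
        else None
    )

    summaries: dict[str, pd.DataFrame] = {}
    datasets: dict[str, summ.ExpressionDataset] = {}
    expressed_sets: dict[str, expr.ExpressedSurfaceome] = {}
    report["expressed_counts"] = {}
    report["class_breakdowns"] = {}
    for ds_paths in config.datasets:

        @_stage(f"summarize[{ds_paths.dataset_id}]")
        def summarize_one(paths=ds_paths) -> None:
            dataset = summ.read_expression(
                paths.matrix, paths.samples, dataset_id=paths.dataset_id
            )
            if any(s.replicate_group for s in dataset.samples):
                dataset = summ.collapse_replicates(dataset)
            if dataset.reporter_to_symbol is not None:
                dataset = summ.consolidate_to_symbols(dataset)
            summary = summ.summarize_genes(dataset)
            summary.to_csv(outdir / f"summary_{paths.dataset_id}.tsv", sep="\t")
            surfaceome = expr.expressed_surfaceome(
                summary, catalogue, dataset_id=paths.dataset_id
            )
            datasets[paths.dataset_id] = dataset
            summaries[paths.dataset_id] = summary
            expressed_sets[paths.dataset_id] = surfaceome
            _write_gene_list(
                surfaceome.genes, catalogue,
                outdir / f"expressed_{paths.dataset_id}.tsv",
            )
            breakdown = expr.class_breakdown(surfaceome.genes, catalogue, "main")
            breakdown.to_csv(
                outdir / f"classes_{paths.dataset_id}.tsv", sep="\t", index=False
            )
            report["expressed_counts"][paths.dataset_id] = len(surfaceome.genes)
            report["class_breakdowns"][paths.dataset_id] = breakdown.to_dict("records")

        summarize_one()

    # Cross-dataset intersection (first two datasets define the core set).
    ids = [d.dataset_id for d in config.datasets]
    core_genes: frozenset[str]
    if len(ids) >= 2:
        core_genes = expr.intersect_expressed(
            expressed_sets[ids[0]], expressed_sets[ids[1]]
        )
        overlap = expr.multi_overlap(
            [expressed_sets[i].genes for i in ids], names=ids
        )
        report["intersection_size"] = len(core_genes)
        report["overlap_regions"] = {
            "+".join(n for n, m in zip(overlap.set_names, pattern) if m): count
            for pattern, count in overlap.regions.items()
        }
        _write_gene_list(core_genes, catalogue, outdir / "intersection.tsv")
        report["intersection_class_breakdown"] = expr.class_breakdown(
            core_genes, catalogue, "main"
        ).to_dict("records")
    else:
        core_genes = expressed_sets[ids[0]].genes
        report["intersection_size"] = len(core_genes)

    # Motif tier tests on the first dataset (Q1 vs Q4 surfaceome genes).
    @_stage("motif_tests")
    def motif_tests() -> None:
        first = summaries[ids[0]]
        q1 = expr.quartile_subsets(first, catalogue, "Q1")
        q4 = expr.quartile_subsets(first, catalogue, "Q4")
        out = {}
        if q1 and q4:
            for motif in ("O", "C", "noncyt_nxst"):
                res = diff.motif_tier_test(q1, q4, catalogue, motif)
                out[motif] = {
                    "table": res.table.tolist(),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
        report["motif_tests"] = out

    motif_tests()

    # HPV screen on the first dataset containing both HPV groups.
    @_stage("hpv_screen")
    def hpv_stage() -> None:
        report["hpv_summary"] = None
        for ds_id in ids:
            dataset = datasets[ds_id]
            statuses = [s.hpv_status for s in dataset.samples]
            if statuses.count("neg") >= 2 and statuses.count("pos") >= 2:
                results = diff.hpv_screen(dataset, core_genes, alpha=config.alpha)
                results.to_csv(
                    outdir / f"hpv_screen_{ds_id}.tsv", sep="\t", index=False
                )
                summary = diff.class_difference_summary(results, catalogue, "main")
                summary.to_csv(
                    outdir / f"hpv_classes_{ds_id}.tsv", sep="\t", index=False
                )
                n_sig = int(results["significant"].sum())
                report["hpv_summary"] = {
                    "dataset_id": ds_id,
                    "n_tested": len(results),
                    "n_significant": n_sig,
                    "percent_hpv_independent": (
                        100.0 * (1 - n_sig / len(results)) if len(results) else None
                    ),
                    "classes": summary.to_dict("records"),
                }
                break

    hpv_stage()

    # Druggability of the core gene set.
    if drugs is not None:

        @_stage("druggability")
        def drug_stage() -> None:
            summary = drug.druggability_summary(core_genes, catalogue, drugs)
            drug.format_summary(summary).to_csv(
                outdir / "druggability.tsv", sep="\t", index=False
            )
            report["druggability"] = summary.to_dict("records")

        drug_stage()

    # Clinical statistics.
    if config.clinical:

        @_stage("clinical")
        def clinical_stage() -> None:
            records = clin.read_clinical_table(config.clinical)
            rng = np.random.default_rng(config.seed)
            table = clin.cohort_table(records, rng=rng)
            table.to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)
            report["clinical_tests"] = _jsonable_frame(table)

            # p16 x HPV on the 2x2 excluding Unknown.
            frame = clin.clinical_to_frame(records)
            known = frame[frame["p16"] != "Unknown"]
            crosstab = pd.crosstab(known["p16"], known["hpv_status"])
            crosstab = crosstab.reindex(
                index=["Negative", "Positive"], columns=["neg", "pos"], fill_value=0
            )
            res = clin.fisher_exact_2x2(crosstab.to_numpy())
            report["p16_hpv"] = {
                "table": res.table.tolist(),
                "p_value": res.p_value,
                "method": res.method,
            }

            report["survival"] = _survival_stage(config, records, datasets, outdir)

        clinical_stage()

    if config.ihc:

        @_stage("ihc")
        def ihc_stage() -> None:
            records = clin.read_ihc_table(config.ihc)
            out = {}
            for marker in sorted({r.marker for r in records}):
                statistic, p = clin.ihc_compartment_compare(records, marker)
                out[marker] = {"statistic": statistic, "p_value": p}
            report["ihc_tests"] = out

        ihc_stage()

    report_path = Path(outdir) / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", report_path)
    return report


def _survival_stage(
    config: RunConfig,
    records: Sequence[clin.ClinicalRecord],
    datasets: dict[str, summ.ExpressionDataset],
    outdir: Path,
) -> dict:
    """Median-dichotomized KM/log-rank per marker gene, when expression matches."""
    patient_ids = {r.patient_id for r in records}
    expr_dataset = None
    for dataset in datasets.values():
        if patient_ids <= set(dataset.values.columns):
            expr_dataset = dataset
            break
    out: dict = {}
    if expr_dataset is None:
        return out
    for gene in config.marker_genes:
        if gene not in expr_dataset.values.index:
            continue
        expression = expr_dataset.values.loc[gene, sorted(patient_ids)]
        try:
            groups = clin.dichotomize_by_median(expression)
        except ValueError:
            continue
        comparison = clin.km_logrank(records, groups.to_dict())
        out[gene] = {
            "groups": [
                {
                    "group": g.label,
                    "n": g.n,
                    "events": g.events,
                    "median_os": g.median_os,  # null = not reached
                }
                for g in comparison.groups
            ],
            "logrank_statistic": comparison.logrank_statistic,
            "logrank_p": comparison.logrank_p,
        }
    if out:
        (outdir / "survival.json").write_text(
            json.dumps(out, indent=2, sort_keys=True) + "\n"
        )
    return out


def _write_gene_list(genes, catalogue, path: Path) -> None:
    table, _ = ref.annotation_join(genes, catalogue)
    table.to_csv(path, sep="\t", index=False)


def _jsonable_frame(df: pd.DataFrame) -> list[dict]:
    records = df.to_dict("records")
    for row in records:
        for key, value in row.items():
            if isinstance(value, float) and np.isnan(value):
                row[key] = None
    return records
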