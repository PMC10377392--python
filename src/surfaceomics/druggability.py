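"""Druggability summary: cross-reference a gene set with a drug-target map.

For each Almen main class within the gene set: the number of targets,
the total number of mapped compounds (per-target set sizes summed, no
cross-target deduplication), the mean compounds per target, the number
of targets with at least one compound ("target-drug hits"), and that
number as a percentage of the class. Classes are ordered by hit count
descending.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .reference import Catalogue, DrugTargetMap

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "label",
    "n_targets",
    "total_drugs",
    "mean_drugs",
    "n_targets_with_drug",
    "percent_with_drug",
)


def druggability_summary(
    genes: Iterable[str], catalogue: Catalogue, drugs: DrugTargetMap
) -> pd.DataFrame:
    """Per-class druggability of a gene set.

    Every gene contributes to exactly one class (missing annotation
    counts as Unclassified), so ``n_targets`` sums to the set size.
    Drug-map symbols outside the gene set are ignored (count logged).
    ``mean_drugs`` and ``percent_with_drug`` are exact ratios; round at
    display time (both conventionally to 2 d.p.).
    """
    gene_list = sorted(set(genes))
    unmatched = len(set(drugs.entries) - set(gene_list))
    if unmatched:
        logger.info(
            "druggability_summary: %d drug-map symbols outside the gene set", unmatched
        )

    per_class: dict[str, dict[str, int]] = {}
    for gene in gene_list:
        ann = catalogue.get(gene)
        label = ann.main_class_label if ann is not None else "Unclassified"
        acc = per_class.setdefault(
            label, {"n_targets": 0, "total_drugs": 0, "n_targets_with_drug": 0}
        )
        n_compounds = drugs.n_compounds(gene)
        acc["n_targets"] += 1
        acc["total_drugs"] += n_compounds
        acc["n_targets_with_drug"] += int(n_compounds > 0)

    rows = []
    for label, acc in per_class.items():
        n = acc["n_targets"]
        rows.append(
            {
                "label": label,
                "n_targets": n,
                "total_drugs": acc["total_drugs"],
                "mean_drugs": acc["total_drugs"] / n,
                "n_targets_with_drug": acc["n_targets_with_drug"],
                "percent_with_drug": 100.0 * acc["n_targets_with_drug"] / n,
            }
        )
    df = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    if not df.empty:
        df = df.sort_values(
            ["n_targets_with_drug", "label"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def format_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Display copy with mean_drugs and percent_with_drug at 2 d.p."""
    out = df.copy()
    out["mean_drugs"] = out["mean_drugs"].round(2)
    out["percent_with_drug"] = out["percent_with_drug"].round(2)
    return out
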