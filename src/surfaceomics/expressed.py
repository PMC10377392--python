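"""Expressed surfaceomes: top-quartile surfaceome genes and set algebra.

The expressed surfaceome of a dataset is the set of catalogue surfaceome
genes falling in quartile Q4 of that dataset's whole-transcriptome
expression (quartiles computed over ALL genes, surfaceome genes then
binned — this is why tier sizes are unequal). Expressed surfaceomes from
different datasets are compared by plain symbol intersection; a gene
absent from a platform simply cannot enter that dataset's tier, and no
imputation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

from .reference import Catalogue
from .summarize import QUARTILE_LABELS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressedSurfaceome:
    """Surfaceome genes in a dataset's top expression quartile."""

    dataset_id: str
    genes: frozenset[str]
    source_quartile: str = "Q4"


@dataclass(frozen=True)
class OverlapReport:
    """Venn decomposition of several gene sets.

    ``regions`` maps a membership pattern (one boolean per input set, in
    order) to the number of genes showing exactly that pattern; the
    all-absent pattern is omitted. ``intersection`` is the global
    intersection and ``union`` the global union.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[bool, ...], int]
    intersection: frozenset[str]
    union: frozenset[str]


def quartile_subsets(
    summaries: pd.DataFrame, catalogue: Catalogue, tier: str
) -> frozenset[str]:
    """Surfaceome genes of the dataset falling in the requested tier.

    ``summaries`` must come from :func:`surfaceomics.summarize.summarize_genes`
    run on ALL genes of the dataset, so that tiers are relative to the
    whole transcriptome.
    """
    if tier not in QUARTILE_LABELS:
        raise ValueError(f"tier must be one of {QUARTILE_LABELS}, got {tier!r}")
    in_tier = set(summaries.index[summaries["quartile"] == tier].astype(str))
    return frozenset(in_tier & catalogue.surfaceome_symbols)


def expressed_surfaceome(
    summaries: pd.DataFrame, catalogue: Catalogue, dataset_id: str = ""
) -> ExpressedSurfaceome:
    """The dataset's expressed surfaceome: surfaceome genes in Q4."""
    if len(catalogue.surfaceome_symbols) == 0:
        logger.warning("catalogue contains no surfaceome genes; empty result")
    return ExpressedSurfaceome(
        dataset_id=dataset_id,
        genes=quartile_subsets(summaries, catalogue, "Q4"),
    )


def intersect_expressed(
    a: ExpressedSurfaceome | Iterable[str], b: ExpressedSurfaceome | Iterable[str]
) -> frozenset[str]:
    """Symbol intersection of two expressed surfaceomes (symmetric)."""
    sa = a.genes if isinstance(a, ExpressedSurfaceome) else frozenset(a)
    sb = b.genes if isinstance(b, ExpressedSurfaceome) else frozenset(b)
    return sa & sb


def multi_overlap(
    sets: Sequence[Iterable[str]], names: Sequence[str] | None = None
) -> OverlapReport:
    """Full Venn decomposition of two or more gene sets.

    Reports the exclusive count of every membership region, so any
    reading of a multi-cohort overlap (global intersection, pairwise
    intersections, genes private to one cohort) can be assembled from
    the same report.
    """
    materialized = [frozenset(s) for s in sets]
    if len(materialized) < 2:
        raise ValueError("multi_overlap requires at least two sets")
    if names is None:
        names = tuple(f"set{i + 1}" for i in range(len(materialized)))
    names = tuple(names)
    if len(names) != len(materialized):
        raise ValueError("one name per set required")

    union = frozenset().union(*materialized)
    regions: dict[tuple[bool, ...], int] = {
        pattern: 0
        for pattern in product((False, True), repeat=len(materialized))
        if any(pattern)
    }
    for gene in union:
        pattern = tuple(gene in s for s in materialized)
        regions[pattern] += 1
    intersection = frozenset.intersection(*materialized)
    return OverlapReport(
        set_names=names, regions=regions, intersection=intersection, union=union
    )


def class_breakdown(
    genes: Iterable[str], catalogue: Catalogue, level: str = "main"
) -> pd.DataFrame:
    """Functional-class composition of a gene set.

    Counts genes per Almen class (``level="main"``) or subclass
    (``level="sub"``); genes without an annotation at the requested
    level are bucketed as ``Unclassified`` so counts always sum to the
    set size. Returns columns ``label``, ``count``, ``percent``
    (unrounded) and ``percent_display`` (integer-rounded), sorted by
    count descending then label.
    """
    if level not in ("main", "sub"):
        raise ValueError(f"level must be 'main' or 'sub', got {level!r}")
    gene_list = sorted(set(genes))
    counts: dict[str, int] = {}
    for gene in gene_list:
        ann = catalogue.get(gene)
        if ann is None:
            label = "Unclassified"
        elif level == "main":
            label = ann.main_class_label
        else:
            label = ann.almen_sub if ann.almen_sub is not None else "Unclassified"
        counts[label] = counts.get(label, 0) + 1
    total = len(gene_list)
    rows = [
        {
            "label": label,
            "count": n,
            "percent": 100.0 * n / total if total else 0.0,
        }
        for label, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["label", "count", "percent"])
    if not df.empty:
        df = df.sort_values(
            ["count", "label"], ascending=[False, True]
        ).reset_index(drop=True)
        df["percent_display"] = df["percent"].round(0).astype(int)
    else:
        df["percent_display"] = pd.Series(dtype=int)
    return df
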