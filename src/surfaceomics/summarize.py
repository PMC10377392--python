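"""Per-gene rank/quantile summaries and quartile tiers of expression.

A normalized (log-like) expression matrix enters reporter-level; it is
collapsed across technical duplicates (column means within a replicate
group), consolidated to gene symbols (keeping, per symbol, the reporter
with the highest median expression across samples), and then summarized:
per sample, genes are rank-ordered and assigned their empirical-CDF
quantile; per gene, the median rank and median quantile across samples
are taken, and the median quantile is binned into expression quartiles
Q1-Q4. Quartiles are always relative to ALL genes of the dataset, not to
any subset of interest.

Conventions (the rank/quantile step is scale-free, so these matter only
for ties and boundaries):

* quantile of gene g in sample s = (# genes with expression <= g's) / n,
  i.e. the ecdf step function evaluated at the data points; ties share
  the upper value; range (0, 1].
* ranks ascend (1 = lowest expression) with average ranks for ties.
* quartile bins are half-open on the left, closed on the right:
  (0, .25] -> Q1, (.25, .5] -> Q2, (.5, .75] -> Q3, (.75, 1] -> Q4.
* the median over an even number of samples is the midpoint of the two
  central values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")
HPV_STATUSES = ("neg", "pos", "unknown")


class ExpressionDataError(ValueError):
    """Malformed expression matrix or sample metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    Samples sharing a ``replicate_group`` are technical duplicates and
    are averaged by :func:`collapse_replicates`.
    """

    sample_id: str
    dataset_id: str = ""
    hpv_status: str = "unknown"
    replicate_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hpv_status not in HPV_STATUSES:
            raise ExpressionDataError(
                f"sample {self.sample_id}: hpv_status must be one of "
                f"{HPV_STATUSES}, got {self.hpv_status!r}"
            )


@dataclass(frozen=True)
class ExpressionDataset:
    """A normalized genes-x-samples matrix with sample metadata.

    ``values`` rows are reporters or gene symbols (index = row ids),
    columns are sample ids matching ``samples`` in order. Missing values
    are rejected at construction: every pipeline stage assumes a dense
    matrix.
    """

    values: pd.DataFrame
    samples: tuple[SampleMeta, ...]
    reporter_to_symbol: Optional[Mapping[str, str]] = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ExpressionDataError(
                "matrix columns must match sample metadata ids, in order"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ExpressionDataError("duplicate sample_id in metadata")
        if self.values.index.has_duplicates:
            raise ExpressionDataError("duplicate row ids in expression matrix")
        if self.values.isna().any().any():
            raise ExpressionDataError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass(frozen=True)
class GeneExpressionSummary:
    """Per-gene summary: median rank, median ecdf quantile, quartile tier."""

    symbol: str
    median_rank: float
    median_quantile: float
    quartile: str


def quartile_of_quantile(q: float) -> str:
    """Map an ecdf quantile in (0, 1] to its quartile tier.

    Boundaries are closed on the right: exactly 0.25 is Q1, exactly 0.75
    is Q3, so only quantiles strictly above 0.75 reach Q4.
    """
    if not 0 < q <= 1:
        raise ValueError(f"quantile must lie in (0, 1], got {q}")
    if q <= 0.25:
        return "Q1"
    if q <= 0.5:
        return "Q2"
    if q <= 0.75:
        return "Q3"
    return "Q4"


def collapse_replicates(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average technical duplicate columns within each replicate group.

    Samples without a replicate group pass through unchanged. The
    collapsed column keeps the metadata of the group's first member and
    is named after its replicate group. A group mixing HPV statuses is
    rejected: averaging across biologically distinct samples is a
    metadata error, not a reduction.
    """
    groups: dict[str, list[SampleMeta]] = {}
    order: list[tuple[str, SampleMeta | None]] = []
    for meta in dataset.samples:
        if meta.replicate_group is None:
            order.append((meta.sample_id, meta))
        else:
            if meta.replicate_group not in groups:
                order.append((meta.replicate_group, None))
                groups[meta.replicate_group] = []
            groups[meta.replicate_group].append(meta)

    for group, members in groups.items():
        statuses = {m.hpv_status for m in members}
        if len(statuses) > 1:
            raise ExpressionDataError(
                f"replicate group {group!r} mixes HPV statuses {sorted(statuses)}"
            )

    columns: dict[str, pd.Series] = {}
    metas: list[SampleMeta] = []
    for key, single in order:
        if single is not None:
            columns[key] = dataset.values[key]
            metas.append(single)
        else:
            members = groups[key]
            member_ids = [m.sample_id for m in members]
            columns[key] = dataset.values[member_ids].mean(axis=1)
            metas.append(replace(members[0], sample_id=key, replicate_group=None))
    values = pd.DataFrame(columns, index=dataset.values.index)
    return ExpressionDataset(
        values=values,
        samples=tuple(metas),
        reporter_to_symbol=dataset.reporter_to_symbol,
        dataset_id=dataset.dataset_id,
    )


def consolidate_to_symbols(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse reporters to gene symbols.

    For each symbol, the single reporter with the highest median
    expression across samples is kept; median ties break toward the
    lexicographically smallest reporter id. Reporters with no symbol
    mapping are dropped (count logged).
    """
    if dataset.reporter_to_symbol is None:
        raise ExpressionDataError("consolidation requires a reporter_to_symbol map")
    mapping = dataset.reporter_to_symbol
    medians = dataset.values.median(axis=1)

    best: dict[str, str] = {}  # symbol -> winning reporter
    dropped = 0
    for reporter in dataset.values.index:
        symbol = mapping.get(reporter)
        if symbol is None:
            dropped += 1
            continue
        incumbent = best.get(symbol)
        if incumbent is None:
            best[symbol] = reporter
            continue
        m_new, m_old = medians[reporter], medians[incumbent]
        if m_new > m_old or (m_new == m_old and str(reporter) < str(incumbent)):
            best[symbol] = reporter
    if dropped:
        logger.info("consolidate_to_symbols: dropped %d unmapped reporters", dropped)

    symbols = sorted(best)
    values = dataset.values.loc[[best[s] for s in symbols]]
    values.index = pd.Index(symbols, name="symbol")
    return ExpressionDataset(
        values=values,
        samples=dataset.samples,
        reporter_to_symbol=None,
        dataset_id=dataset.dataset_id,
    )


def sample_ranks(dataset: ExpressionDataset) -> pd.DataFrame:
    """Within-sample ascending ranks (1 = lowest), average ranks at ties."""
    return dataset.values.rank(axis=0, method="average", ascending=True)


def sample_quantiles(dataset: ExpressionDataset) -> pd.DataFrame:
    """Within-sample ecdf quantiles: P(X <= x) over the sample's genes.

    Equivalent to maximal rank / n, so tied genes share the upper
    quantile and every column attains exactly 1 at its maximum.
    """
    n = dataset.n_genes
    return dataset.values.rank(axis=0, method="max", ascending=True) / n


def summarize_genes(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene median rank, median quantile and quartile tier.

    The dataset must be consolidated (one row per symbol) and contain
    at least one sample. Returns a DataFrame indexed by symbol with
    columns ``median_rank``, ``median_quantile``, ``quartile``.
    """
    if dataset.n_samples < 1:
        raise ExpressionDataError("summarize_genes requires at least one sample")
    ranks = sample_ranks(dataset)
    quantiles = sample_quantiles(dataset)
    out = pd.DataFrame(
        {
            "median_rank": ranks.median(axis=1),
            "median_quantile": quantiles.median(axis=1),
        },
        index=dataset.values.index,
    )
    out["quartile"] = out["median_quantile"].map(quartile_of_quantile)
    out.index.name = "symbol"
    return out


def summaries_to_records(summaries: pd.DataFrame) -> list[GeneExpressionSummary]:
    """View a summary frame as a list of per-gene records."""
    return [
        GeneExpressionSummary(
            symbol=str(sym),
            median_rank=float(row["median_rank"]),
            median_quantile=float(row["median_quantile"]),
            quartile=str(row["quartile"]),
        )
        for sym, row in summaries.iterrows()
    ]


# ---------------------------------------------------------------------------
# I/O


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV: sample_id, dataset_id, hpv_status, replicate_group."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    metas = []
    for _, row in df.iterrows():
        group = row.get("replicate_group")
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]).strip(),
                dataset_id=str(row.get("dataset_id", "") or ""),
                hpv_status=str(row.get("hpv_status", "unknown") or "unknown"),
                replicate_group=None if pd.isna(group) or group == "" else str(group),
            )
        )
    return metas


def read_expression(
    matrix_path: str | Path,
    samples: Sequence[SampleMeta] | str | Path,
    dataset_id: str = "",
) -> ExpressionDataset:
    """Read an expression TSV (first column ``symbol`` or ``reporter``).

    When the first column is named ``reporter`` a second column
    ``symbol`` is expected and becomes the reporter-to-symbol map.
    ``samples`` may be a metadata TSV path or a pre-built list; samples
    are reordered to match the matrix columns.
    """
    df = pd.read_csv(matrix_path, sep="\t")
    if isinstance(samples, (str, Path)):
        samples = read_sample_table(samples)
    first = df.columns[0]
    reporter_to_symbol = None
    if first == "reporter":
        if "symbol" not in df.columns[:2]:
            raise ExpressionDataError(
                "reporter-level matrix must carry a 'symbol' second column"
            )
        reporter_to_symbol = dict(
            zip(df["reporter"].astype(str), df["symbol"].astype(str))
        )
        values = df.drop(columns=["symbol"]).set_index("reporter")
    elif first == "symbol":
        values = df.set_index("symbol")
    else:
        raise ExpressionDataError(
            f"first column must be 'symbol' or 'reporter', got {first!r}"
        )
    values.index = values.index.astype(str)
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in values.columns if c not in by_id]
    if missing:
        raise ExpressionDataError(f"samples missing from metadata: {missing}")
    ordered = tuple(by_id[c] for c in values.columns)
    return ExpressionDataset(
        values=values.astype(float),
        samples=ordered,
        reporter_to_symbol=reporter_to_symbol,
        dataset_id=dataset_id or (ordered[0].dataset_id if ordered else ""),
    )


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path,
                     samples_path: Optional[str | Path] = None) -> None:
    out = dataset.values.copy()
    if dataset.reporter_to_symbol is not None:
        out.insert(0, "symbol",
                   [dataset.reporter_to_symbol.get(r, "") for r in out.index])
        out.index.name = "reporter"
    else:
        out.index.name = "symbol"
    out.to_csv(matrix_path, sep="\t")
    if samples_path is not None:
        rows = [
            {
                "sample_id": s.sample_id,
                "dataset_id": s.dataset_id,
                "hpv_status": s.hpv_status,
                "replicate_group": s.replicate_group or "",
            }
            for s in dataset.samples
        ]
        pd.DataFrame(rows).to_csv(samples_path, sep="\t", index=False)
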