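"""Differential screening by HPV status and motif contingency tests.

Per-gene expression differences between HPV-negative and HPV-positive
samples are screened with a two-sided Welch (unequal-variance) t-test at
an unadjusted significance level alpha (default 0.05, recorded with each
result set); the per-class summary reports, for each functional class,
the fraction of its tested genes that reached significance. No
multiple-testing correction is applied: the class summaries are
descriptive screens, not confirmatory calls.

Glycosylation-motif enrichment between expression tiers uses Pearson's
chi-squared on the 2x2 tier-by-motif table WITHOUT continuity
correction (the uncorrected statistic reproduces published quartile
comparisons computed the same way; Yates' correction would not).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import Catalogue
from .summarize import ExpressionDataset

logger = logging.getLogger(__name__)

MOTIF_FIELDS = {
    "O": "glycomineO_present",
    "C": "glycomineC_present",
    "noncyt_nxst": "noncyt_nxst_present",
}


@dataclass(frozen=True)
class ContingencyTestResult:
    table: np.ndarray
    statistic: float
    df: int
    p_value: float
    method: str  # "pearson_chisq_uncorrected" | "fisher_exact"


class DegenerateDataWarning(UserWarning):
    """Test input carries no information (e.g. zero variance everywhere)."""


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances).

    Degenerate input with zero variance in both groups is reported as
    (t=0, p=1) with a warning rather than NaN, so screened genes keep a
    defined p-value and denominators stay comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires at least two values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn(
            "zero variance in both groups; reporting t=0, p=1",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def hpv_screen(
    dataset: ExpressionDataset,
    genes: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of expression, HPV-negative vs HPV-positive.

    Genes absent from the matrix are skipped (count logged). Returns a
    DataFrame with columns ``symbol``, ``mean_neg``, ``mean_pos``, ``t``,
    ``p``, ``significant`` (p < alpha, unadjusted); ``alpha`` is stored
    in ``DataFrame.attrs``.
    """
    neg_ids = [s.sample_id for s in dataset.samples if s.hpv_status == "neg"]
    pos_ids = [s.sample_id for s in dataset.samples if s.hpv_status == "pos"]
    if len(neg_ids) < 2 or len(pos_ids) < 2:
        raise ValueError("hpv_screen requires >=2 samples in each HPV group")

    requested = sorted(set(genes))
    present = [g for g in requested if g in dataset.values.index]
    skipped = len(requested) - len(present)
    if skipped:
        logger.info("hpv_screen: %d requested genes absent from matrix", skipped)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDataWarning)
        for gene in present:
            xv = dataset.values.loc[gene, neg_ids].to_numpy(dtype=float)
            yv = dataset.values.loc[gene, pos_ids].to_numpy(dtype=float)
            t, p = welch_t_test(xv, yv)
            rows.append(
                {
                    "symbol": gene,
                    "mean_neg": float(xv.mean()),
                    "mean_pos": float(yv.mean()),
                    "t": t,
                    "p": p,
                    "significant": bool(p < alpha),
                }
            )
    out = pd.DataFrame(
        rows, columns=["symbol", "mean_neg", "mean_pos", "t", "p", "significant"]
    )
    out.attrs["alpha"] = alpha
    return out


def class_difference_summary(
    results: pd.DataFrame, catalogue: Catalogue, level: str = "main"
) -> pd.DataFrame:
    """Per-class fraction of screened genes with a significant difference.

    Columns: ``label``, ``n_different``, ``n_total``, ``percent``
    (unrounded), ``percent_display`` (integer-rounded). Sorted by label.
    """
    if level not in ("main", "sub"):
        raise ValueError(f"level must be 'main' or 'sub', got {level!r}")
    tallies: dict[str, list[int]] = {}
    for _, row in results.iterrows():
        ann = catalogue.get(row["symbol"])
        if ann is None:
            label = "Unclassified"
        elif level == "main":
            label = ann.main_class_label
        else:
            label = ann.almen_sub if ann.almen_sub is not None else "Unclassified"
        total_sig = tallies.setdefault(label, [0, 0])
        total_sig[0] += 1
        total_sig[1] += int(bool(row["significant"]))
    rows = [
        {
            "label": label,
            "n_different": sig,
            "n_total": total,
            "percent": 100.0 * sig / total,
        }
        for label, (total, sig) in sorted(tallies.items())
    ]
    df = pd.DataFrame(rows, columns=["label", "n_different", "n_total", "percent"])
    df["percent_display"] = (
        df["percent"].round(0).astype(int) if not df.empty else pd.Series(dtype=int)
    )
    return df


def pearson_chisq_2x2(table: np.ndarray) -> ContingencyTestResult:
    """Uncorrected Pearson chi-squared on a 2x2 table, df=1, two-sided."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "a marginal total is zero; the chi-squared approximation is "
            "undefined — use fisher_exact_2x2 instead"
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyTestResult(
        table=table.astype(int),
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        method="pearson_chisq_uncorrected",
    )


def motif_tier_test(
    tier_a: Iterable[str],
    tier_b: Iterable[str],
    catalogue: Catalogue,
    motif: str,
) -> ContingencyTestResult:
    """Compare motif presence between two expression tiers.

    Builds the 2x2 table (tier x motif present/absent) from the
    catalogue's collapsed motif flags and applies the uncorrected
    Pearson chi-squared test. ``motif`` is one of ``"O"``, ``"C"``,
    ``"noncyt_nxst"``. Symmetric in tier order.
    """
    if motif not in MOTIF_FIELDS:
        raise ValueError(f"motif must be one of {sorted(MOTIF_FIELDS)}, got {motif!r}")
    field = MOTIF_FIELDS[motif]
    table = np.zeros((2, 2), dtype=int)
    for i, tier in enumerate((tier_a, tier_b)):
        genes = sorted(set(tier))
        if not genes:
            raise ValueError("both tiers must be nonempty")
        for gene in genes:
            ann = catalogue.get(gene)
            if ann is None or getattr(ann, field) is None:
                raise ValueError(f"gene {gene} lacks a {motif} motif annotation")
            table[i, 0 if getattr(ann, field) else 1] += 1
    return pearson_chisq_2x2(table)
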