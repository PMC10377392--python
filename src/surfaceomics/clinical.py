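"""Clinical association and survival statistics.

Covers the patient-facing statistics of the analysis: cohort
characteristic tables compared across HPV groups (exact Fisher tests for
categoricals, Wilcoxon rank-sum for continuous variables),
immunohistochemistry compartment comparisons (membrane vs nuclear
percent-positive, unpaired Wilcoxon by default), and overall-survival
comparisons where patients are dichotomized into high/low by the median
expression of a marker gene and compared by Kaplan-Meier curves with a
log-rank test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import qth_survival_time

from .differential import ContingencyTestResult

logger = logging.getLogger(__name__)

IHC_MARKERS = ("CD147", "FGFR1", "MCT1")
IHC_COMPARTMENTS = ("membrane", "nuclear")


# ---------------------------------------------------------------------------
# Records and I/O


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    hpv_status: str  # "neg" | "pos"
    p16: str = "Unknown"  # "Negative" | "Positive" | "Unknown"
    histology: str = ""
    lvi: bool = False
    pT: int = 1
    pN: int = 0
    age_years: float = float("nan")
    os_months: float = 0.0
    os_event: bool = False

    def __post_init__(self) -> None:
        if self.hpv_status not in ("neg", "pos"):
            raise ValueError(f"{self.patient_id}: hpv_status must be neg/pos")
        if self.p16 not in ("Negative", "Positive", "Unknown"):
            raise ValueError(f"{self.patient_id}: bad p16 level {self.p16!r}")
        if not math.isfinite(self.os_months) or self.os_months < 0:
            raise ValueError(f"{self.patient_id}: os_months must be finite and >= 0")


def percent_category(percent_positive: float) -> int:
    """Bin percent of positive cells: <=25% -> 1, up to 60% -> 2, above -> 3."""
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must lie in [0, 100]")
    if percent_positive <= 25:
        return 1
    if percent_positive <= 60:
        return 2
    return 3


@dataclass(frozen=True)
class IHCRecord:
    sample_id: str
    marker: str
    hpv_status: str
    compartment: str  # "membrane" | "nuclear"
    intensity: int  # 0 none .. 3 strong
    percent_positive: float

    def __post_init__(self) -> None:
        if self.marker not in IHC_MARKERS:
            raise ValueError(f"unknown IHC marker {self.marker!r}")
        if self.compartment not in IHC_COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError("intensity must be an integer 0-3")
        if not 0 <= self.percent_positive <= 100:
            raise ValueError("percent_positive must lie in [0, 100]")

    @property
    def percent_category(self) -> int:
        return percent_category(self.percent_positive)


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClinicalRecord(
            patient_id=str(r["patient_id"]),
            hpv_status=str(r["hpv_status"]),
            p16=str(r.get("p16", "Unknown")),
            histology=str(r.get("histology", "")),
            lvi=bool(r.get("lvi", False)) if not isinstance(r.get("lvi"), str)
            else str(r["lvi"]).strip().lower() in ("true", "yes", "1"),
            pT=int(r.get("pT", 1)),
            pN=int(r.get("pN", 0)),
            age_years=float(r.get("age_years", float("nan"))),
            os_months=float(r.get("os_months", 0.0)),
            os_event=bool(r.get("os_event", False))
            if not isinstance(r.get("os_event"), str)
            else str(r["os_event"]).strip().lower() in ("true", "yes", "1"),
        )
        for _, r in df.iterrows()
    ]


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "hpv_status": r.hpv_status,
                "p16": r.p16,
                "histology": r.histology,
                "lvi": r.lvi,
                "pT": r.pT,
                "pN": r.pN,
                "age_years": r.age_years,
                "os_months": r.os_months,
                "os_event": r.os_event,
            }
            for r in records
        ]
    )


def read_ihc_table(path: str | Path) -> list[IHCRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        IHCRecord(
            sample_id=str(r["sample_id"]),
            marker=str(r["marker"]),
            hpv_status=str(r["hpv_status"]),
            compartment=str(r["compartment"]),
            intensity=int(r["intensity"]),
            percent_positive=float(r["percent_positive"]),
        )
        for _, r in df.iterrows()
    ]


def ihc_to_frame(records: Iterable[IHCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "marker": r.marker,
                "hpv_status": r.hpv_status,
                "compartment": r.compartment,
                "intensity": r.intensity,
                "percent_positive": r.percent_positive,
                "percent_category": r.percent_category,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Exact tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyTestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value sums hypergeometric probabilities of all
    tables (with the observed margins) no more probable than the
    observed one. A zero margin carries no information: p = 1 with a
    warning. The reported statistic is the sample odds ratio.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a nonnegative 2x2 integer table")
    if table.sum() == 0:
        raise ValueError("table total must be positive")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1", UserWarning, stacklevel=2)
        return ContingencyTestResult(
            table=table, statistic=float("nan"), df=1, p_value=1.0,
            method="fisher_exact",
        )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ContingencyTestResult(
        table=table, statistic=float(odds), df=1, p_value=float(p),
        method="fisher_exact",
    )


def fisher_exact_2xk(
    table: Sequence[Sequence[int]],
    max_tables: int = 2_000_000,
    n_monte_carlo: int = 200_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, str]:
    """Two-sided Fisher test on a 2xk table by exhaustive enumeration.

    Conditions on both margins; enumerates every 2xk table with those
    margins and sums the multivariate hypergeometric probabilities of
    tables no more probable than the observed one. Above ``max_tables``
    candidate tables, falls back to Monte-Carlo sampling of the null
    (the returned method string flags the fallback).

    Returns (p_value, method) with method in
    {"fisher_exact_enumeration", "fisher_monte_carlo"}.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or (table < 0).any():
        raise ValueError("expected a nonnegative 2xk integer table")
    col_totals = table.sum(axis=0)
    keep = col_totals > 0
    table = table[:, keep]
    col_totals = col_totals[keep]
    k = table.shape[1]
    r1 = int(table[0].sum())
    n = int(table.sum())
    if n == 0 or r1 == 0 or r1 == n or k < 2:
        return 1.0, "fisher_exact_enumeration"

    log_denom = _log_comb(n, r1)

    def log_prob(row: np.ndarray) -> float:
        return sum(_log_comb(int(c), int(a)) for c, a in zip(col_totals, row)) - log_denom

    # Count candidate tables (product of per-column ranges bounds the count).
    bound = 1
    for c in col_totals:
        bound *= int(c) + 1
        if bound > max_tables:
            break

    obs_lp = log_prob(table[0])
    tol = 1e-9
    if bound <= max_tables:
        # depth-first over row-1 cell values a_0..a_{k-1} summing to r1
        def recurse(j: int, remaining: int, acc_lp: float) -> float:
            if j == k - 1:
                if remaining > col_totals[j]:
                    return 0.0
                lp = acc_lp + _log_comb(int(col_totals[j]), remaining) - log_denom
                return math.exp(lp) if lp <= obs_lp + tol else 0.0
            lo = max(0, remaining - int(col_totals[j + 1:].sum()))
            hi = min(int(col_totals[j]), remaining)
            s = 0.0
            for a in range(lo, hi + 1):
                s += recurse(j + 1, remaining - a,
                             acc_lp + _log_comb(int(col_totals[j]), a))
            return s

        total = recurse(0, r1, 0.0)
        return min(1.0, total), "fisher_exact_enumeration"

    # Monte-Carlo fallback: sample row-1 allocations from the null.
    rng = rng if rng is not None else np.random.default_rng(0)
    hits = 0
    for _ in range(n_monte_carlo):
        draw = rng.multivariate_hypergeometric(col_totals, r1)
        if log_prob(np.asarray(draw)) <= obs_lp + tol:
            hits += 1
    p = (hits + 1) / (n_monte_carlo + 1)
    return min(1.0, p), "fisher_monte_carlo"


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples are small
    (n <= 25 each) and tie-free; otherwise a normal approximation with
    tie correction and a continuity correction applied toward the null
    mean (so identical samples give exactly p = 1). Returns the
    Mann-Whitney U statistic for x and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and x.size <= 25 and y.size <= 25:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)

    n1, n2 = x.size, y.size
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0 or u == mu:
        return float(u), 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    return float(u), float(min(1.0, p))


# ---------------------------------------------------------------------------
# IHC compartment comparison


def ihc_compartment_compare(
    records: Iterable[IHCRecord], marker: str, paired: bool = False
) -> tuple[float, float]:
    """Membrane vs nuclear percent-positive for one marker.

    Default is an unpaired two-sided Wilcoxon rank-sum on
    percent_positive across samples. ``paired=True`` instead runs a
    signed-rank test pairing compartments within each sample.
    """
    recs = [r for r in records if r.marker == marker]
    if not recs:
        raise ValueError(f"no IHC records for marker {marker!r}")
    membrane = [r for r in recs if r.compartment == "membrane"]
    nuclear = [r for r in recs if r.compartment == "nuclear"]
    if len(membrane) < 2 or len(nuclear) < 2:
        raise ValueError("need >=2 records per compartment")
    if not paired:
        return wilcoxon_rank_sum(
            [r.percent_positive for r in membrane],
            [r.percent_positive for r in nuclear],
        )
    mem = {r.sample_id: r.percent_positive for r in membrane}
    nuc = {r.sample_id: r.percent_positive for r in nuclear}
    shared = sorted(set(mem) & set(nuc))
    if len(shared) < 2:
        raise ValueError("paired comparison needs >=2 samples with both compartments")
    diffs = np.array([mem[s] - nuc[s] for s in shared])
    if np.all(diffs == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diffs, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class GroupSurvival:
    label: str
    n: int
    events: int
    median_os: Optional[float]  # None = never crosses 0.5 ("not reached")
    curve: pd.DataFrame = field(repr=False)  # columns: time, survival


@dataclass(frozen=True)
class SurvivalComparison:
    groups: tuple[GroupSurvival, ...]
    logrank_statistic: float
    logrank_p: float

    def group(self, label: str) -> GroupSurvival:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def dichotomize_by_median(expression: pd.Series) -> pd.Series:
    """Split patients into 'high' (> median) and 'low' (<= median).

    Values tied with the median go to 'low'. All-equal expression
    admits no split and raises.
    """
    expression = expression.astype(float)
    if expression.size < 2:
        raise ValueError("need at least two patients to dichotomize")
    med = float(expression.median())
    if float(expression.max()) == float(expression.min()):
        raise ValueError("expression is constant; no median split possible")
    labels = pd.Series(
        np.where(expression > med, "high", "low"), index=expression.index
    )
    return labels


def km_logrank(
    records: Iterable[ClinicalRecord],
    groups: Mapping[str, str],
) -> SurvivalComparison:
    """Kaplan-Meier curves per group with a two-sided log-rank test.

    ``groups`` maps patient_id to a group label (e.g. "high"/"low").
    Median OS per group is the earliest time at which the product-limit
    estimate drops to 0.5 or below; ``None`` when the curve never does
    ("not reached"). The log-rank chi-squared has 1 df for two groups.
    """
    recs = [r for r in records if r.patient_id in groups]
    labels = sorted({groups[r.patient_id] for r in recs})
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")

    summaries = []
    arrays = {}
    for label in labels:
        sub = [r for r in recs if groups[r.patient_id] == label]
        times = np.array([r.os_months for r in sub], dtype=float)
        events = np.array([r.os_event for r in sub], dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events, label=label)
        median = qth_survival_time(0.5, kmf.survival_function_)
        median_os = None if not np.isfinite(median) else float(median)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        summaries.append(
            GroupSurvival(
                label=label,
                n=len(sub),
                events=int(events.sum()),
                median_os=median_os,
                curve=curve,
            )
        )
        arrays[label] = (times, events)

    (t_a, e_a), (t_b, e_b) = arrays[labels[0]], arrays[labels[1]]
    res = _lifelines_logrank(t_a, t_b, event_observed_A=e_a, event_observed_B=e_b)
    return SurvivalComparison(
        groups=tuple(summaries),
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# Cohort table


def cohort_table(
    records: Sequence[ClinicalRecord],
    continuous: Sequence[str] = ("age_years",),
    categorical: Sequence[str] = ("histology", "lvi", "p16", "pT", "pN"),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cohort characteristics by HPV status with per-variable tests.

    Continuous variables are summarized as median (IQR) per group and
    compared with the Wilcoxon rank-sum test; categorical variables as
    n (%) per level with an exact Fisher test on the 2xk cross-tab
    (Monte-Carlo fallback above enumeration limits, flagged in the
    ``test`` column). Returns one row per variable level with the test
    result attached to the variable's first row.
    """
    frame = clinical_to_frame(records)
    neg = frame[frame["hpv_status"] == "neg"]
    pos = frame[frame["hpv_status"] == "pos"]
    rows: list[dict[str, object]] = []

    for var in continuous:
        xv, yv = neg[var].dropna(), pos[var].dropna()
        if xv.nunique() <= 1 and yv.nunique() <= 1 and set(xv) == set(yv):
            p, test = 1.0, "wilcoxon_rank_sum"
        else:
            _, p = wilcoxon_rank_sum(xv.to_numpy(), yv.to_numpy())
            test = "wilcoxon_rank_sum"
        rows.append(
            {
                "variable": var,
                "level": "",
                "hpv_neg": _median_iqr(xv),
                "hpv_pos": _median_iqr(yv),
                "p": p,
                "test": test,
            }
        )

    for var in categorical:
        levels = sorted(frame[var].astype(str).unique())
        counts = np.array(
            [
                [int((neg[var].astype(str) == lv).sum()) for lv in levels],
                [int((pos[var].astype(str) == lv).sum()) for lv in levels],
            ]
        )
        p, method = fisher_exact_2xk(counts, rng=rng)
        for i, lv in enumerate(levels):
            rows.append(
                {
                    "variable": var,
                    "level": lv,
                    "hpv_neg": _n_percent(counts[0, i], len(neg)),
                    "hpv_pos": _n_percent(counts[1, i], len(pos)),
                    "p": p if i == 0 else np.nan,
                    "test": method if i == 0 else "",
                }
            )
    return pd.DataFrame(
        rows, columns=["variable", "level", "hpv_neg", "hpv_pos", "p", "test"]
    )


def _median_iqr(values: pd.Series) -> str:
    if values.empty:
        return "NA"
    q1, med, q3 = values.quantile([0.25, 0.5, 0.75])
    return f"{med:g} ({q1:g}, {q3:g})"


def _n_percent(count: int, total: int) -> str:
    pct = 100.0 * count / total if total else 0.0
    return f"{count} ({pct:.0f}%)"
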