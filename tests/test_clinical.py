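import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from surfaceomics import (
    ClinicalRecord,
    IHCRecord,
    cohort_table,
    dichotomize_by_median,
    fisher_exact_2x2,
    fisher_exact_2xk,
    ihc_compartment_compare,
    km_logrank,
    wilcoxon_rank_sum,
)
from surfaceomics.clinical import percent_category


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p_k = hypergeom.pmf(k, n, c1, r1)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(1.0, total)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_random_small_tables_match_enumeration_oracle(self, rng):
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            res = fisher_exact_2x2(table)
            assert res.p_value == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0

    def test_two_sided_bounds(self, rng):
        table = [[7, 2], [1, 8]]
        res = fisher_exact_2x2(table)
        _, one_sided = stats.fisher_exact(table, alternative="less")
        one_sided = min(one_sided, stats.fisher_exact(table, alternative="greater")[1])
        assert one_sided <= res.p_value <= 1.0


class TestFisher2xk:
    def test_reduces_to_2x2(self, rng):
        for _ in range(10):
            table = rng.integers(1, 10, size=(2, 2))
            p, method = fisher_exact_2xk(table)
            assert method == "fisher_exact_enumeration"
            assert p == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)

    def test_2x3_matches_r_style_enumeration(self):
        # small 2x3 table; oracle: direct enumeration over the free cells
        table = np.array([[3, 1, 4], [2, 5, 0]])
        p, _ = fisher_exact_2xk(table)
        col = table.sum(axis=0)
        r1 = table[0].sum()
        n = table.sum()
        denom = math.comb(n, r1)
        p_obs = math.prod(math.comb(c, a) for c, a in zip(col, table[0])) / denom
        total = 0.0
        for a0 in range(col[0] + 1):
            for a1 in range(col[1] + 1):
                a2 = r1 - a0 - a1
                if 0 <= a2 <= col[2]:
                    pk = (
                        math.comb(col[0], a0)
                        * math.comb(col[1], a1)
                        * math.comb(col[2], a2)
                    ) / denom
                    if pk <= p_obs * (1 + 1e-7):
                        total += pk
        assert p == pytest.approx(total, rel=1e-9)

    def test_monte_carlo_fallback_flagged(self, rng):
        table = rng.integers(20, 60, size=(2, 8))
        p, method = fisher_exact_2xk(
            table, max_tables=10, n_monte_carlo=2000, rng=rng
        )
        assert method == "fisher_monte_carlo"
        assert 0 < p <= 1


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_maximal_separation_exact(self):
        # all 10 orderings of ranks: only 2 of 20 signed arrangements as extreme
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert p == pytest.approx(0.1)

    def test_untied_5v5_matches_permutation_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(loc=1.0, size=5)
        u_obs, p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = 5 * 5 / 2
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            u = ranks[list(idx)].sum() - 5 * 6 / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)

    def test_tied_large_sample_uses_corrected_normal(self, rng):
        x = np.repeat([1.0, 2.0, 3.0], 10)
        y = np.repeat([2.0, 3.0, 4.0], 10)
        _, p = wilcoxon_rank_sum(x, y)
        assert 0 < p < 0.05  # clear shift, ties handled


class TestIHC:
    @staticmethod
    def records(membrane, nuclear, marker="CD147"):
        recs = []
        for i, v in enumerate(membrane):
            recs.append(
                IHCRecord(f"s{i}", marker, "neg", "membrane", 3, float(v))
            )
        for i, v in enumerate(nuclear):
            recs.append(
                IHCRecord(f"s{i}", marker, "neg", "nuclear", 1, float(v))
            )
        return recs

    def test_maximal_separation_significant(self):
        recs = self.records([90] * 6, [5] * 6)
        _, p = ihc_compartment_compare(recs, "CD147")
        assert p < 0.01

    def test_identical_distributions_p_one(self):
        recs = self.records([50, 60, 70], [50, 60, 70])
        _, p = ihc_compartment_compare(recs, "CD147")
        assert p == 1.0

    def test_missing_marker_rejected(self):
        recs = self.records([90] * 3, [5] * 3)
        with pytest.raises(ValueError, match="FGFR1"):
            ihc_compartment_compare(recs, "FGFR1")

    def test_planted_membrane_excess_power(self):
        # synthetic cohorts with a planted membrane excess: significant
        # in >90% of replicates
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            mem = np.clip(rng.normal(80, 10, size=6), 0, 100)
            nuc = np.clip(rng.normal(20, 10, size=6), 0, 100)
            _, p = ihc_compartment_compare(self.records(mem, nuc), "CD147")
            hits += p < 0.05
        assert hits / reps > 0.9

    def test_paired_variant(self):
        recs = self.records([90, 85, 95, 88], [10, 12, 9, 11])
        _, p = ihc_compartment_compare(recs, "CD147", paired=True)
        assert p < 0.2  # n=4 pairs; smallest attainable two-sided p is 0.125

    @pytest.mark.parametrize(
        "percent,category", [(0.0, 1), (25.0, 1), (30.0, 2), (60.0, 2), (61.0, 3), (100.0, 3)]
    )
    def test_percent_category_bins(self, percent, category):
        assert percent_category(percent) == category


class TestDichotomize:
    def test_even_split(self):
        labels = dichotomize_by_median(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        )
        assert set(labels[labels == "low"].index) == {"a", "b"}
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_odd_n_median_goes_low(self):
        labels = dichotomize_by_median(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert list(labels) == ["low", "low", "high"]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize_by_median(pd.Series([2.0, 2.0, 2.0]))

    def test_random_vector_matches_midpoint_oracle(self, rng):
        x = pd.Series(rng.normal(size=31))
        labels = dichotomize_by_median(x)
        med = np.median(x.to_numpy())
        for i, v in x.items():
            assert labels[i] == ("high" if v > med else "low")
        assert (labels == "high").any() and (labels == "low").any()


def make_records(times, events, prefix="p"):
    return [
        ClinicalRecord(
            patient_id=f"{prefix}{i}",
            hpv_status="neg",
            os_months=float(t),
            os_event=bool(e),
        )
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKmLogrank:
    def test_identical_groups_null_logrank(self):
        recs = make_records([5, 10, 15, 20], [1, 1, 1, 1], "a") + make_records(
            [5, 10, 15, 20], [1, 1, 1, 1], "b"
        )
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        cmp = km_logrank(recs, groups)
        assert cmp.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.logrank_p == pytest.approx(1.0)

    def test_toy_uncensored_km_matches_hand_step_function(self):
        # group a: deaths at 2, 4 -> S = 1, .5, 0; median = 4 (first t with S<=.5 is 2? no: S(2)=.5 -> median 2)
        recs = make_records([2, 4], [1, 1], "a") + make_records([1, 3], [1, 1], "b")
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        cmp = km_logrank(recs, groups)
        a = cmp.group("a")
        curve = dict(zip(a.curve["time"], a.curve["survival"]))
        assert curve[2.0] == pytest.approx(0.5)
        assert curve[4.0] == pytest.approx(0.0)
        assert a.median_os == 2.0  # earliest time S(t) <= 0.5

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(20, size=12).round(1)
        recs = make_records(times, [1] * 12, "a") + make_records(
            rng.exponential(20, size=12).round(1), [1] * 12, "b"
        )
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        cmp = km_logrank(recs, groups)
        a = cmp.group("a")
        for t, s in zip(a.curve["time"], a.curve["survival"]):
            assert s == pytest.approx(np.mean(times > t))

    def test_label_swap_invariance(self, rng):
        recs = make_records(rng.exponential(30, 9), rng.random(9) < 0.8, "a")
        recs += make_records(rng.exponential(10, 9), rng.random(9) < 0.8, "b")
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        swapped = {k: ("a" if v == "b" else "b") for k, v in groups.items()}
        c1, c2 = km_logrank(recs, groups), km_logrank(recs, swapped)
        assert c1.logrank_statistic == pytest.approx(c2.logrank_statistic)
        assert c1.logrank_p == pytest.approx(c2.logrank_p)

    def test_zero_event_group_median_not_reached(self):
        recs = make_records([10, 20, 30], [0, 0, 0], "a") + make_records(
            [5, 10, 15], [1, 1, 1], "b"
        )
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        cmp = km_logrank(recs, groups)
        assert cmp.group("a").median_os is None
        assert math.isfinite(cmp.logrank_p)

    def test_hazard_ratio_four_power(self):
        # exponential survival, HR 4, n = 9 vs 9: rejection rate at the
        # 0.05 level exceeds 60% over 500 replicates
        rng = np.random.default_rng(8)
        reps, hits = 500, 0
        for _ in range(reps):
            t_low = rng.exponential(40, size=9)
            t_high = rng.exponential(10, size=9)
            recs = make_records(t_low, [1] * 9, "a") + make_records(
                t_high, [1] * 9, "b"
            )
            groups = {r.patient_id: r.patient_id[0] for r in recs}
            hits += km_logrank(recs, groups).logrank_p < 0.05
        assert hits / reps > 0.6


class TestCohortTable:
    @staticmethod
    def cohort(rng):
        recs = []
        for i in range(18):
            status = "neg" if i < 8 else "pos"
            recs.append(
                ClinicalRecord(
                    patient_id=f"p{i}",
                    hpv_status=status,
                    p16="Positive" if status == "pos" else "Negative",
                    histology=["Usual", "Basaloid"][i % 2],
                    lvi=bool(i % 3),
                    pT=1 + i % 3,
                    pN=i % 4,
                    age_years=50.0 + i,
                    os_months=float(10 + i),
                    os_event=bool(i % 2),
                )
            )
        return recs

    def test_row_counts_cover_cohort(self, rng):
        table = cohort_table(self.cohort(rng), rng=rng)
        age = table[table["variable"] == "age_years"]
        assert len(age) == 1
        p16 = table[table["variable"] == "p16"]
        neg_total = sum(int(v.split(" ")[0]) for v in p16["hpv_neg"])
        pos_total = sum(int(v.split(" ")[0]) for v in p16["hpv_pos"])
        assert neg_total + pos_total == 18

    def test_identical_age_distributions_p_one(self, rng):
        recs = [
            ClinicalRecord(
                patient_id=f"p{i}{g}",
                hpv_status=g,
                age_years=float(40 + i),
                os_months=1.0,
            )
            for g in ("neg", "pos")
            for i in range(5)
        ]
        table = cohort_table(recs, categorical=(), rng=rng)
        assert table.loc[table["variable"] == "age_years", "p"].iloc[0] == 1.0

    def test_perfectly_associated_p16_significant(self, rng):
        table = cohort_table(self.cohort(rng), rng=rng)
        p = table.loc[table["variable"] == "p16", "p"].iloc[0]
        assert p < 0.001
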