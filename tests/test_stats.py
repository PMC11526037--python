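import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fci.stats import (
    biomarker_report,
    exact_mw_p,
    exact_wilcoxon_p,
    mann_whitney,
    mann_whitney_u_counts,
    median_iqr,
    mw_z,
    signed_rank_counts,
    wilcoxon_signed_rank,
    wilcoxon_z,
)

# data realising specific U statistics for n = (4, 6)
GROUPS_U2 = ([1, 2, 3, 6], [4, 5, 7, 8, 9, 10])
GROUPS_U0 = ([1, 2, 3, 4], [5, 6, 7, 8, 9, 10])
GROUPS_U3 = ([1, 2, 3, 7], [4, 5, 6, 8, 9, 10])
GROUPS_U5 = ([1, 2, 4, 8], [3, 5, 6, 7, 9, 10])


def brute_force_u_counts(n1, n2):
    """Oracle: explicit enumeration of all C(n1+n2, n1) rank assignments."""
    counts = {}
    for idx in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(idx) - n1 * (n1 + 1) // 2
        counts[u] = counts.get(u, 0) + 1
    return counts


def brute_force_wilcoxon_counts(n):
    """Oracle: explicit enumeration of all 2^n sign patterns."""
    counts = {}
    for signs in itertools.product((0, 1), repeat=n):
        w = sum((i + 1) for i, s in enumerate(signs) if s)
        counts[w] = counts.get(w, 0) + 1
    return counts


class TestMannWhitney:
    def test_u2_printed_statistics(self):
        cmp = mann_whitney(*GROUPS_U2)
        assert cmp.statistic == 2
        assert cmp.p_exact == pytest.approx(8 / 210)
        assert round(cmp.p_exact, 3) == 0.038
        assert cmp.z == pytest.approx(-2.132, abs=5e-4)
        assert round(cmp.z, 1) == -2.1
        assert cmp.effect_size_r == pytest.approx(0.674, abs=5e-4)

    def test_complete_separation(self):
        cmp = mann_whitney(*GROUPS_U0)
        assert cmp.statistic == 0
        assert cmp.p_exact == pytest.approx(2 / 210)

    def test_u3_and_u5(self):
        c3 = mann_whitney(*GROUPS_U3)
        assert c3.statistic == 3
        assert round(c3.p_exact, 3) == 0.067
        c5 = mann_whitney(*GROUPS_U5)
        assert c5.statistic == 5
        assert round(c5.p_exact, 3) == 0.171
        assert round(c5.effect_size_r, 3) == 0.472

    def test_identical_groups_degenerate(self):
        cmp = mann_whitney([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert cmp.p_exact == 1.0 and cmp.p_normal == 1.0
        assert cmp.z == 0.0 and cmp.effect_size_r == 0.0
        assert cmp.statistic == pytest.approx(4.5)  # n1*n2/2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (4, 6), (5, 5)])
    def test_dp_counts_equal_enumeration(self, n1, n2):
        counts = mann_whitney_u_counts(n1, n2)
        oracle = brute_force_u_counts(n1, n2)
        for u in range(n1 * n2 + 1):
            assert counts[u] == oracle.get(u, 0)

    def test_monotone_transform_invariance(self):
        a, b = [0.3, 1.2, 2.9, 5.5], [0.7, 1.8, 3.3, 4.4, 6.0, 7.1]
        base = mann_whitney(a, b)
        for f in (np.exp, np.log1p, lambda x: np.asarray(x) ** 3):
            cmp = mann_whitney(f(a), f(b))
            assert cmp.statistic == base.statistic
            assert cmp.p_exact == base.p_exact

    def test_group_swap_symmetry(self):
        a, b = [1.0, 4.0, 9.0, 11.0], [2.0, 3.0, 5.0, 6.0, 7.0, 8.0]
        assert mann_whitney(a, b).p_exact == mann_whitney(b, a).p_exact
        assert mann_whitney(a, b).statistic == mann_whitney(b, a).statistic

    def test_ties_use_midranks_and_corrected_variance(self):
        cmp = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert np.isfinite(cmp.z)
        assert 0 < cmp.p_exact <= 1
        # tie-corrected |z| exceeds the uncorrected value (smaller variance)
        assert abs(cmp.z) >= abs(mw_z(cmp.statistic, 3, 3))

    def test_tail_mass_convention_available(self):
        assert exact_mw_p(2, 4, 6, two_sided="tail_mass") <= 1.0
        # doubled lower tail is at least as large as the exact tail mass
        assert exact_mw_p(2, 4, 6, "double") >= exact_mw_p(2, 4, 6, "tail_mass") - 1e-12

    def test_type_one_error_conservative_under_null(self):
        # exact test at nominal 0.05 rejects at most 5% of null datasets
        rng = np.random.default_rng(0)
        n1, n2 = 4, 6
        counts = mann_whitney_u_counts(n1, n2)
        total = comb(n1 + n2, n1)
        cdf = np.cumsum([float(c) for c in counts]) / total
        rejections = 0
        n_rep = 10_000
        for _ in range(n_rep):
            pooled = rng.standard_normal(n1 + n2)
            ranks = pooled.argsort().argsort() + 1
            u_a = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            u = int(min(u_a, n1 * n2 - u_a))
            p = min(1.0, 2 * cdf[u])
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.05


class TestWilcoxon:
    def test_w1_n10_printed_statistics(self):
        assert wilcoxon_z(1, 10) == pytest.approx(-2.701, abs=5e-4)
        a = np.arange(1, 11, dtype=float)
        b = a + np.arange(1, 11)  # all negative diffs except we flip rank-1
        b[0] = a[0] - 0.5  # the smallest |difference| is positive -> W = 1
        cmp = wilcoxon_signed_rank(a, b)
        assert cmp.statistic == 1
        assert round(cmp.p_normal, 3) == 0.007

    def test_w0_n10_printed_statistics(self):
        a = np.arange(1, 11, dtype=float)
        cmp = wilcoxon_signed_rank(a, a + np.arange(1, 11))
        assert cmp.statistic == 0
        assert cmp.z == pytest.approx(-2.803, abs=5e-4)
        assert round(cmp.p_normal, 3) == 0.005
        assert cmp.p_exact == pytest.approx(2 / 1024)

    def test_w0_n9_printed_statistics(self):
        a = np.arange(1.0, 10.0)
        cmp = wilcoxon_signed_rank(a, a + np.arange(1, 10))
        assert cmp.z == pytest.approx(-2.666, abs=5e-4)
        assert round(cmp.p_normal, 3) == 0.008

    def test_identical_pairs_degenerate(self):
        a = [1.0, 2.0, 3.0]
        cmp = wilcoxon_signed_rank(a, a)
        assert cmp.p_exact == 1.0 and cmp.p_normal == 1.0

    def test_zero_differences_dropped(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 2.0, 4.0, 6.0, 9.0]  # two zero diffs
        cmp = wilcoxon_signed_rank(a, b)
        assert cmp.n1 == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_dp_counts_equal_enumeration(self, n):
        counts, total = signed_rank_counts(range(1, n + 1))
        oracle = brute_force_wilcoxon_counts(n)
        assert total == 2**n
        for w in range(n * (n + 1) // 2 + 1):
            assert counts[2 * w] == oracle.get(w, 0)

    def test_exact_p_equals_enumeration(self):
        n = 10
        oracle = brute_force_wilcoxon_counts(n)
        smax = n * (n + 1) // 2
        for w_obs in (0, 1, 5, 11):
            direct = exact_wilcoxon_p(w_obs, list(range(1, n + 1)))
            hits = sum(c for w, c in oracle.items() if min(w, smax - w) <= w_obs)
            assert direct == pytest.approx(hits / 2**n)


class TestMedianIqr:
    def test_three_values(self):
        assert median_iqr([1, 2, 3]) == pytest.approx((2.0, 1.5, 2.5))

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_midpoint_median(self):
        med, _, _ = median_iqr([0.03, 0.04, 0.06, 0.09])
        assert med == pytest.approx(0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


def tidy(rows):
    return pd.DataFrame(rows, columns=["subject_id", "roi_role", "biomarker", "value"])


class TestBiomarkerReport:
    def test_identical_classes_all_p_one(self):
        rows = []
        for i in range(4):
            rows.append((f"S{i}", "tumour", "beta", 0.1))
            rows.append((f"S{i}", "adipose", "beta", 0.1))
        report = biomarker_report(tidy(rows))
        assert (report.p_exact == 1.0).all()
        assert (report.p_normal == 1.0).all()

    def test_separated_beta_cohort_significant(self):
        rng = np.random.default_rng(2)
        rows = []
        grouping = {}
        for i in range(4):
            rows.append((f"I{i}", "tumour", "beta", 0.05 + 0.005 * rng.standard_normal()))
            grouping[f"I{i}"] = True
        for i in range(6):
            rows.append((f"N{i}", "tumour", "beta", 0.19 + 0.005 * rng.standard_normal()))
            grouping[f"N{i}"] = False
        report = biomarker_report(tidy(rows), invasive_by_subject=grouping)
        row = report[report.comparison == "invasive_vs_noninvasive"].iloc[0]
        assert row.p_exact <= 0.05

    def test_missing_roi_reduces_pairs(self):
        rows = []
        for i in range(5):
            rows.append((f"S{i}", "tumour", "r1", 6.8 + 0.1 * i))
            if i != 2:  # one subject has no glandular ROI
                rows.append((f"S{i}", "glandular", "r1", 8.1 + 0.1 * i))
        report = biomarker_report(tidy(rows))
        row = report[report.comparison == "tumour_vs_glandular"].iloc[0]
        assert row.n == 4

    def test_small_class_skipped_with_warning(self):
        rows = [("S0", "tumour", "beta", 0.1), ("S1", "tumour", "beta", 0.2)]
        grouping = {"S0": True, "S1": False}
        with pytest.warns(UserWarning, match="skipped"):
            report = biomarker_report(tidy(rows), invasive_by_subject=grouping)
        assert report.empty
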