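"""Nonparametric tests, correlation banding, ROC and summaries."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from igscore.stats import (
    BAND_MODERATE,
    BAND_SLIGHT,
    BAND_STRONG,
    BAND_VERY_STRONG,
    DomainError,
    UndefinedCorrelationError,
    band_strength,
    compare_groups,
    correlation_matrix,
    fisher_exact_2x2,
    mann_whitney_u,
    pg_ratio,
    roc,
    select_cutoff,
    significance_stars,
    spearman,
    summarize_group,
)


def mann_whitney_enumeration(x, y):
    """Full enumeration of all C(n+m, n) rank assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties: plain ranks
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        us.append(ranks[list(combo)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    m_u = len(x) * len(y) / 2
    p = np.mean(np.abs(us - m_u) >= abs(u_obs - m_u) - 1e-12)
    return u_obs, p


def fisher_enumeration(table):
    """Two-sided p by summing hypergeometric masses <= observed (fixed margins)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    def mass(aa):
        return (
            math.comb(r1, aa) * math.comb(r2, c1 - aa) / math.comb(n, c1)
        )
    p_obs = mass(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        m = mass(aa)
        if m <= p_obs * (1 + 1e-7):
            total += m
    return min(total, 1.0)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_constant_samples(self):
        _, p = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 5), (5, 5)])
    def test_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x, y = rng.normal(size=nx), rng.normal(size=ny) + 0.5
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = mann_whitney_enumeration(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_fixture_ig_totals_strongly_separated(self, cohort):
        healthy = [p.ig_total for p in cohort if p.group == "healthy"]
        perio = [p.ig_total for p in cohort if p.group == "periodontitis"]
        _, p = mann_whitney_u(healthy, perio)
        assert p < 0.001


class TestFisherExact:
    def test_gender_table_not_significant(self):
        orat, p = fisher_exact_2x2([[9, 2], [4, 7]])
        assert p > 0.05
        assert p == pytest.approx(0.0805, abs=5e-5)

    def test_balanced_table(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact_2x2([[0, 0], [1, 2]])

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_enumeration(t), rel=1e-7, abs=1e-12)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.5, 1.0, 2.0, 3.5, 4.0])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_worked_rank_example(self):
        # d² = (0,1,1,1,1): rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestBands:
    @pytest.mark.parametrize(
        "rho,band",
        [(0.76, BAND_STRONG), (0.39, BAND_SLIGHT), (-0.85, BAND_VERY_STRONG),
         (0.4, BAND_MODERATE), (0.6, BAND_STRONG), (0.8, BAND_VERY_STRONG),
         (0.0, BAND_SLIGHT), (-0.5, BAND_MODERATE)],
    )
    def test_banding_on_absolute_value(self, rho, band):
        assert band_strength(rho) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            band_strength(1.5)

    def test_stars(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-6) == "****"


class TestCorrelationMatrix:
    def test_duplicated_variable_is_very_strong(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 2, 3, 4, 5]})
        (entry,) = correlation_matrix(df, ["x", "y"])
        assert entry.rho == pytest.approx(1.0)
        assert entry.band == BAND_VERY_STRONG

    def test_constant_column_flagged_not_computable(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "k": [7.0, 7, 7, 7]})
        (entry,) = correlation_matrix(df, ["x", "k"])
        assert not entry.computable and entry.rho is None

    def test_fixture_pg_ratio_correlates_with_ig_total(self, cohort):
        df = pd.DataFrame(
            {
                "pg_ratio": [
                    pg_ratio(p.pg_amount, p.total_bacteria) for p in cohort
                ],
                "ig_total": [p.ig_total for p in cohort],
            }
        )
        (entry,) = correlation_matrix(df, ["pg_ratio", "ig_total"])
        assert entry.rho > 0
        assert entry.p < 0.05

    def test_bh_correction_only_inflates_p(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        raw = correlation_matrix(df, list("abcd"))
        adj = correlation_matrix(df, list("abcd"), bh_correction=True)
        for e_raw, e_adj in zip(raw, adj):
            assert e_adj.p >= e_raw.p - 1e-12


def brute_force_confusion(scores, labels, cutoff):
    scores, labels = np.asarray(scores), np.asarray(labels)
    tp = ((scores >= cutoff) & (labels == 1)).sum()
    fn = ((scores < cutoff) & (labels == 1)).sum()
    tn = ((scores < cutoff) & (labels == 0)).sum()
    fp = ((scores >= cutoff) & (labels == 0)).sum()
    return tp / (tp + fn), tn / (tn + fp)


class TestROC:
    def test_perfect_separation(self):
        res = roc([0, 10], [0, 1])
        assert res.auc == pytest.approx(1.0)

    def test_identical_distributions_auc_half(self):
        res = roc([1, 5, 9, 1, 5, 9], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(0.5)

    def test_sens_spec_match_brute_force_each_cutoff(self):
        scores = [0, 1, 2, 5, 3, 6, 9, 10]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        res = roc(scores, labels)
        for i, c in enumerate(res.thresholds):
            sens, spec = brute_force_confusion(scores, labels, c)
            assert res.sensitivity[i] == pytest.approx(sens)
            assert res.specificity[i] == pytest.approx(spec)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc([1, 2], [1, 1])

    @given(
        st.lists(st.integers(0, 15), min_size=2, max_size=30),
        st.data(),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotonicity_and_auc_bounds(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        res = roc(scores, labels)
        assert (np.diff(res.sensitivity) <= 1e-12).all()
        assert (np.diff(res.specificity) >= -1e-12).all()
        assert 0.0 <= res.auc <= 1.0


class TestSelectCutoff:
    def test_separated_band_selects_smallest(self):
        # healthy <= 3, periodontitis >= 6: J maximal on {4, 5, 6}
        res = roc([0, 1, 2, 3, 6, 7, 9, 12], [0, 0, 0, 0, 1, 1, 1, 1])
        j = res.youden()
        assert set(res.thresholds[np.isclose(j, j.max())]) == {4, 5, 6}
        assert select_cutoff(res) == 4

    def test_tied_optima_take_smallest(self):
        res = roc([0, 1, 2, 5, 3, 6, 9, 10], [0, 0, 0, 0, 1, 1, 1, 1])
        assert select_cutoff(res) == 3

    def test_single_optimum(self):
        res = roc([0, 0, 5, 5], [0, 0, 1, 1])
        assert select_cutoff(res) == 1

    def test_invariant_under_cohort_duplication(self):
        scores = [0, 1, 2, 5, 3, 6, 9, 10]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        once = select_cutoff(roc(scores, labels))
        thrice = select_cutoff(roc(scores * 3, labels * 3))
        assert once == thrice


class TestRatioAndSummary:
    @pytest.mark.parametrize(
        "pg,total,expected", [(0.0, 6.93, 0.0), (5.0, 20.0, 25.0), (3.3, 11.98, 27.5)]
    )
    def test_ratio_percent(self, pg, total, expected):
        assert pg_ratio(pg, total) == pytest.approx(expected, abs=0.05)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            pg_ratio(1.0, 0.0)

    def test_symmetric_set_format(self):
        assert summarize_group([1, 2, 3, 4, 5]).format() == "3 (2–4)–3"

    def test_single_value_format(self):
        assert summarize_group([7]).format() == "7 (7–7)–7"

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize_group([])

    def test_fixture_periodontitis_median_near_target(self, small_config, cohort):
        perio = [p.ig_total for p in cohort if p.group == "periodontitis"]
        target = small_config.ig_median_target["periodontitis"]
        assert abs(summarize_group(perio).median - target) <= 2


class TestCompareGroups:
    def test_table1_style_comparison(self, cohort):
        from igscore.synthetic import cohort_to_frame

        df = cohort_to_frame(cohort)
        df["is_female"] = df["gender"] == "F"
        comps = compare_groups(
            df, quantitative=["age", "ppd_mm"], qualitative=["is_female", "smoker"]
        )
        by_var = {c.variable: c for c in comps}
        assert by_var["age"].p < 0.001
        assert by_var["ppd_mm"].p < 0.001
        assert by_var["age"].test == "mann-whitney"
        assert by_var["is_female"].test == "fisher"
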