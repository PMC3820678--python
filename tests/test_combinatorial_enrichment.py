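import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combichip.combinatorial_enrichment import (
    all_pattern_labels,
    assign_patterns,
    benjamini_hochberg,
    chi_square_gof,
    enrichment_ratio,
    euler_counts,
    expected_fraction,
    group_enrichment_table,
    group_status_fraction,
    pattern_label,
    percentile_summary,
    two_sample_ttest,
)

FACTORS = ("CREB", "CEBPB", "CJUN")


def _bound(rows):
    return pd.DataFrame(rows, columns=FACTORS)


class TestAssignPatterns:
    def test_two_bound(self):
        df = _bound({"p1": [True, True, False]}).T if False else pd.DataFrame(
            {"CREB": [True], "CEBPB": [True], "CJUN": [False]}, index=["p1"]
        )
        assert assign_patterns(df, FACTORS)["p1"] == "CREB+CEBPB"

    def test_none_bound(self):
        df = pd.DataFrame({"CREB": [False], "CEBPB": [False], "CJUN": [False]}, index=["p1"])
        assert assign_patterns(df, FACTORS)["p1"] == "none"

    def test_all_bound(self):
        df = pd.DataFrame({"CREB": [True], "CEBPB": [True], "CJUN": [True]}, index=["p1"])
        assert assign_patterns(df, FACTORS)["p1"] == "CREB+CEBPB+CJUN"

    def test_missing_call_drops_promoter(self):
        df = pd.DataFrame(
            {"CREB": [True, np.nan], "CEBPB": [True, True], "CJUN": [False, True]},
            index=["p1", "p2"],
        )
        patterns = assign_patterns(df, FACTORS)
        assert list(patterns.index) == ["p1"]

    def test_missing_factor_column_is_error(self):
        df = pd.DataFrame({"CREB": [True]}, index=["p1"])
        with pytest.raises(KeyError):
            assign_patterns(df, FACTORS)

    def test_labels_partition(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.random((200, 3)) < 0.4, columns=FACTORS,
            index=[f"p{i}" for i in range(200)],
        )
        patterns = assign_patterns(df, FACTORS)
        assert set(patterns.unique()) <= set(all_pattern_labels(FACTORS))
        assert len(patterns) == 200


class TestEulerCounts:
    def test_one_promoter_per_pattern_marginals(self):
        labels = all_pattern_labels(FACTORS)
        patterns = pd.Series(labels, index=[f"p{i}" for i in range(8)])
        counts, marginals = euler_counts(patterns, FACTORS)
        assert counts.sum() == 8
        # each factor appears in exactly 4 of the 8 patterns
        assert all(marginals[f] == 4 for f in FACTORS)

    def test_empty_universe(self):
        patterns = pd.Series(dtype=object)
        counts, marginals = euler_counts(patterns, FACTORS)
        assert counts.sum() == 0
        assert all(marginals == 0)

    def test_conservation_random(self):
        rng = np.random.default_rng(9)
        labels = all_pattern_labels(FACTORS)
        patterns = pd.Series(
            rng.choice(labels, 500), index=[f"p{i}" for i in range(500)]
        )
        counts, marginals = euler_counts(patterns, FACTORS)
        assert counts.sum() == 500
        for f in FACTORS:
            expect = sum(counts[lab] for lab in labels if f in lab.split("+"))
            assert marginals[f] == expect


class TestFractions:
    def test_group_status_fraction(self):
        patterns = pd.Series(["A"] * 50, index=[f"p{i}" for i in range(50)])
        statuses = pd.Series(
            ["induced"] * 10 + ["unchanged"] * 40, index=patterns.index
        )
        assert group_status_fraction(patterns, statuses, "A", "induced") == (50, 10, 0.2)

    def test_zero_status(self):
        patterns = pd.Series(["A"] * 50, index=[f"p{i}" for i in range(50)])
        statuses = pd.Series(["unchanged"] * 50, index=patterns.index)
        assert group_status_fraction(patterns, statuses, "A", "induced") == (50, 0, 0.0)

    def test_empty_group_flagged(self):
        patterns = pd.Series(["A"], index=["p0"])
        statuses = pd.Series(["induced"], index=["p0"])
        n_group, n_status, frac = group_status_fraction(patterns, statuses, "B", "induced")
        assert n_group == 0 and math.isnan(frac)

    def test_expected_fraction_published_counts(self):
        statuses = pd.Series(["induced"] * 797 + ["unchanged"] * (20328 - 797))
        assert expected_fraction(statuses, "induced") == pytest.approx(797 / 20328)
        assert expected_fraction(statuses, "induced") == pytest.approx(0.0392, abs=5e-5)

    def test_expected_fraction_extremes(self):
        assert expected_fraction(pd.Series(["induced"] * 5), "induced") == 1.0
        assert expected_fraction(pd.Series(["unchanged"] * 5), "induced") == 0.0

    def test_enrichment_ratio_published_inputs(self):
        ratio = enrichment_ratio(0.20, 797 / 20328)
        assert ratio == pytest.approx(5.1011, abs=1e-4)
        assert ratio >= 5.0

    def test_enrichment_ratio_identity_and_zero(self):
        assert enrichment_ratio(0.3, 0.3) == 1.0
        assert enrichment_ratio(0.0, 0.2) == 0.0
        assert math.isnan(enrichment_ratio(0.1, 0.0))


class TestChiSquareGof:
    def test_hand_formula_example(self):
        chi2, p = chi_square_gof([30, 70], [20, 80])
        assert chi2 == pytest.approx(6.25)
        # oracle: upper tail of chi2 with 1 df equals erfc(sqrt(x/2))
        assert p == pytest.approx(math.erfc(math.sqrt(6.25 / 2)), rel=1e-12)
        assert p == pytest.approx(0.012419, abs=1e-6)

    def test_observed_equals_expected(self):
        chi2, p = chi_square_gof([25, 25, 50], [25, 25, 50])
        assert chi2 == 0.0
        assert p == 1.0

    def test_extreme_table(self):
        chi2, _ = chi_square_gof([0, 100], [50, 50])
        assert chi2 == pytest.approx(100.0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            chi_square_gof([1, 2], [0, 3])

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="total"):
            chi_square_gof([10, 10], [50, 50])

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=6),
        st.integers(0, 10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_manual_sum(self, observed, seed):
        rng = np.random.default_rng(seed)
        k = len(observed)
        expected = rng.random(k) + 0.1
        expected *= sum(observed) / expected.sum() if sum(observed) else 1.0
        if sum(observed) == 0:
            return
        chi2, _ = chi_square_gof(observed, expected)
        manual = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert chi2 == pytest.approx(manual, rel=1e-12)

    @pytest.mark.parametrize(
        "n,p0,observed_dev",
        [(1_000_000, 0.5, 500), (1_000_000, 0.2, 800)],
    )
    def test_matches_monte_carlo_null(self, n, p0, observed_dev):
        """Analytic p within 2x Monte-Carlo SE of a 1e5-draw multinomial null."""
        rng = np.random.default_rng(1234)
        observed = [n * p0 + observed_dev, n * (1 - p0) - observed_dev]
        expected = [n * p0, n * (1 - p0)]
        chi2_obs, p_analytic = chi_square_gof(observed, expected)
        draws = rng.binomial(n, p0, size=100_000)
        chi2_sim = (draws - n * p0) ** 2 / (n * p0) + (
            (n - draws) - n * (1 - p0)
        ) ** 2 / (n * (1 - p0))
        p_mc = float(np.mean(chi2_sim >= chi2_obs - 1e-9))
        se = math.sqrt(p_mc * (1 - p_mc) / 100_000)
        assert abs(p_analytic - p_mc) <= 2 * se


class TestTwoSampleTTest:
    def test_textbook_example(self):
        t, p = two_sample_ttest([1, 2, 3], [4, 5, 6])
        # oracle: pooled formula; s_p^2 = 1, t = -3 / sqrt(2/3)
        assert t == pytest.approx(-3 * math.sqrt(3 / 2), rel=1e-9)
        assert t == pytest.approx(-3.674235, abs=1e-6)
        assert p == pytest.approx(0.021312, abs=1e-6)

    def test_identical_samples(self):
        t, p = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        t1, p1 = two_sample_ttest([1, 2, 3], [4, 5, 6])
        t2, p2 = two_sample_ttest([4, 5, 6], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_ttest([2, 2, 2], [2, 2, 2])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1], [2, 3])

    def test_welch_option(self):
        t_pooled, _ = two_sample_ttest([1, 2, 3, 7], [4, 5, 6])
        t_welch, _ = two_sample_ttest([1, 2, 3, 7], [4, 5, 6], equal_var=False)
        assert t_pooled != t_welch

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=10),
        st.lists(st.floats(-10, 10), min_size=3, max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_pooled_formula(self, x, y):
        x, y = np.array(x), np.array(y)
        sx, sy = np.var(x, ddof=1), np.var(y, ddof=1)
        if sx + sy < 1e-12:
            return
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2)
        manual = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        t, _ = two_sample_ttest(x, y)
        assert t == pytest.approx(manual, rel=1e-9, abs=1e-9)


def _quantile_oracle(values, p):
    """Sort-and-interpolate (type 7) quantile."""
    v = sorted(values)
    h = (len(v) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestPercentileSummary:
    def test_single_value(self):
        s = percentile_summary([3.5])
        assert (s.p15, s.p50, s.p85) == (3.5, 3.5, 3.5)

    def test_median_of_grid(self):
        assert percentile_summary(list(range(101))).p50 == 50

    def test_matches_oracle_on_20_values(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 2, 20).tolist()
        s = percentile_summary(vals)
        assert s.p15 == pytest.approx(_quantile_oracle(vals, 0.15), rel=1e-12)
        assert s.p50 == pytest.approx(_quantile_oracle(vals, 0.50), rel=1e-12)
        assert s.p85 == pytest.approx(_quantile_oracle(vals, 0.85), rel=1e-12)

    def test_ordered(self):
        rng = np.random.default_rng(11)
        s = percentile_summary(rng.normal(0, 1, 50))
        assert s.p15 <= s.p50 <= s.p85

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_summary([])


class TestGroupEnrichmentTable:
    @pytest.fixture
    def universe(self):
        rng = np.random.default_rng(12)
        labels = all_pattern_labels(FACTORS)
        n = 1000
        patterns = pd.Series(
            rng.choice(labels, n), index=[f"p{i}" for i in range(n)]
        )
        statuses = pd.Series(
            rng.choice(["induced", "repressed", "unchanged"], n, p=[0.1, 0.1, 0.8]),
            index=patterns.index,
        )
        return patterns, statuses

    def test_conservation(self, universe):
        patterns, statuses = universe
        tab = group_enrichment_table(patterns, statuses, FACTORS)
        for status in ("induced", "repressed"):
            sub = tab[tab["status"] == status]
            assert sub["n_group"].sum() == len(patterns)
            assert sub["n_status"].sum() == int((statuses == status).sum())

    def test_all_promoters_group_ratio_is_exactly_one(self, universe):
        patterns, statuses = universe
        single = pd.Series("all", index=patterns.index)
        n_group, n_status, frac = group_status_fraction(single, statuses, "all", "induced")
        assert enrichment_ratio(frac, expected_fraction(statuses, "induced")) == 1.0

    def test_p_values_in_unit_interval(self, universe):
        patterns, statuses = universe
        tab = group_enrichment_table(patterns, statuses, FACTORS)
        valid = tab["p_value"].dropna()
        assert ((valid > 0) & (valid <= 1)).all()


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert (adj >= np.array(p) - 1e-12).all()
    assert (adj <= 1).all()


def test_pattern_label_deterministic():
    assert pattern_label([False, True, True], FACTORS) == "CEBPB+CJUN"
    assert pattern_label([False, False, False], FACTORS) == "none"
    assert all_pattern_labels(FACTORS)[0] == "none"
    assert len(all_pattern_labels(FACTORS)) == 8
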