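"""Variant enrichment, flexibility distributions, rate correlation."""

import numpy as np
import pytest
import scipy.stats

import dfiscan as d
from dfiscan.analysis import (
    bin_by_pct_dfi,
    conservation_groups,
    default_window,
    enrichment,
    flexibility_distribution,
    group_difference_test,
    rate_dfi_permutation,
    rate_dfi_sliding,
)
from dfiscan.errors import ContractError, JoinError


def uniform_pct(n):
    """Percentile ranks of n distinct values: 100/n, 200/n, ..., 100."""
    return 100.0 * np.arange(1, n + 1) / n


class TestBinning:
    @pytest.mark.parametrize("pct,expected", [
        (20.0, 1),      # "20 <= dfi < 40" boundary belongs to the second bin
        (19.999, 0),
        (39.999, 1),
        (80.0, 4),
        (100.0, 4),
        (0.5, 0),
    ])
    def test_boundary_semantics(self, pct, expected):
        assert bin_by_pct_dfi([pct])[0] == expected

    def test_out_of_range_rejected(self):
        for bad in (0.0, -1.0, 100.5):
            with pytest.raises(ContractError):
                bin_by_pct_dfi([bad])

    def test_edges_validated(self):
        with pytest.raises(ContractError):
            bin_by_pct_dfi([50.0], edges=(40, 40, 80))
        with pytest.raises(ContractError):
            bin_by_pct_dfi([50.0], edges=(0, 50))


class TestEnrichment:
    def test_expected_count_formula(self):
        # 10 positions, 2 in the first category, 5 variants -> E_1 = 1
        pct = np.array([10, 15, 25, 35, 45, 55, 65, 75, 85, 95.0])
        res = enrichment(pct, [0, 1, 2, 3, 4])
        np.testing.assert_array_equal(res.n, [2, 2, 2, 2, 2])
        np.testing.assert_array_equal(res.expected, [1, 1, 1, 1, 1])
        assert abs(res.expected.sum() - 5) <= 1e-9

    def test_null_case(self):
        pct = np.array([10, 15, 25, 35, 45, 55, 65, 75, 85, 95.0])
        res = enrichment(pct, [0, 2, 4, 6, 8])  # one variant per category
        assert res.chi2 == 0.0
        assert res.p == 1.0
        np.testing.assert_array_equal(res.ratio, np.ones(5))

    def test_hand_worked_two_bin_chi2(self):
        # n = (5, 5), N = 10, M = 4, O = (4, 0) -> E = (2, 2), chi2 = 4
        pct = uniform_pct(10) - 5.0   # 5, 15, ..., 95
        res = enrichment(pct, [0, 1, 2, 3], edges=(50.0,))
        np.testing.assert_array_equal(res.n, [5, 5])
        np.testing.assert_array_equal(res.expected, [2.0, 2.0])
        np.testing.assert_array_equal(res.observed, [4.0, 0.0])
        np.testing.assert_array_equal(res.ratio, [2.0, 0.0])
        assert res.chi2 == 4.0
        assert res.dof == 1
        np.testing.assert_allclose(res.p, scipy.stats.chi2.sf(4.0, 1))

    def test_totals_conserved(self):
        rng = np.random.default_rng(0)
        pct = uniform_pct(137)
        pos = rng.integers(0, 137, size=50)
        res = enrichment(pct, pos)
        assert res.observed.sum() == 50
        assert res.n.sum() == 137
        assert abs(res.expected.sum() - 50) <= 1e-9

    def test_variant_outside_profile_is_join_error(self):
        with pytest.raises(JoinError, match="99"):
            enrichment(uniform_pct(10), [0, 99])

    def test_empty_category_warns_and_is_excluded(self):
        pct = np.array([5.0, 10.0, 15.0, 19.0])  # everything below 20
        with pytest.warns(UserWarning, match="excluded"):
            res = enrichment(pct, [0, 1])
        assert res.dof == 0
        assert np.isnan(res.p)
        assert np.isnan(res.ratio[1:]).all()

    def test_chi2_matches_independent_sum(self):
        rng = np.random.default_rng(42)
        pct = uniform_pct(211)
        pos = rng.integers(0, 211, size=300)
        res = enrichment(pct, pos)
        manual = sum((o - e) ** 2 / e
                     for o, e in zip(res.observed, res.expected) if e > 0)
        np.testing.assert_allclose(res.chi2, manual, rtol=1e-12)


class TestFlexibilityDistribution:
    def test_uniform_percentiles_fill_bins_evenly(self):
        dist = flexibility_distribution(uniform_pct(100), np.arange(100),
                                        bin_width=20.0)
        np.testing.assert_allclose(dist.frequency, 0.2)
        assert dist.fraction_at_or_below(100.0) == 1.0

    def test_planted_lowest_quartile(self):
        pct = uniform_pct(100)
        labeled = np.nonzero(pct <= 25.0)[0]
        dist = flexibility_distribution(pct, labeled)
        assert dist.fraction_at_or_below(25.0) == 1.0

    def test_empty_label_set_rejected(self):
        with pytest.raises(ContractError):
            flexibility_distribution(uniform_pct(10), np.array([], dtype=int))


class TestRateCorrelation:
    def test_rates_equal_to_pct_give_perfect_correlation(self):
        pct = uniform_pct(200)
        res = rate_dfi_sliding(pct, pct.copy(), window_size=50, step=25)
        assert abs(res.correlation - 1.0) < 1e-12

    def test_two_window_line(self):
        # windows averaging to (10, 0.1) and (90, 0.9) lie on a line
        pct = np.concatenate([np.full(3, 10.0), np.full(3, 90.0)])
        pct += [-1, 0, 1, -1, 0, 1]
        rates = pct / 100.0
        res = rate_dfi_sliding(pct, rates, window_size=3, step=3)
        assert len(res.window_pct) == 2
        np.testing.assert_allclose(res.window_pct, [10.0, 90.0])
        np.testing.assert_allclose(res.window_rate, [0.1, 0.9])
        assert abs(res.correlation - 1.0) < 1e-12

    def test_window_larger_than_n_rejected(self):
        with pytest.raises(ContractError):
            rate_dfi_sliding(uniform_pct(10), np.ones(10), window_size=11)

    def test_default_window_rule(self):
        assert default_window(100) == 50
        assert default_window(4000) == 200

    def test_monotone_sort_key_preserves_windows_and_sign(self):
        rng = np.random.default_rng(3)
        pct = uniform_pct(150)
        rates = pct / 100.0 + rng.normal(0, 0.2, size=150)
        rates = np.clip(rates, 0, None)
        a = rate_dfi_sliding(pct, rates, window_size=30, step=15)
        # cube is strictly monotone on (0, 100]: same ordering, same windows
        b = rate_dfi_sliding(pct ** 3 / 1e4, rates, window_size=30, step=15)
        np.testing.assert_array_equal(a.window_rate, b.window_rate)
        assert np.sign(a.correlation) == np.sign(b.correlation)

    def test_permutation_null_is_beaten_by_signal(self):
        pct = uniform_pct(150)
        rates = pct / 100.0
        obs, perm = rate_dfi_permutation(pct, rates, window_size=30, step=15,
                                         n_permutations=200, seed=8)
        assert obs.correlation > perm.max()


class TestConservationGroups:
    def test_one_residue_per_group_boundary_mapping(self):
        groups = conservation_groups([10.0, 50.0, 90.0], [0.0, 1.0, 2.0])
        assert groups["ultra_conserved"]["n"] == 1
        assert groups["well_conserved"]["n"] == 1    # r = 1 is well-conserved
        assert groups["less_conserved"]["n"] == 1

    def test_all_zero_rates_single_group(self):
        groups = conservation_groups(uniform_pct(5), np.zeros(5))
        assert groups["ultra_conserved"]["n"] == 5
        assert groups["well_conserved"] is None
        assert groups["less_conserved"] is None

    def test_planted_ordering_of_medians(self):
        pct = uniform_pct(90)
        rates = np.empty(90)
        rates[:30] = 0.0          # lowest-%dfi third ultra-conserved
        rates[30:60] = 0.5
        rates[60:] = 2.0
        groups = conservation_groups(pct, rates)
        assert (groups["ultra_conserved"]["median"]
                < groups["less_conserved"]["median"])


class TestGroupDifference:
    def test_identical_groups_null(self):
        t, p, _ = group_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_separated_groups_match_welch_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
        t, p, df = group_difference_test(a, b)
        # Welch: t = (2 - 102) / sqrt(1/3 + 1/3), df = 4
        np.testing.assert_allclose(t, -100.0 / np.sqrt(2.0 / 3.0), rtol=1e-12)
        np.testing.assert_allclose(df, 4.0, rtol=1e-12)
        assert p < 1e-4

    def test_zero_variance_equal_means_convention(self):
        t, p, _ = group_difference_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_single_element_group_rejected(self):
        with pytest.raises(ContractError):
            group_difference_test([1.0], [1.0, 2.0])
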