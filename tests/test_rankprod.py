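"""Fractional ranking and the rank-product statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from panmir.datatypes import ValidationError
from panmir.rankprod import (
    fractional_rank,
    rank_product,
    rank_product_from_ranks,
    significant_items,
)


class TestFractionalRank:
    def test_ascending_untied(self):
        assert fractional_rank([-2.0, 0.5, 1.3]).tolist() == [1, 2, 3]

    def test_tie_averaging(self):
        assert fractional_rank([1, 1, 2]).tolist() == [1.5, 1.5, 3]

    def test_na_propagates_all_na_errors(self):
        r = fractional_rank([1.0, np.nan, 2.0])
        assert np.isnan(r[1]) and r[0] == 1 and r[2] == 2
        with pytest.raises(ValidationError):
            fractional_rank([np.nan, np.nan])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_descending_is_mirror_for_untied(self, vals):
        asc = fractional_rank(vals, "ascending")
        desc = fractional_rank(vals, "descending")
        assert np.allclose(asc + desc, len(vals) + 1)


class TestRankProduct:
    def test_top_ranked_item_exact_p(self):
        # item ranked 1 in all 3 lists of 4 items: exhaustive p = 1/64
        vals = pd.DataFrame(
            [[0.1, 0.2, 0.3], [1, 2, 1], [2, 1, 2], [3, 3, 3]],
            index=list("abcd"),
        )
        rp = rank_product(vals, method="exact")
        assert rp.table.loc["a", "p_down"] == pytest.approx(1 / 64)

    def test_permutation_matches_enumeration(self, rng):
        vals = pd.DataFrame(
            rng.standard_normal((5, 4)), index=[f"i{k}" for k in range(5)]
        )
        exact = rank_product(vals, method="exact")
        perm = rank_product(vals, method="permutation", n_perm=50_000, seed=5)
        for orient in ("p_up", "p_down"):
            assert np.allclose(exact.table[orient], perm.table[orient], atol=0.01)

    def test_bottom_ranked_item(self):
        vals = pd.DataFrame(
            [[5.0, 5.0], [1.0, 2.0], [2.0, 1.0], [3.0, 4.0]], index=list("wxyz")
        )
        rp = rank_product(vals, method="exact")
        assert rp.table.loc["w", "p_down"] == pytest.approx(1.0)
        assert rp.table.loc["w", "rp_down"] == pytest.approx(1.0)

    def test_null_p_values_uniform(self, rng):
        vals = pd.DataFrame(
            rng.standard_normal((100, 5)), index=[f"i{k}" for k in range(100)]
        )
        rp = rank_product(vals, n_perm=10_000, seed=3, method="permutation")
        assert stats.kstest(rp.table["p_down"], "uniform").pvalue > 0.01

    def test_invariant_to_monotone_transform_and_list_order(self, rng):
        vals = pd.DataFrame(rng.standard_normal((12, 4)))
        a = rank_product(vals, method="exact")
        transformed = vals.apply(lambda c: np.exp(c))[[3, 1, 0, 2]]
        b = rank_product(transformed, method="exact")
        pd.testing.assert_series_equal(a.table["rp_down"], b.table["rp_down"])

    def test_min_lists_exclusion_and_na_handling(self):
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0], [2.0, np.nan, np.nan], [3.0, 2.0, 2.0]],
            index=list("abc"),
        )
        rp = rank_product(vals, min_lists=2, method="exact")
        assert "b" not in rp.table.index and rp.n_excluded == 1
        # excluded rows still occupy ranks: list 0 has 3 ranked items
        assert rp.list_sizes.tolist() == [3, 2, 2]

    def test_smallest_rp_has_most_extreme_p(self, rng):
        vals = pd.DataFrame(rng.standard_normal((20, 3)))
        rp = rank_product(vals, method="exact")
        t = rp.table
        assert t["p_down"].idxmin() == t["rp_down"].idxmin()

    def test_subset_with_full_list_sizes(self, rng):
        """Aggregating a row subset against full-field list sizes keeps the
        per-item p of the full computation."""
        vals = pd.DataFrame(rng.standard_normal((30, 3)), index=range(30))
        full = rank_product(vals, method="exact")
        ranks = vals.apply(lambda c: fractional_rank(c.to_numpy()), raw=False)
        ranks = pd.DataFrame(
            np.column_stack([fractional_rank(vals[c]) for c in vals]), index=vals.index
        )
        sub = rank_product_from_ranks(
            ranks.iloc[:5], [30, 30, 30], method="exact"
        )
        assert np.allclose(sub.table["p_down"], full.table["p_down"].iloc[:5])


class TestSignificantItems:
    def test_empty_result(self):
        vals = pd.DataFrame(
            {0: [np.nan, 1.0, 2.0, np.nan], 1: [1.0, np.nan, np.nan, 2.0]},
            index=list("abcd"),
        )
        rp = rank_product(vals, min_lists=2, method="exact")
        assert significant_items(rp) == ([], [])

    def test_planted_extremes_called_in_both_orientations(self, rng):
        base = rng.standard_normal((60, 6))
        base[0] = 4.0 + rng.standard_normal(6) * 0.1
        base[1] = -4.0 - rng.standard_normal(6) * 0.1
        vals = pd.DataFrame(base, index=[f"i{k}" for k in range(60)])
        rp = rank_product(vals, n_perm=20_000, seed=1, method="permutation")
        pos, neg = significant_items(rp, 0.05)
        assert "i0" in pos and "i1" in neg
        assert set(pos).isdisjoint(neg)
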