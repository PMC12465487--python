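"""The blocked permutation engine against brute-force oracles, the BY
step-up against closed form and statsmodels, and the Kruskal–Wallis screen
against the rank-sum formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from phenoscreen import (
    StatsConfig,
    block_permutation_ttest,
    by_adjust,
    count_significant,
    exhaustive_block_permutation_oracle,
    kruskal_wallis_screen,
)


def _random_instance(rng, max_wells=12):
    """A small random blocked two-group dataset with >=2 wells per group."""
    while True:
        n = int(rng.integers(6, max_wells + 1))
        n_blocks = int(rng.integers(1, 3))
        blocks = rng.integers(0, n_blocks, n)
        groups = rng.integers(0, 2, n)
        ok = (groups == 0).sum() >= 2 and (groups == 1).sum() >= 2
        # each block needs both labels somewhere overall; degenerate blocks fine
        if ok:
            break
    X = rng.normal(size=(n, 2)) + groups[:, None] * rng.normal()
    return X, groups, blocks


class TestBlockPermutationTtest:
    def test_identical_constant_groups_give_t_zero_p_one(self):
        X = np.full((6, 3), 5.0)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = block_permutation_ttest(X, groups, None,
                                      StatsConfig(n_permutations=200))
        assert (res.table["t_obs"] == 0.0).all()
        assert (res.table["p_raw"] == 1.0).all()

    def test_single_block_worked_example_converges_to_exact(self):
        """A = {0, 1}, B = {10, 11}: exhaustive two-sided p is 2/6."""
        X = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
        groups = np.array(["A", "A", "B", "B"])
        p_exact, _ = exhaustive_block_permutation_oracle(X, groups)
        assert p_exact[0] == pytest.approx(2 / 6)
        res = block_permutation_ttest(
            X, groups, None, StatsConfig(n_permutations=20000, rng_seed=2))
        assert res.table["p_raw"].iloc[0] == pytest.approx(1 / 3, abs=0.01)

    def test_extreme_separation_hits_estimator_lower_bound(self):
        """When the arrangement space is huge and separation extreme, no
        sampled permutation reaches |t_obs| and p = 1/(B+1)."""
        rng = np.random.default_rng(0)
        n = 24
        groups = np.repeat([0, 1], n // 2)
        blocks = np.tile([0, 1], n // 2)
        X = (rng.normal(size=n) * 0.1 + groups * 1000.0)[:, None]
        B = 999
        res = block_permutation_ttest(X, groups, blocks,
                                      StatsConfig(n_permutations=B, rng_seed=4))
        assert res.table["p_raw"].iloc[0] == pytest.approx(1 / (B + 1))

    def test_sampled_p_matches_exhaustive_oracle(self):
        """Sampled p within 0.01 of exact enumeration on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            X, groups, blocks = _random_instance(rng)
            p_exact, _ = exhaustive_block_permutation_oracle(X, groups, blocks)
            res = block_permutation_ttest(
                X, groups, blocks,
                StatsConfig(n_permutations=20000,
                            rng_seed=int(rng.integers(2 ** 31))))
            assert np.abs(res.table["p_raw"].to_numpy() - p_exact).max() < 0.01

    def test_row_order_invariance(self):
        """Shuffling well order (with labels) leaves all p-values unchanged."""
        rng = np.random.default_rng(7)
        X, groups, blocks = _random_instance(rng)
        cfg = StatsConfig(n_permutations=500, rng_seed=9)
        res1 = block_permutation_ttest(X, groups, blocks, cfg)
        perm = rng.permutation(len(groups))
        res2 = block_permutation_ttest(X[perm], groups[perm], blocks[perm], cfg)
        np.testing.assert_array_equal(res1.table["p_raw"].to_numpy(),
                                      res2.table["p_raw"].to_numpy())

    def test_missing_group_is_an_error(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="absent"):
            block_permutation_ttest(X, np.array(["a"] * 4), None,
                                    StatsConfig(n_permutations=10),
                                    levels=("a", "b"))

    def test_nan_policy_skips_underpowered_features(self):
        X = np.random.default_rng(1).normal(size=(8, 2))
        X[:5, 0] = np.nan  # group a retains a single finite value
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = block_permutation_ttest(X, groups, None,
                                      StatsConfig(n_permutations=100))
        assert res.table["skip_reason"].iloc[0] == "insufficient_finite_data"
        assert np.isnan(res.table["p_raw"].iloc[0])
        assert res.table["skip_reason"].iloc[1] == ""
        assert res.n_skipped == 1

    def test_all_features_skipped_is_an_error(self):
        X = np.full((6, 2), np.nan)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="skipped"):
            block_permutation_ttest(X, groups, None,
                                    StatsConfig(n_permutations=10))

    def test_raw_p_bounds_and_adjusted_dominance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 30))
        groups = np.repeat([0, 1], 5)
        B = 200
        res = block_permutation_ttest(X, groups, None,
                                      StatsConfig(n_permutations=B, rng_seed=1))
        p = res.table["p_raw"]
        assert (p >= 1 / (B + 1)).all() and (p <= 1).all()
        assert (res.table["p_adjusted"] >= p - 1e-15).all()
        assert (res.table["p_adjusted"] <= 1).all()


class TestExhaustiveOracle:
    def test_arrangement_count_two_blocks(self):
        """2 blocks x (2 vs 2 wells): C(4,2)^2 = 36 arrangements, and the
        identity arrangement makes p >= 1/36."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 1))
        groups = np.tile([0, 0, 1, 1], 2)
        blocks = np.repeat([0, 1], 4)
        p, _ = exhaustive_block_permutation_oracle(X, groups, blocks)
        assert p[0] >= 1 / 36
        assert round(p[0] * 36) == pytest.approx(p[0] * 36)  # multiple of 1/36

    def test_identical_data_gives_p_one(self):
        X = np.full((6, 1), 2.0)
        groups = np.array([0, 0, 0, 1, 1, 1])
        p, _ = exhaustive_block_permutation_oracle(X, groups)
        assert p[0] == 1.0

    def test_combinatorial_bound_enforced(self):
        X = np.zeros((40, 1))
        groups = np.tile([0, 1], 20)
        with pytest.raises(ValueError, match="not enumerable"):
            exhaustive_block_permutation_oracle(X, groups, max_arrangements=100)


def _by_oracle(p):
    """Independent closed-form BY step-up for the tests."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    cm = sum(1.0 / i for i in range(1, m + 1))
    cand = p[order] * m * cm / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(cand[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestByAdjust:
    def test_worked_vector_equalises(self):
        adj = by_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 25 / 300)

    def test_single_p_unchanged(self):
        assert by_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (by_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_closed_form_and_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            adj = by_adjust(p)
            np.testing.assert_allclose(adj, _by_oracle(p), rtol=1e-12)
            sm = multipletests(p, method="fdr_by")[1]
            np.testing.assert_allclose(adj, sm, rtol=1e-10)

    def test_nan_passthrough_excluded_from_family(self):
        adj = by_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], _by_oracle([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_dominates_bh_dominates_raw(self, p):
        """BY adjusted >= BH adjusted >= raw p, elementwise, on any input."""
        p = np.asarray(p)
        by = by_adjust(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (by >= bh - 1e-12).all()
        assert (bh >= p - 1e-12).all()


class TestCountSignificant:
    def test_known_mask(self):
        from phenoscreen.stats import PermutationTestResult
        n = 20
        table = pd.DataFrame({
            "t_obs": np.zeros(n), "p_raw": np.ones(n), "p_adjusted": np.ones(n),
            "significant": [True] * 7 + [False] * 13,
            "skip_reason": [""] * n,
        }, index=[f"prestim_f{i}" if i < 10 else f"poststim_f{i}"
                  for i in range(n)])
        res = PermutationTestResult(table=table, n_permutations=10,
                                    statistic="pooled_t", fdr_q=0.05)
        total, breakdown = count_significant(res)
        assert total == 7
        assert breakdown["prestim"] == 7
        assert breakdown.sum() == total

    def test_empty(self):
        from phenoscreen.stats import PermutationTestResult
        table = pd.DataFrame({"t_obs": [0.0], "p_raw": [1.0],
                              "p_adjusted": [1.0], "significant": [False],
                              "skip_reason": [""]}, index=["f"])
        res = PermutationTestResult(table=table, n_permutations=10,
                                    statistic="pooled_t", fdr_q=0.05)
        assert count_significant(res)[0] == 0


def _kw_oracle(*samples):
    """Brute-force tie-corrected Kruskal–Wallis H."""
    pooled = np.concatenate(samples)
    N = pooled.size
    import scipy.stats
    ranks = scipy.stats.rankdata(pooled)
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum() / (N ** 3 - N))
    return h / tie


class TestKruskalWallis:
    def test_worked_rank_example(self):
        res = kruskal_wallis_screen(np.array([1.0, 2, 3, 4, 5, 6])[:, None],
                                    np.array(["a"] * 3 + ["b"] * 3))
        assert res.table["H"].iloc[0] == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups(self):
        res = kruskal_wallis_screen(np.array([1.0, 2, 3, 1, 2, 3])[:, None],
                                    np.array(["a"] * 3 + ["b"] * 3))
        assert res.table["H"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_ties_match_brute_force(self):
        a = np.array([1.0, 1.0, 2.0])
        b = np.array([2.0, 3.0, 3.0])
        res = kruskal_wallis_screen(np.concatenate([a, b])[:, None],
                                    np.array(["a"] * 3 + ["b"] * 3))
        assert res.table["H"].iloc[0] == pytest.approx(_kw_oracle(a, b))

    def test_constant_feature_skipped(self):
        X = np.column_stack([np.full(6, 3.0), np.arange(6.0)])
        res = kruskal_wallis_screen(X, np.array(["a"] * 3 + ["b"] * 3))
        assert res.table["skip_reason"].iloc[0] == "zero_variance"
        assert res.table["skip_reason"].iloc[1] == ""

    def test_three_groups_df(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        res = kruskal_wallis_screen(X, labels)
        assert res.n_groups == 3
        import scipy.stats
        for j in range(3):
            h, p = scipy.stats.kruskal(*(X[labels == lv, j]
                                         for lv in ("a", "b", "c")))
            assert res.table["H"].iloc[j] == pytest.approx(h)
            assert res.table["p_raw"].iloc[j] == pytest.approx(p)
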