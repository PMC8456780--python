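import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

import scellintegrate as sci
from scellintegrate.markers import (
    MarkerCutoffs,
    _fisher_vectorized,
    _wilcoxon_vectorized,
)


# --- independent oracles ---------------------------------------------------


def rank_sum_p_enumeration(a, b):
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {}
    # mid-ranks
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        for k in range(i, j):
            ranks.setdefault(pooled[i], (i + j + 1) / 2)
        i = j
    obs = sum(ranks[x] for x in a)
    n1 = len(a)
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    pooled_ranks = [ranks[x] for x in pooled]
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = sum(pooled_ranks[i] for i in combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    n_in, n_out = a + b, c + d
    M, K = n_in + n_out, a + c

    def pmf(x):
        if x < 0 or x > K or x > n_in or K - x > n_out:
            return Fraction(0)
        return Fraction(math.comb(n_in, x) * math.comb(n_out, K - x), math.comb(M, K))

    p_obs = pmf(a)
    return float(sum(p for x in range(K + 1) if (p := pmf(x)) <= p_obs))


# --- scalar operations -----------------------------------------------------


class TestWilcoxon:
    def test_separated_groups_p_point_one(self):
        assert sci.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert rank_sum_p_enumeration([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert sci.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            sci.wilcoxon_rank_sum([], [1.0])

    def test_exact_path_matches_enumeration_small_n(self, rng):
        """Exact p agrees with full enumeration for tie-free inputs, n <= 6."""
        for _ in range(120):
            n1, n2 = rng.integers(1, 7, size=2)
            vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = vals[:n1], vals[n1:]
            assert sci.wilcoxon_rank_sum(a, b) == pytest.approx(
                rank_sum_p_enumeration(a, b), abs=1e-12
            )

    def test_type_one_error_calibrated(self):
        """Null rejection at 0.05 within [0.03, 0.07] over 2,000 simulations."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(60, 2000))
        mask = np.zeros(60, dtype=bool)
        mask[:30] = True
        p = _wilcoxon_vectorized(X, mask)
        assert 0.03 <= np.mean(p < 0.05) <= 0.07

    def test_vectorized_matches_scipy_asymptotic_with_ties(self, rng):
        X = rng.integers(0, 4, size=(40, 25)).astype(float)
        mask = np.zeros(40, dtype=bool)
        mask[rng.choice(40, 17, replace=False)] = True
        p_vec = _wilcoxon_vectorized(X, mask)
        for j in range(25):
            ref = stats.mannwhitneyu(
                X[mask, j], X[~mask, j], alternative="two-sided", method="asymptotic"
            ).pvalue
            assert p_vec[j] == pytest.approx(min(ref, 1.0), abs=1e-10)


class TestFisherExact:
    def test_three_vs_zero_of_three(self):
        assert sci.fisher_exact_frequency(3, 3, 0, 3) == pytest.approx(0.1)
        assert fisher_p_enumeration(3, 0, 0, 3) == pytest.approx(0.1)

    def test_balanced_identical_frequencies(self):
        assert sci.fisher_exact_frequency(5, 10, 5, 10) == pytest.approx(1.0)

    def test_degenerate_all_zero(self):
        assert sci.fisher_exact_frequency(0, 4, 0, 6) == pytest.approx(1.0)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            sci.fisher_exact_frequency(5, 3, 0, 3)

    def test_agrees_with_enumeration_all_small_tables(self):
        """Exhaustive agreement with hypergeometric enumeration, total n <= 20."""
        for n_in in range(1, 11):
            for n_out in range(1, 21 - n_in):
                for a in range(n_in + 1):
                    for c in range(0, n_out + 1, max(1, n_out // 3)):
                        expected = fisher_p_enumeration(a, n_in - a, c, n_out - c)
                        got = sci.fisher_exact_frequency(a, n_in, c, n_out)
                        assert got == pytest.approx(expected, rel=1e-7, abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        n_in, n_out = 37, 81
        k_in = rng.integers(0, n_in + 1, size=60)
        k_out = rng.integers(0, n_out + 1, size=60)
        p_vec = _fisher_vectorized(k_in, n_in, k_out, n_out)
        for i in range(60):
            ref = sci.fisher_exact_frequency(int(k_in[i]), n_in, int(k_out[i]), n_out)
            assert p_vec[i] == pytest.approx(ref, rel=1e-6, abs=1e-12)


class TestCombineFisher:
    def test_ones_stay_one(self):
        assert sci.combine_fisher(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert sci.combine_fisher(0.05, 0.05) == pytest.approx(expected, abs=1e-12)
        # closed form: X = -2(2 ln 0.05) = 11.98293, exp(-X/2)(1 + X/2)
        assert sci.combine_fisher(0.05, 0.05) == pytest.approx(0.0174787, abs=1e-5)

    def test_symmetric_and_zero_floored(self):
        assert sci.combine_fisher(0.01, 0.3) == sci.combine_fisher(0.3, 0.01)
        assert 0.0 < sci.combine_fisher(0.0, 0.5) < 1e-250


class TestBH:
    def test_hand_computed_step_up(self):
        got = sci.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert sci.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.random(50))
        adj = sci.bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p)  # BH never decreases a p-value


# --- find_markers ----------------------------------------------------------


def _norm_from_counts(counts):
    counts = np.asarray(counts)
    cm = sci.CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=np.array([f"c{i}" for i in range(counts.shape[0])], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(counts.shape[1])], dtype=object),
        sample_of_cell=np.full(counts.shape[0], "s", dtype=object),
    )
    return sci.normalize(cm)


class TestFindMarkers:
    @staticmethod
    def _two_group_counts(seed=5, n=200, n_genes=300, shifted=range(10), fold=8.0):
        rng = np.random.default_rng(seed)
        base = rng.gamma(2.0, 1.0, size=n_genes)
        mult = np.ones((2 * n, n_genes))
        mult[:n, list(shifted)] = fold
        lam = rng.gamma(2.0, (base * mult) / 2.0)
        counts = rng.poisson(lam)
        labels = np.array([0] * n + [1] * n)
        return counts, labels

    def test_planted_shift_passes_all_cutoffs(self):
        counts, labels = self._two_group_counts()
        table = sci.find_markers(_norm_from_counts(counts), labels)
        row = table[(table["cluster"] == 0) & (table["gene"] == "g0")].iloc[0]
        assert row["log2fc"] >= 1.5
        assert row["p_adj"] < 0.05
        assert row["freq_in"] > 0.3
        assert bool(row["is_marker"])

    def test_low_fold_change_excluded_regardless_of_p(self):
        counts, labels = self._two_group_counts()
        table = sci.find_markers(
            _norm_from_counts(counts), labels, cutoffs=MarkerCutoffs(min_abs_log2fc=1.5)
        )
        sub = table[np.abs(table["log2fc"]) < 1.5]
        assert not sub["is_marker"].any()

    def test_frequency_exactly_at_cutoff_excluded(self):
        # gene g0: expressed in exactly 30% of cluster 0 at huge counts,
        # nowhere else -> freq_in == 0.3 exactly, so the strict > excludes it
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 4, size=(40, 30))
        counts[:, 0] = 0
        counts[:6, 0] = 500
        labels = np.array([0] * 20 + [1] * 20)
        table = sci.find_markers(_norm_from_counts(counts), labels)
        row = table[(table["cluster"] == 0) & (table["gene"] == "g0")].iloc[0]
        assert row["freq_in"] == pytest.approx(0.3)
        assert row["log2fc"] >= 1.5
        assert not bool(row["is_marker"])

    def test_small_cluster_skipped_with_warning(self):
        counts, labels = self._two_group_counts(n=50)
        labels = labels.copy()
        labels[:2] = 2  # cluster of size 2
        with pytest.warns(UserWarning, match="skipped"):
            table = sci.find_markers(_norm_from_counts(counts), labels)
        assert 2 not in set(table["cluster"])

    def test_null_combined_statistic_calibrated(self):
        """Null rejection rate of the combined p in [0.02, 0.08]."""
        rng = np.random.default_rng(7)
        base = rng.gamma(1.0, 2.0, size=2000)
        lam = rng.gamma(2.0, np.tile(base, (400, 1)) / 2.0)
        counts = rng.poisson(lam)
        labels = np.array([0] * 200 + [1] * 200)
        expressed = (counts > 0).sum(axis=0) >= 10
        table = sci.find_markers(_norm_from_counts(counts[:, expressed]), labels)
        sub = table[table["cluster"] == 0]
        rate = float(np.mean(sub["p_combined"] < 0.05))
        assert 0.02 <= rate <= 0.08


class TestPrerankedScores:
    def _table(self):
        counts, labels = TestFindMarkers._two_group_counts(n=60, n_genes=80)
        return sci.find_markers(_norm_from_counts(counts), labels)

    def test_rank_score_definition_and_order(self):
        table = self._table()
        ranked = sci.preranked_scores(table, 0)
        sub = table[table["cluster"] == 0].set_index("gene")
        expected = sub["log2fc"] * (-np.log10(np.maximum(sub["p_adj"], 1e-300)))
        assert ranked.loc["g0"] == pytest.approx(expected.loc["g0"])
        assert np.all(np.diff(ranked.to_numpy()) <= 1e-12)

    def test_score_examples(self):
        assert 2 * (-np.log10(0.01)) == pytest.approx(4.0)
        table = self._table()
        ranked = sci.preranked_scores(table, 0)
        p1 = table[(table["cluster"] == 0) & (table["p_adj"] >= 1.0)]
        for g in p1["gene"]:
            assert ranked.loc[g] == pytest.approx(0.0)

    def test_negative_scores_sort_last_and_missing_cluster_raises(self):
        table = self._table()
        ranked = sci.preranked_scores(table, 0)
        negs = ranked[ranked < 0]
        if len(negs):
            assert ranked.index.get_loc(negs.index[0]) >= len(ranked) - len(negs)
        with pytest.raises(KeyError):
            sci.preranked_scores(table, 99)
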