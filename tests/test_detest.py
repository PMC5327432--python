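import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import nbinom

import acscreen as ac
from acscreen.detest import bh_fdr


def exact_ac_probability(x: int, i: int, n1: int, n2: int) -> Fraction:
    """p(i|x) by direct evaluation of the defining formula in exact
    rational arithmetic — the independent oracle for the log-space code."""
    r = Fraction(n2, n1)
    return (
        r**i
        * Fraction(math.factorial(x + i), math.factorial(x) * math.factorial(i))
        / (1 + r) ** (x + i + 1)
    )


class TestPointProbability:
    def test_empty_counts_equal_libraries(self):
        assert ac.ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5)
        assert ac.ac_probability(1, 0, 10**6, 10**6) == pytest.approx(0.25)

    @pytest.mark.parametrize("x,i,n1,n2", [
        (5, 3, 1_000_000, 2_000_000),
        (0, 7, 1_000_000, 2_000_000),
        (12, 0, 3, 5),
        (40, 55, 999_999, 1_000_001),
        (100, 250, 10**6, 10**6),
        (10_000, 10_500, 10**6, 10**6),
        (10_000, 2_415, 10**6, 10**5),
    ])
    def test_matches_exact_rational_arithmetic(self, x, i, n1, n2):
        exact = float(exact_ac_probability(x, i, n1, n2))
        assert ac.ac_probability(x, i, n1, n2) == pytest.approx(
            exact, rel=1e-12)

    def test_matches_negative_binomial_identity(self):
        """p(i|x) is the NB mass with x+1 successes at success probability
        N1/(N1+N2), evaluated at i failures."""
        # x capped at 100: deeper in the tails scipy's own pmf drifts to
        # ~1e-12, beyond which the exact-rational checks take over
        for x in (0, 1, 5, 100):
            for ratio in (0.1, 1.0, 10.0):
                n1 = 1_000_000
                n2 = int(ratio * n1)
                p = n1 / (n1 + n2)
                for i in (0, 1, 3, 50, int((x + 1) * ratio) + 7):
                    expected = nbinom.pmf(i, x + 1, p)
                    got = ac.ac_probability(x, i, n1, n2)
                    assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("x", [0, 1, 5, 100])
    @pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0])
    def test_normalizes_to_one(self, x, ratio):
        n1 = 1_000_000
        n2 = int(ratio * n1)
        mean = (x + 1) * ratio
        hi = int(mean + 60 * math.sqrt((x + 1) * ratio * (1 + ratio)) + 200)
        total = sum(ac.ac_probability(x, i, n1, n2) for i in range(hi))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_survives_counts_of_order_1e7(self):
        v = ac.ac_probability(10**7, 10**7, 10**7, 10**7)
        assert 0 < v < 1e-3
        assert math.isfinite(v)


class TestTwoSidedPValue:
    def test_concordant_counts_give_p_one(self):
        assert ac.ac_pvalue(7, 7, 10**6, 10**6) == 1.0
        assert ac.ac_pvalue(0, 0, 123, 456_789) == 1.0

    def test_zero_versus_fifty_brute_force_tail(self):
        # upper tail of p(i|0) with equal libraries is geometric:
        # sum_{i>=y} (1/2)^(i+1) = (1/2)^y, doubled
        tail = sum(0.5 ** (i + 1) for i in range(50, 1100))
        expected = min(1.0, 2 * tail)
        assert ac.ac_pvalue(0, 50, 10**6, 10**6) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("x,y,n1,n2", [
        (10, 40, 10**6, 10**6),
        (40, 10, 10**6, 10**6),
        (100, 30, 10**6, 2 * 10**6),
        (3, 0, 10**6, 10**6),
        (0, 3, 10**6, 3 * 10**6),
        (1000, 1200, 10**7, 10**7),
        (251, 249, 10**6, 10**6),
    ])
    def test_matches_negative_binomial_tails(self, x, y, n1, n2):
        """Independent oracle: the doubled smaller-tail construction
        evaluated with scipy's NB distribution functions."""
        p = n1 / (n1 + n2)
        if y * n1 >= x * n2:
            tail = nbinom.sf(y - 1, x + 1, p)
        else:
            tail = nbinom.cdf(y, x + 1, p)
        assert ac.ac_pvalue(x, y, n1, n2) == pytest.approx(
            min(1.0, 2 * tail), rel=1e-9)

    def test_discordance_gives_small_p_in_both_directions(self):
        lo = ac.ac_pvalue(5, 500, 10**6, 10**6)
        hi = ac.ac_pvalue(500, 5, 10**6, 10**6)
        assert lo < 1e-10 and hi < 1e-10

    def test_null_distribution_is_conservative(self, null_pvalues):
        """Under equal expression the p-values are stochastically >=
        uniform: P(p <= a) stays within the binomial slack of a."""
        n = null_pvalues.size
        for alpha in (0.05, 0.01, 0.001):
            frac = np.mean(null_pvalues <= alpha)
            assert frac <= 1.5 * alpha + 3 * math.sqrt(alpha / n)


def bh_reference(pvals):
    """Straight transcription of the step-up definition, O(m^2)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda k: pvals[k])
    q = [None] * m
    for rank0, idx in enumerate(order):
        q[idx] = min(
            min(m * pvals[j] / (r + 1) for r, j in enumerate(order)
                if r >= rank0),
            1.0,
        )
    return q


class TestBHFDR:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.04]).tolist() == [0.04]

    def test_matches_definitional_oracle(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(bh_fdr(p), bh_reference(p), rtol=1e-15)
        rng = np.random.default_rng(5)
        p = rng.uniform(size=57)
        np.testing.assert_allclose(bh_fdr(p), bh_reference(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=200), rng.uniform(size=20) * 1e-4])
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_constant_inputs_are_fixed_points(self):
        assert bh_fdr([0.2] * 7).tolist() == [0.2] * 7

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


def two_sample_table(xs, ys, n1=None, n2=None):
    counts = np.column_stack([xs, ys]).astype(np.int64)
    genes = [ac.GeneRecord(f"g{i}", 1000) for i in range(len(xs))]
    totals = np.array([n1 or counts[:, 0].sum() or 1,
                       n2 or counts[:, 1].sum() or 1])
    return ac.CountTable(genes=genes, samples=["a", "b"], counts=counts,
                         totals=totals)


class TestTestPair:
    def test_double_zero_gene_undefined_fold_p_one(self):
        table = two_sample_table([0, 10], [0, 10], 100, 100)
        res = ac.test_pair(table, ac.compute_fpkm(table), "a", "b")
        assert res[0].p_value == 1.0
        assert math.isnan(res[0].log2_fold)
        assert res[0].fold_undefined

    def test_worked_fold_example(self):
        # FPKM ratio 32.77/6.83 is the published 2.26 at 2-decimal rounding
        fa, fb = 32.77, 6.83
        assert round(math.log2(fa / fb), 2) == 2.26

    def test_null_table_produces_no_discoveries(self):
        xs = np.arange(1, 101) * 3
        table = two_sample_table(xs, xs, 10**6, 10**6)
        res = ac.test_pair(table, ac.compute_fpkm(table), "a", "b")
        assert all(r.p_value == 1.0 for r in res)
        assert not any(r.q_value <= 0.001 for r in res)

    def test_fold_antisymmetry_and_infinite_sentinels(self):
        table = two_sample_table([30, 0, 8], [3, 9, 0], 10**6, 10**6)
        expr = ac.compute_fpkm(table)
        ab = ac.test_pair(table, expr, "a", "b")
        ba = ac.test_pair(table, expr, "b", "a")
        assert ab[0].log2_fold == pytest.approx(-ba[0].log2_fold)
        assert ab[1].log2_fold == -math.inf and ba[1].log2_fold == math.inf
        assert ab[2].log2_fold == math.inf
        assert ab[0].q_value >= ab[0].p_value - 1e-15

    def test_unknown_sample_is_an_error(self):
        table = two_sample_table([1], [2], 10, 10)
        with pytest.raises(KeyError, match="nope"):
            ac.test_pair(table, ac.compute_fpkm(table), "a", "nope")
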