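"""Agreement statistics against independent oracles and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from dietagree import (
    AgreementSummary,
    CrossTable,
    UndefinedStatisticError,
    average_over_groups,
    cross_classification,
    cross_table,
    evaluate_criteria,
    linear_weights,
    quadratic_weights,
    spearman,
    weighted_kappa,
)


def _random_level_vectors(rng, n, k):
    return rng.integers(1, k + 1, size=n), rng.integers(1, k + 1, size=n)


def _brute_force_kappa(counts, w):
    """Independent direct double-sum of po and pe."""
    n = counts.sum()
    k = counts.shape[0]
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            pij = counts[i, j] / n
            pi = counts[i, :].sum() / n
            pj = counts[:, j].sum() / n
            po += w[i, j] * pij
            pe += w[i, j] * pi * pj
    return (po - pe) / (1 - pe)


class TestSpearman:
    def test_identical_orderings(self):
        r = spearman([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert r.rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        r = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_equals_pearson_on_midranks_with_ties(self):
        x, y = [1, 1, 2, 3], [1, 2, 2, 3]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_matches_scipy_on_random_tied_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = _random_level_vectors(rng, 40, 6)
            ours = spearman(x, y).rho
            ref = sps.spearmanr(x, y).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_fisher_z_interval_and_p(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 7, 60)
        y = np.clip(x + rng.integers(-1, 2, 60), 1, 6)
        r = spearman(x, y)
        se = 1 / math.sqrt(60 - 3)
        z = math.atanh(r.rho)
        assert r.ci_low == pytest.approx(math.tanh(z - 1.96 * se), abs=1e-4)
        assert r.ci_high == pytest.approx(math.tanh(z + 1.96 * se), abs=1e-4)
        assert r.p == pytest.approx(2 * sps.norm.sf(abs(z) / se))
        assert r.ci_low < r.rho < r.ci_high

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = _random_level_vectors(rng, 30, 6)
        assert spearman(x, y).rho == pytest.approx(spearman(y, x).rho)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 7, 25)
        assert spearman(x, x).rho == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([2, 2, 2, 2], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spearman([1, 2, 3], [1, 2, 3])


class TestCrossTable:
    def test_diagonal_only(self):
        t = cross_table([1, 1, 2], [1, 1, 2], k=6)
        assert t.n == 3
        assert t.counts[0, 0] == 2 and t.counts[1, 1] == 1
        assert np.all(t.counts == np.diag(np.diag(t.counts)))

    def test_corner_cells(self):
        t = cross_table([1, 6], [6, 1], k=6)
        assert t.counts[0, 5] == 1 and t.counts[5, 0] == 1

    def test_marginals_match_tallies_on_random_sample(self):
        rng = np.random.default_rng(4)
        x, y = _random_level_vectors(rng, 50, 6)
        t = cross_table(x, y, k=6)
        for lv in range(1, 7):
            assert t.counts[lv - 1, :].sum() == np.sum(x == lv)
            assert t.counts[:, lv - 1].sum() == np.sum(y == lv)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cross_table([0, 1], [1, 1], k=6)


class TestCrossClassification:
    def test_identical_vectors(self):
        cc = cross_classification(cross_table([1, 2, 3, 4], [1, 2, 3, 4], 6))
        assert (cc.exact_pct, cc.exact_adjacent_pct, cc.extreme_pct) == (100, 100, 0)

    def test_all_opposite_extremes(self):
        cc = cross_classification(cross_table([1, 1], [6, 6], 6))
        assert (cc.exact_pct, cc.exact_adjacent_pct, cc.extreme_pct) == (0, 0, 100)

    def test_hand_counted_example(self):
        # one exact, one adjacent, one two-off, one extreme
        cc = cross_classification(
            cross_table([1, 2, 5, 1], [1, 3, 3, 6], 6)
        )
        assert cc.exact_pct == pytest.approx(25.0)
        assert cc.exact_adjacent_pct == pytest.approx(50.0)
        assert cc.extreme_pct == pytest.approx(25.0)

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 200))
            k = int(rng.integers(2, 7))
            x, y = _random_level_vectors(rng, n, k)
            cc = cross_classification(cross_table(x, y, k))
            exact = sum(a == b for a, b in zip(x, y))
            adj = sum(abs(a - b) <= 1 for a, b in zip(x, y))
            extreme = sum(
                {a, b} == {1, k} for a, b in zip(x, y)
            )
            assert cc.exact_pct == pytest.approx(100 * exact / n)
            assert cc.exact_adjacent_pct == pytest.approx(100 * adj / n)
            assert cc.extreme_pct == pytest.approx(100 * extreme / n)

    @given(
        st.lists(
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            min_size=1, max_size=60,
        )
    )
    def test_exact_never_exceeds_exact_plus_adjacent(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        cc = cross_classification(cross_table(x, y, 6))
        assert 0 <= cc.exact_pct <= cc.exact_adjacent_pct <= 100
        assert 0 <= cc.extreme_pct <= 100


class TestWeights:
    def test_linear_values(self):
        w = linear_weights(6)
        assert w[0, 0] == 1.0
        assert w[0, 5] == 0.0  # extreme disagreement gets no credit
        assert w[0, 2] == pytest.approx(0.6)  # 1 - 2/5

    def test_k2_reduces_to_identity(self):
        assert np.allclose(linear_weights(2), np.eye(2))

    def test_quadratic_values(self):
        w = quadratic_weights(6)
        assert w[0, 2] == pytest.approx(1 - 4 / 25)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        t = CrossTable(np.diag([3, 4, 5]))
        assert weighted_kappa(t, linear_weights(3)).kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # table equal to the outer product of its marginals
        t = CrossTable(np.outer([1, 2, 3], [2, 2, 2]))
        assert weighted_kappa(t, linear_weights(3)).kappa == pytest.approx(0.0)

    def test_three_by_three_against_double_sum(self):
        counts = np.array([[2, 1, 0], [1, 3, 1], [0, 1, 2]])
        w = linear_weights(3)
        ours = weighted_kappa(CrossTable(counts), w).kappa
        assert ours == pytest.approx(_brute_force_kappa(counts, w))

    def test_thousand_random_tables_against_double_sum(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 8, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            t = CrossTable(counts)
            w = linear_weights(k)
            try:
                ours = weighted_kappa(t, w).kappa
            except UndefinedStatisticError:
                continue
            assert ours == pytest.approx(_brute_force_kappa(counts, w), abs=1e-12)

    def test_matches_sklearn_linear_kappa_on_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x, y = _random_level_vectors(rng, 80, 6)
            ours = weighted_kappa(cross_table(x, y, 6), linear_weights(6)).kappa
            ref = cohen_kappa_score(
                x, y, labels=list(range(1, 7)), weights="linear"
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_k2_linear_equals_unweighted_kappa(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            x, y = _random_level_vectors(rng, 60, 2)
            try:
                ours = weighted_kappa(cross_table(x, y, 2), linear_weights(2)).kappa
            except UndefinedStatisticError:
                continue
            ref = cohen_kappa_score(x, y, labels=[1, 2])
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_never_exceeds_one_and_equality_iff_diagonal(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 5, size=(k, k))
            if counts.sum() == 0:
                counts[0, 1] = 1
            try:
                res = weighted_kappa(CrossTable(counts), linear_weights(k))
            except UndefinedStatisticError:
                continue
            off_diag = counts.sum() - np.trace(counts)
            assert res.kappa <= 1 + 1e-12
            assert (res.kappa == pytest.approx(1.0)) == (off_diag == 0)

    def test_degenerate_marginals_flagged(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[1, 1] = 10  # everyone in one cell: pe = 1
        with pytest.raises(UndefinedStatisticError):
            weighted_kappa(CrossTable(counts), linear_weights(3))

    def test_se0_positive_and_p_small_for_strong_agreement(self):
        rng = np.random.default_rng(10)
        x = rng.integers(1, 7, 100)
        y = np.clip(x + rng.integers(-1, 2, 100), 1, 6)
        res = weighted_kappa(cross_table(x, y, 6), linear_weights(6))
        assert res.se0 > 0
        assert res.p < 0.001


class TestPermutationInvariance:
    def test_all_statistics_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(11)
        x, y = _random_level_vectors(rng, 50, 6)
        perm = rng.permutation(50)
        xp, yp = x[perm], y[perm]
        assert spearman(x, y).rho == pytest.approx(spearman(xp, yp).rho)
        t1, t2 = cross_table(x, y, 6), cross_table(xp, yp, 6)
        assert np.array_equal(t1.counts, t2.counts)
        w = linear_weights(6)
        assert weighted_kappa(t1, w).kappa == pytest.approx(
            weighted_kappa(t2, w).kappa
        )


class TestCriteria:
    @pytest.mark.parametrize(
        "scc,exact,adj,extreme,kappa,expected",
        [
            # whole-sample app-vs-FFQ averages: everything passes
            (0.67, 50.7, 90.2, 0.0, 0.49, (True, True, True, True, True)),
            # weak correlation and poor kappa fail those two criteria
            (0.29, 40.0, 80.0, 0.0, 0.18, (False, True, True, True, False)),
            # thresholds are inclusive on the boundary
            (0.5, 35.0, 75.0, 8.0, 0.41, (True, True, True, True, True)),
            (0.499, 34.9, 74.9, 8.1, 0.409, (False,) * 5),
        ],
    )
    def test_verdicts(self, scc, exact, adj, extreme, kappa, expected):
        s = AgreementSummary(
            food_group="fruit", method_pair="app_vs_ffq", stratum="all",
            n=203, scc=scc, exact_pct=exact, exact_adjacent_pct=adj,
            extreme_pct=extreme, kappa_w=kappa,
        )
        v = evaluate_criteria(s)
        assert (v.scc_ok, v.exact_ok, v.adjacent_ok, v.extreme_ok, v.kappa_ok) == expected
        assert v.overall == all(expected)


class TestAverageRow:
    def _row(self, g, scc, kappa=0.5):
        return AgreementSummary(
            food_group=g, method_pair="app_vs_ffq", stratum="all", n=100,
            scc=scc, exact_pct=50.0, exact_adjacent_pct=90.0,
            extreme_pct=0.0, kappa_w=kappa,
        )

    def test_identical_rows_average_to_themselves(self):
        avg = average_over_groups([self._row(f"g{i}", 0.5) for i in range(10)])
        assert avg.scc == pytest.approx(0.5)

    def test_mean_of_two(self):
        avg = average_over_groups([self._row("a", 0.4), self._row("b", 0.6)])
        assert avg.scc == pytest.approx(0.5)

    def test_average_carries_no_interval(self):
        avg = average_over_groups([self._row("a", 0.4), self._row("b", 0.6)])
        assert avg.scc_ci_low is None and avg.scc_p is None
        assert avg.kappa_se is None

    def test_undefined_cells_excluded(self):
        rows = [self._row("a", 0.4), self._row("b", 0.6)]
        rows.append(
            AgreementSummary(
                food_group="c", method_pair="app_vs_ffq", stratum="all",
                n=100, scc=None, exact_pct=50.0, exact_adjacent_pct=90.0,
                extreme_pct=0.0, kappa_w=0.5,
            )
        )
        avg = average_over_groups(rows)
        assert avg.scc == pytest.approx(0.5)  # mean over the two defined rows
        assert avg.exact_pct == pytest.approx(50.0)
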