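import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rankagree as ra
import oracles

EXAMPLE = ra.ContingencyTable(np.array([[2, 1], [0, 2]]))


def tables(max_C=5, max_n=12):
    """Hypothesis strategy: random small contingency tables as count lists."""
    return st.integers(1, max_C).flatmap(
        lambda C: st.lists(
            st.tuples(st.integers(0, C - 1), st.integers(0, C - 1)),
            min_size=1, max_size=max_n,
        ).map(lambda pairs: ra.ContingencyTable.from_pairs(
            [p[0] for p in pairs], [p[1] for p in pairs], C))
    )


class TestPercentageAgreement:
    def test_diagonal_is_full_agreement(self):
        table = ra.ContingencyTable(np.diag([3, 2, 5]))
        assert ra.percentage_agreement(table) == 100.0

    def test_example_table(self):
        assert ra.percentage_agreement(EXAMPLE, 0) == 80.0

    def test_sum_score_pairs_with_tolerance(self):
        table = ra.ContingencyTable.from_pairs([10, 12, 14], [11, 12, 16], 17)
        assert ra.percentage_agreement(table, 0) == pytest.approx(100 / 3)
        assert ra.percentage_agreement(table, 1) == pytest.approx(200 / 3)
        assert ra.percentage_agreement(table, 2) == 100.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ra.ValidationError):
            ra.percentage_agreement(EXAMPLE, -1)


class TestMinTolerance:
    def test_perfect_agreement_needs_none(self):
        assert ra.min_tolerance(ra.ContingencyTable(np.diag([4]))) == 0

    def test_sum_score_pairs(self):
        table = ra.ContingencyTable.from_pairs([10, 12, 14], [11, 12, 16], 17)
        assert ra.min_tolerance(table, 70) == 2
        assert ra.min_tolerance(table, 100) == 2

    def test_terminates_at_C_minus_1(self):
        worst = ra.ContingencyTable.from_pairs([0, 3], [3, 0], 4)
        assert ra.min_tolerance(worst, 100) == 3


class TestPointEstimates:
    def test_example_table_values(self):
        assert ra.relative_position(EXAMPLE) == pytest.approx(0.2)
        assert ra.relative_rank_variance(EXAMPLE) == 0.0
        assert ra.roc_points(EXAMPLE).points == ((0.0, 0.0), (0.6, 0.4), (1.0, 1.0))

    def test_maximal_upward_shift(self):
        table = ra.ContingencyTable.from_pairs([0] * 7, [1] * 7, 2)
        assert ra.relative_position(table) == 1.0

    def test_two_category_tables_have_zero_rc(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=(2, 2))
            if counts.sum() == 0:
                continue
            assert ra.relative_concentration(counts) == 0.0

    def test_rc_extreme_vs_central(self):
        # first assessment at the extremes, second all central
        counts = np.zeros((3, 3), int)
        counts[0, 1] = 2
        counts[2, 1] = 2
        assert ra.relative_concentration(counts) == pytest.approx(0.5)

    def test_uniform_2x2_rank_variance(self):
        assert ra.relative_rank_variance([[1, 1], [1, 1]]) == pytest.approx(0.1875)

    def test_single_category_degenerate(self):
        table = ra.ContingencyTable(np.array([[4]]))
        assert ra.percentage_agreement(table) == 100.0
        assert ra.relative_position(table) == 0.0
        assert ra.relative_concentration(table) == 0.0
        assert ra.relative_rank_variance(table) == 0.0
        assert ra.roc_points(table).points == ((0.0, 0.0), (1.0, 1.0))

    def test_rp_from_marginals_matches_table(self, rng):
        counts = oracles.random_table(rng, max_C=4, max_n=12)
        table = ra.ContingencyTable(np.maximum(counts, 0) + np.eye(counts.shape[0], dtype=int))
        p = table.a / table.n
        q = table.b / table.n
        assert ra.relative_position_from_marginals(p, q) == pytest.approx(
            ra.relative_position(table), abs=1e-12)


class TestAugmentedRanks:
    def test_single_cell_all_tied(self):
        ranks = ra.augmented_mean_ranks(np.array([[5]]))
        assert ranks.r1[0, 0] == ranks.r2[0, 0] == 3.0

    def test_example_table_cells(self):
        ranks = ra.augmented_mean_ranks(EXAMPLE)
        assert (ranks.r1[0, 0], ranks.r2[0, 0]) == (1.5, 1.5)
        assert (ranks.r1[0, 1], ranks.r2[0, 1]) == (3.0, 3.0)
        assert (ranks.r1[1, 1], ranks.r2[1, 1]) == (4.5, 4.5)

    def test_antidiagonal_cells(self):
        ranks = ra.augmented_mean_ranks(np.array([[0, 1], [1, 0]]))
        assert (ranks.r1[0, 1], ranks.r2[0, 1]) == (1.0, 2.0)
        assert (ranks.r1[1, 0], ranks.r2[1, 0]) == (2.0, 1.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tables())
    def test_rank_sums_are_conserved(self, table):
        ranks = ra.augmented_mean_ranks(table)
        n = table.n
        mask = table.counts > 0
        expected = n * (n + 1) / 2
        assert (table.counts[mask] * ranks.r1[mask]).sum() == pytest.approx(expected)
        assert (table.counts[mask] * ranks.r2[mask]).sum() == pytest.approx(expected)


class TestOracleEquivalence:
    """The closed forms against exhaustive subject-level enumeration."""

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(tables())
    def test_all_measures_match_enumeration(self, table):
        pairs = oracles.table_pairs(table.counts)
        assert ra.percentage_agreement(table, 1) == pytest.approx(
            oracles.pa_oracle(pairs, 1), abs=1e-12)
        assert ra.relative_position(table) == pytest.approx(
            oracles.rp_oracle(pairs), abs=1e-12)
        assert ra.relative_concentration(table) == pytest.approx(
            oracles.rc_oracle(pairs), abs=1e-12)
        assert ra.relative_rank_variance(table) == pytest.approx(
            oracles.rv_oracle(pairs), abs=1e-12)


class TestInvariances:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tables())
    def test_transpose_antisymmetry(self, table):
        t = table.transpose()
        assert ra.relative_position(t) == pytest.approx(-ra.relative_position(table), abs=1e-12)
        assert ra.relative_concentration(t) == pytest.approx(-ra.relative_concentration(table), abs=1e-12)
        assert ra.relative_rank_variance(t) == pytest.approx(ra.relative_rank_variance(table), abs=1e-12)
        assert ra.percentage_agreement(t) == pytest.approx(ra.percentage_agreement(table))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tables())
    def test_category_reversal_flips_rp(self, table):
        rev = ra.ContingencyTable(table.counts[::-1, ::-1].copy())
        assert ra.relative_position(rev) == pytest.approx(-ra.relative_position(table), abs=1e-12)
        assert ra.percentage_agreement(rev) == pytest.approx(ra.percentage_agreement(table))
        assert ra.relative_rank_variance(rev) == pytest.approx(ra.relative_rank_variance(table), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(tables(max_C=4))
    def test_pa_nondecreasing_in_tolerance(self, table):
        pas = [ra.percentage_agreement(table, k) for k in range(table.C)]
        assert all(lo <= hi + 1e-12 for lo, hi in zip(pas, pas[1:]))
        assert pas[-1] == pytest.approx(100.0)

    def test_marginal_dependence_only(self, rng):
        """RP, RC and the ROC curve see only the marginals: shuffling which
        x goes with which y changes none of them."""
        for _ in range(25):
            counts = oracles.random_table(rng, max_C=5, max_n=12)
            if counts.sum() < 2:
                continue
            pairs = oracles.table_pairs(counts)
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            rng.shuffle(ys)
            other = ra.ContingencyTable.from_pairs(xs, ys, counts.shape[0])
            table = ra.ContingencyTable(counts)
            assert ra.relative_position(other) == pytest.approx(
                ra.relative_position(table), abs=1e-12)
            assert ra.relative_concentration(other) == pytest.approx(
                ra.relative_concentration(table), abs=1e-12)
            assert ra.roc_points(other).points == ra.roc_points(table).points

    @pytest.mark.parametrize("C", [5, 20])
    def test_independent_assessments_approach_analytic_rv_limit(self, rng, C):
        """Under independence with uniform marginals the population RV is
        (1 - 1/C)^2 (C^2 - 1) / C^2: ties depress it below 1 on coarse
        scales, and it tends to 1 as the number of categories grows."""
        x = rng.integers(0, C, size=4000)
        y = rng.integers(0, C, size=4000)
        rv = ra.relative_rank_variance(ra.ContingencyTable.from_pairs(x, y, C))
        limit = (1 - 1 / C) ** 2 * (C**2 - 1) / C**2
        assert rv == pytest.approx(limit, abs=0.08)

    def test_identical_assessments_have_no_disagreement(self, rng):
        x = rng.integers(0, 4, size=200)
        table = ra.ContingencyTable.from_pairs(x, x, 4)
        est = ra.agreement_estimates(table, tolerances=(1,))
        assert est.PA == 100.0 and est.min_k == 0
        assert est.RP == est.RC == est.RV == 0.0


class TestRocCurve:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tables())
    def test_endpoints_and_monotonicity(self, table):
        curve = ra.roc_points(table)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        assert np.all(np.diff(curve.u) >= 0) and np.all(np.diff(curve.v) >= 0)

    def test_identical_marginals_lie_on_diagonal(self):
        # symmetric counts => equal marginals
        sym = ra.ContingencyTable(np.array([[2, 1], [1, 3]]))
        curve = ra.roc_points(sym)
        assert np.allclose(curve.u, curve.v)
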