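import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortomorph.stats import (
    ContingencyTable,
    correlation_matrix,
    fisher_exact_rxc,
    format_p,
    interrater_agreement,
    kruskal_wallis_dunn,
    mann_whitney,
    spearman,
)

from oracles import oracle_freeman_halton, oracle_mann_whitney

# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_disjoint_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.exact

    def test_identical_samples(self):
        res = mann_whitney([1.5, 2.5, 3.5], [1.5, 2.5, 3.5])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(6):
            x = rng.normal(size=8)
            y = rng.normal(0.5, 1.0, size=8)
            res = mann_whitney(x, y)
            assert res.exact
            assert res.p_value == pytest.approx(
                oracle_mann_whitney(x, y), abs=1e-12
            )

    def test_ties_use_asymptotic(self):
        res = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert not res.exact
        assert 0 < res.p_value <= 1

    def test_large_samples_asymptotic(self, rng):
        res = mann_whitney(rng.normal(size=30), rng.normal(size=30))
        assert not res.exact

    def test_p_in_unit_interval(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=7)
            p = mann_whitney(x, y).p_value
            assert 0 < p <= 1


# ---------------------------------------------------------------------------
# Fisher / Freeman-Halton
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_proportional_rows_p1(self):
        assert fisher_exact_rxc([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_hand_enumeration_2x2(self):
        # [[2,3],[4,1]]: five admissible tables, sum of P <= P_obs = 0.5238
        assert fisher_exact_rxc([[2, 3], [4, 1]]).p_value == pytest.approx(
            0.5238, abs=5e-5
        )

    @pytest.mark.parametrize(
        "table,printed",
        [
            ([[1, 16], [9, 9]], 0.0072),
            ([[0, 17], [11, 7]], 0.0001),
            ([[2, 15], [12, 6]], 0.0016),
            ([[3, 14], [14, 4]], 0.0006),
            ([[6, 11], [12, 6]], 0.0943),
            ([[12, 5], [7, 11]], 0.0922),
            ([[4, 0], [9, 16], [4, 2]], 0.0299),
            ([[6, 4, 7], [2, 8, 8]], 0.2185),
            ([[14, 0, 3], [9, 3, 6]], 0.0793),
        ],
    )
    def test_reproduces_published_2group_tables(self, table, printed):
        assert round(fisher_exact_rxc(table).p_value, 4) == printed

    def test_scipy_agreement_2x2(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            ours = fisher_exact_rxc(t.tolist()).p_value
            theirs = scipy_fisher(t)[1]
            assert ours == pytest.approx(theirs, abs=1e-10)

    @given(
        cells=st.lists(st.integers(0, 6), min_size=4, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_2x2_matches_rational_oracle(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        arr = np.array(t)
        if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
            return
        assert fisher_exact_rxc(t).p_value == pytest.approx(
            oracle_freeman_halton(t), abs=1e-10
        )

    @given(
        cells=st.lists(st.integers(0, 4), min_size=6, max_size=6),
    )
    @settings(max_examples=40, deadline=None)
    def test_rxc_matches_rational_oracle(self, cells):
        t = [cells[:3], cells[3:]]
        arr = np.array(t)
        if (arr.sum(0) == 0).any() or (arr.sum(1) == 0).any():
            return
        if arr.sum() > 30:
            return
        assert fisher_exact_rxc(t).p_value == pytest.approx(
            oracle_freeman_halton(t), abs=1e-10
        )

    def test_permutation_and_transpose_invariance(self):
        t = np.array([[4, 0], [9, 16], [4, 2]])
        base = fisher_exact_rxc(t.tolist()).p_value
        assert fisher_exact_rxc(t[::-1].tolist()).p_value == pytest.approx(base)
        assert fisher_exact_rxc(t[:, ::-1].tolist()).p_value == pytest.approx(base)
        assert fisher_exact_rxc(t.T.tolist()).p_value == pytest.approx(base)

    def test_enumeration_cap(self):
        t = [[50, 60, 70], [80, 90, 100], [60, 70, 80]]
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_rxc(t, max_tables=1000)

    def test_monte_carlo_fallback_close_to_exact(self):
        t = [[6, 4, 7], [2, 8, 8]]
        exact = fisher_exact_rxc(t).p_value
        mc = fisher_exact_rxc(t, max_tables=10, monte_carlo=True,
                              mc_draws=20000, seed=1)
        assert not mc.exact
        assert mc.p_value == pytest.approx(exact, abs=0.02)

    def test_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_array([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            ContingencyTable.from_array([[1, 2]])
        with pytest.raises(ValueError, match="margins"):
            fisher_exact_rxc([[0, 0], [1, 2]])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


class TestKruskalWallisDunn:
    def test_hand_computed_h(self):
        om, _ = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert om.statistic == pytest.approx(7.2)  # 12/90 * 279 - 30

    def test_all_identical_values(self):
        om, pw = kruskal_wallis_dunn([[2, 2], [2, 2], [2, 2]])
        assert om.statistic == 0.0 and om.p_value == 1.0
        assert all(p.p_value == 1.0 for p in pw)

    def test_identical_pair_dunn_p_one(self):
        _, pw = kruskal_wallis_dunn([[1, 2, 3], [1, 2, 3], [10, 11, 12]])
        first_pair = next(p for p in pw if p.extra["pair"] == (0, 1))
        assert first_pair.statistic == pytest.approx(0.0)
        assert first_pair.p_value == 1.0

    def test_dunn_adjusted_ge_unadjusted(self, rng):
        groups = [rng.normal(loc, 1.0, size=6) for loc in (0, 0.5, 1.5)]
        _, pw = kruskal_wallis_dunn(groups)
        for p in pw:
            assert p.p_value >= p.extra["p_unadjusted"] - 1e-15
            assert p.adjustment == "dunn-bonferroni"

    def test_number_of_pairs(self):
        _, pw = kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert len(pw) == 6

    def test_scipy_h_agreement_with_ties(self, rng):
        from scipy.stats import kruskal

        groups = [rng.integers(0, 4, size=8).astype(float) for _ in range(3)]
        om, _ = kruskal_wallis_dunn(groups)
        h, p = kruskal(*groups)
        assert om.statistic == pytest.approx(h)
        assert om.p_value == pytest.approx(p)


# ---------------------------------------------------------------------------
# Spearman & inter-rater
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 5], [2, 4, 9, 12]).statistic == pytest.approx(1.0)

    def test_hand_example(self):
        # d² = (0,1,1,0) -> rho = 1 - 6*2/60 = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).statistic == pytest.approx(0.8)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman(x, y**3 + 5 * y).statistic == pytest.approx(base)

    def test_constant_flagged_undefined(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.statistic)
        assert res.extra["undefined"]

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])

    def test_correlation_matrix_structure(self, rng):
        data = {
            "a": rng.normal(size=15),
            "b": rng.normal(size=15),
            "c": rng.normal(size=15),
        }
        cm = correlation_matrix(data)
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert np.allclose(cm.rho, cm.rho.T)
        assert (np.abs(cm.rho) <= 1.0 + 1e-12).all()


class TestInterrater:
    def test_identical_raters(self):
        scores = np.array([[1, 1], [2, 2], [3, 3], [1, 1], [2, 2]])
        tab = interrater_agreement(scores)
        assert tab["rho"].iloc[0] == pytest.approx(1.0)

    def test_monotone_relabeling_hand_example(self):
        # rater B maps (1,2,3)->(1,3,3); mid-rank rho computed by hand:
        # a=(1,2,3,1,2), b=(1,3,3,1,3); ranks a=(1.5,3.5,5,1.5,3.5),
        # b=(1.5,4,4,1.5,4) -> pearson(ranks) = 0.9186 (3 dp)
        a = [1, 2, 3, 1, 2]
        b = [1, 3, 3, 1, 3]
        tab = interrater_agreement(np.column_stack([a, b]))
        from scipy.stats import rankdata

        ra, rb = rankdata(a), rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert tab["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_rater_flagged(self):
        scores = np.array([[1, 2], [1, 3], [1, 1], [1, 2]])
        tab = interrater_agreement(scores)
        assert not tab["defined"].iloc[0]

    def test_concordant_simulation(self):
        from aortomorph.synth import CohortSpec, generate_cohort

        subjects, _ = generate_cohort(CohortSpec(seed=42, rater_noise_sd=0.3))
        tab = interrater_agreement(
            subjects[["score_rater1", "score_rater2", "score_rater3"]]
        )
        assert (tab["rho"] >= 0.7).all()

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            interrater_agreement(np.array([[1], [2], [3]]))
        with pytest.raises(ValueError):
            interrater_agreement(np.array([[1, 2], [2, 3]]))


class TestFormatP:
    def test_styles(self):
        assert format_p(0.0072) == "0.0072"
        assert format_p(0.00004) == "< 0.0001"
        assert format_p(0.00005) == "0.0001"
        assert format_p(1.0) == "1.0000"
        assert format_p(float("nan")) == "NA"
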