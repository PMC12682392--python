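"""Statistical chain: normality gate, categorical tests, logistic, ROC."""

import numpy as np
import pytest
from scipy import stats as sps

from aptwi.stats import (
    ContingencyTable2x2,
    SeparationError,
    chi_square_2x2,
    compare_groups,
    delong_test,
    delong_variance,
    fisher_exact_2x2,
    fisher_rxc_montecarlo,
    roc_analysis,
    shapiro_wilk,
    stepwise_logistic,
    univariate_logistic,
)


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)

    def test_matches_independent_reference_implementation(self):
        # reference W/p from R 4.3.3 shapiro.test on the same sample
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.788815, abs=1e-3)
        assert p == pytest.approx(0.006704, abs=1e-3)

    def test_large_normal_sample_not_rejected(self):
        x = np.random.default_rng(1234).standard_normal(5000)
        _, p = shapiro_wilk(x)
        assert p > 0.01

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.random.default_rng(0).normal(size=5001))


class TestCompareGroups:
    def test_identical_groups(self, rng):
        x = rng.normal(size=30)
        vals = np.concatenate([x, x])
        g = np.r_[np.zeros(30), np.ones(30)]
        res = compare_groups(vals, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_normal_groups_significant(self, rng):
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        g = np.r_[np.zeros(50), np.ones(50)]
        res = compare_groups(vals, g)
        assert res.test_used in ("t", "welch_t")
        assert res.p_value < 1e-3

    def test_skewed_data_routes_to_mann_whitney(self, rng):
        vals = np.r_[rng.lognormal(0, 1.5, 40), rng.lognormal(0.5, 1.5, 40)]
        g = np.r_[np.zeros(40), np.ones(40)]
        res = compare_groups(vals, g)
        assert res.test_used == "mann_whitney"

    def test_unequal_variance_routes_to_welch(self, rng):
        vals = np.r_[rng.normal(0, 1, 60), rng.normal(0, 5, 60)]
        g = np.r_[np.zeros(60), np.ones(60)]
        res = compare_groups(vals, g)
        assert res.test_used in ("welch_t", "mann_whitney")
        if res.normal:
            assert res.test_used == "welch_t"

    def test_bad_groupings_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3, 4], [0, 0, 1, 1])  # n<3 per group


class TestChiSquare:
    # printed 2x2 statistics of the source cohort (rows: level yes/no,
    # cols: responder / non-responder)
    CASES = [
        ((11, 43, 32, 22), 17.040, False),   # ER
        ((10, 34, 33, 31), 9.047, False),    # PR
        ((26, 14, 17, 51), 16.816, False),   # HER2
        ((26, 40, 17, 25), 0.013, False),    # lymph node
        ((31, 45, 12, 20), 0.102, False),    # histological grade
        ((35, 58, 8, 7), 1.328, False),      # enhancement pattern
        ((42, 54, 1, 11), 4.203, True),      # Ki-67, Yates (min expected 4.78)
    ]

    @pytest.mark.parametrize("cells,want,corrected", CASES)
    def test_reproduces_printed_statistics(self, cells, want, corrected):
        res = chi_square_2x2(ContingencyTable2x2(*cells))
        assert res.statistic == pytest.approx(want, abs=5e-4)
        assert res.correction_applied == corrected

    def test_proportional_table_gives_zero(self):
        res = chi_square_2x2(ContingencyTable2x2(10, 20, 10, 20))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 7))

    def test_textbook_formula_identity(self, rng):
        """Uncorrected Pearson statistic equals n(ad-bc)^2 / product of
        margins, on random tables with all expected counts >= 5."""
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(5, 60, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            if t.expected().min() < 5:
                continue
            res = chi_square_2x2(t)
            n = a + b + c + d
            want = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(want, abs=1e-9)
            checked += 1


def _fisher_enumeration(t: ContingencyTable2x2) -> float:
    """Brute-force two-sided Fisher p: enumerate all fixed-margin tables."""
    r1, c1, n = t.a + t.b, t.a + t.c, t.n
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {a: sps.hypergeom.pmf(a, n, c1, r1) for a in range(lo, hi + 1)}
    p_obs = probs[t.a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        assert fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(1 / 3)

    def test_single_column_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(4, 0, 7, 0)) == pytest.approx(1.0)

    def test_matches_full_enumeration(self, rng):
        for _ in range(50):
            cells = rng.integers(0, 12, size=4)
            if cells.sum() == 0:
                continue
            t = ContingencyTable2x2(*map(int, cells))
            assert fisher_exact_2x2(t) == pytest.approx(
                _fisher_enumeration(t), abs=1e-9)


class TestFisherMonteCarlo:
    def test_agrees_with_exact_2x2(self):
        t = ContingencyTable2x2(8, 2, 3, 9)
        exact = fisher_exact_2x2(t)
        p, se = fisher_rxc_montecarlo(t.array, reps=20000, seed=42)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_independent_table_large_p(self):
        table = np.array([[30, 60, 30], [20, 40, 20]])
        p, _ = fisher_rxc_montecarlo(table, reps=10000, seed=1)
        assert p > 0.5

    def test_seed_determinism_and_reps_floor(self):
        table = np.array([[5, 1], [2, 8]])
        p1, _ = fisher_rxc_montecarlo(table, reps=10000, seed=7)
        p2, _ = fisher_rxc_montecarlo(table, reps=10000, seed=7)
        assert p1 == p2
        with pytest.raises(ValueError):
            fisher_rxc_montecarlo(table, reps=500, seed=0)


def _expand_counts(a, b, c, d):
    """Patient-level binary records from 2x2 counts (x, y)."""
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return x, y


class TestUnivariateLogistic:
    PRINTED = [
        ((11, 32, 43, 22), 0.18, -1.74),   # ER+ (a=pos responders)
        ((26, 17, 14, 51), 5.57, 1.72),    # HER2+
    ]

    @pytest.mark.parametrize("counts,want_or,want_beta", PRINTED)
    def test_reproduces_printed_odds_ratios(self, counts, want_or, want_beta):
        a, b, c, d = counts
        x, y = _expand_counts(a, b, c, d)
        m = univariate_logistic(x, y, name="marker")
        t = m.term("marker")
        assert round(t.odds_ratio, 2) == want_or
        assert round(t.beta, 2) == want_beta
        assert t.odds_ratio == pytest.approx(np.exp(t.beta))
        assert t.ci_low == pytest.approx(np.exp(t.beta - 1.96 * t.se))

    def test_binary_or_equals_cross_product(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(3, 40, size=4)
            x, y = _expand_counts(int(a), int(b), int(c), int(d))
            m = univariate_logistic(x, y)
            assert m.term("x").odds_ratio == pytest.approx(
                (a * d) / (b * c), rel=1e-6)

    def test_perfect_separation_raises(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        y = x.copy()
        with pytest.raises(SeparationError):
            univariate_logistic(x, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_logistic([0.0, 1.0, 0.0], [1, 1, 1])


class TestStepwise:
    def _cohort(self, rng, n=300, beta=np.log(5.0)):
        x = (rng.random(n) < 0.5).astype(float)
        noise = {f"noise_{i}": rng.standard_normal(n) for i in range(4)}
        p = 1 / (1 + np.exp(-(-0.8 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        return {"signal": x, **noise}, y

    def test_strong_predictor_selected_among_noise(self):
        # the true predictor always enters; noise co-admissions happen at the
        # nominal rate (~1 - 0.95^4 per replicate with 4 noise candidates)
        selected = alone = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            cand, y = self._cohort(rng)
            if np.unique(y).size < 2:
                continue
            m = stepwise_logistic(cand, y)
            selected += "signal" in m.term_names
            alone += m.term_names == ("signal",)
        assert selected >= 24
        assert alone >= 15

    def test_all_noise_usually_intercept_only(self):
        import warnings
        empty = 0
        for seed in range(25):
            rng = np.random.default_rng(2000 + seed)
            cand = {f"n{i}": rng.standard_normal(200) for i in range(4)}
            y = (rng.random(200) < 0.4).astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = stepwise_logistic(cand, y)
            if not m.terms:
                empty += 1
        # family-wise admit rate ~ 4 * 0.05
        assert empty >= 15

    def test_duplicated_predictor_admitted_once(self, rng):
        x = (rng.random(400) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-(-0.5 + 2.0 * x)))
        y = (rng.random(400) < p).astype(float)
        m = stepwise_logistic({"a_copy": x.copy(), "b_orig": x}, y)
        assert len(m.terms) == 1
        assert m.term_names == ("a_copy",)  # lexicographic tie-break


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert r.cutoff == 3

    def test_three_quarters_from_pair_enumeration(self):
        r = roc_analysis([3, 1, 2, 4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_ties_count_half_matches_pair_oracle(self, rng):
        scores = rng.integers(0, 5, size=60).astype(float)
        labels = rng.integers(0, 2, size=60)
        if np.unique(labels).size < 2:
            labels[0], labels[1] = 0, 1
        r = roc_analysis(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]).sum()
        want = pairs / (pos.size * neg.size)
        assert max(r.auc, 1 - r.auc) == pytest.approx(max(want, 1 - want))

    def test_anti_predictor_flips_orientation(self):
        # lower scores mark the positive class -> flipped orientation
        r = roc_analysis([1, 2, 3, 4], [1, 1, 0, 0])
        assert r.auc == 1.0 and r.orientation == "<="

    def test_accuracy_identity(self, rng):
        scores = rng.normal(size=50) + np.r_[np.zeros(25), np.ones(25)]
        labels = np.r_[np.zeros(25), np.ones(25)].astype(int)
        r = roc_analysis(scores, labels)
        tp, fn, tn, fp = r.counts
        assert r.accuracy == pytest.approx(100 * (tp + tn) / 50)
        # cutoff attains max Youden J among all observed thresholds
        best = max(
            (np.mean(scores[labels == 1] >= c) + np.mean(scores[labels == 0] < c))
            for c in scores)
        got = (tp / (tp + fn)) + (tn / (tn + fp))
        assert got == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def _paired(self, rng, n=40):
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        a = rng.normal(size=n) + y
        b = 0.7 * a + rng.normal(size=n) * 0.5
        return a, b, y

    def test_identical_classifiers(self, rng):
        a, _, y = self._paired(rng)
        with pytest.raises(ValueError):
            delong_test(a, a, y)

    def test_swap_negates_z(self, rng):
        a, b, y = self._paired(rng)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_variance_matches_jackknife(self, rng):
        """DeLong AUC variance within 10% of the leave-one-out jackknife."""
        a, _, y = self._paired(rng, n=40)
        auc, var = delong_variance(a, y)
        n = y.size
        loo = np.array([
            delong_variance(np.delete(a, i), np.delete(y, i))[0]
            for i in range(n)
        ])
        jack = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert var == pytest.approx(jack, rel=0.10)
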