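"""Statistical metrics against hand-computed values and enumeration oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

from melb.errors import ValidationError
from melb.metrics import (ConfusionCounts, cohens_kappa, correlation, cui,
                          cui_grade, fisher_odds_ratio, mcc, roc_auc, welch_t)


class TestMCC:
    @pytest.mark.parametrize("counts,expected", [
        (dict(tp=10, tn=10, fp=0, fn=0), 1.0),
        (dict(tp=0, tn=0, fp=5, fn=5), -1.0),
        (dict(tp=6, fp=2, fn=1, tn=8), 46 / math.sqrt(5040)),  # 0.6479...
    ])
    def test_hand_computed(self, counts, expected):
        assert mcc(ConfusionCounts(**counts)) == pytest.approx(expected, abs=1e-6)

    def test_zero_marginal_is_zero(self):
        assert mcc(ConfusionCounts(tp=0, fn=0, fp=3, tn=7)) == 0.0

    def test_label_swap_symmetry(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
            sw = ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)
            assert mcc(c) == pytest.approx(mcc(sw), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = ConfusionCounts.from_labels(y.astype(bool), p.astype(bool))
        assert mcc(c) == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


class TestCUI:
    def test_se_ppv_product_and_grade(self):
        # Se=0.9, PPV=0.8: tp=36, fn=4, fp=9 -> CUI+ = 0.72, "good"
        c = ConfusionCounts(tp=36, fn=4, fp=9, tn=51)
        out = cui(c)
        assert out["cui_pos"] == pytest.approx(0.72)
        assert out["grade_pos"] == "good"

    def test_perfect_classifier_excellent(self):
        out = cui(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert out["cui_pos"] == out["cui_neg"] == 1.0
        assert out["grade_pos"] == out["grade_neg"] == "excellent"

    @pytest.mark.parametrize("value,grade", [
        (0.48, "poor"), (0.49, "satisfactory"), (0.64, "good"),
        (0.81, "excellent"), (0.809, "good")])
    def test_grade_boundaries_closed_left(self, value, grade):
        assert cui_grade(value) == grade

    def test_undefined_ppv_flagged(self):
        out = cui(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
        assert out["grade_pos"] == "undefined"


class TestKappa:
    def test_hand_computed(self):
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_perfect_diagonal(self):
        assert cohens_kappa([[7, 0], [0, 13]]) == 1.0

    def test_independence_table_zero(self):
        # margins (30, 70) x (40, 60) in proportion: p_o == p_e
        assert cohens_kappa([[12, 18], [28, 42]]) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        a = rng.integers(0, 2, 80)
        b = rng.integers(0, 2, 80)
        t = [[np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
             [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))]]
        assert cohens_kappa(t) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestAUC:
    def test_examples(self):
        assert roc_auc([0.8, 0.9], [0.1, 0.2]) == 1.0
        assert roc_auc([0.9, 0.4], [0.6, 0.1]) == 0.75  # 3 of 4 concordant
        assert roc_auc([0.2, 0.5, 0.7], [0.2, 0.5, 0.7]) == 0.5

    def test_agrees_with_sklearn_and_monotone_invariance(self, rng):
        pos = rng.random(20)
        neg = rng.random(15)
        y = np.r_[np.ones(20), np.zeros(15)]
        s = np.r_[pos, neg]
        assert roc_auc(pos, neg) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        transformed = np.exp(3 * s)  # strictly monotone
        assert roc_auc(transformed[:20], transformed[20:]) == \
            pytest.approx(roc_auc(pos, neg), abs=1e-12)


def _fisher_enumeration_p(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration
    (probability-mass rule)."""
    a, b, c, d = np.asarray(table).ravel()
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    probs = {x: comb(c1, x, exact=True) * comb(n - c1, r1 - x, exact=True)
             for x in range(lo, hi + 1)}
    total = sum(probs.values())
    obs = probs[a] / total
    return sum(v / total for v in probs.values() if v / total <= obs * (1 + 1e-12))


class TestFisher:
    def test_example_table(self):
        out = fisher_odds_ratio([[8, 2], [1, 9]])
        assert out["odds_ratio"] == pytest.approx(36.0)
        assert out["p_two_sided"] == pytest.approx(_fisher_enumeration_p([[8, 2], [1, 9]]),
                                                   abs=1e-12)

    def test_no_association(self):
        out = fisher_odds_ratio([[5, 5], [5, 5]])
        assert out["odds_ratio"] == 1.0
        assert out["p_two_sided"] == 1.0

    def test_zero_cell_haldane_flag(self):
        out = fisher_odds_ratio([[5, 0], [2, 7]])
        assert out["haldane_corrected"]
        assert np.isfinite(out["odds_ratio"])

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0:
                continue
            out = fisher_odds_ratio(t)
            assert out["p_two_sided"] == pytest.approx(
                _fisher_enumeration_p(t), abs=1e-9), t


class TestWelch:
    def test_identical_groups(self):
        out = welch_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert out["mean_diff"] == 0.0

    def test_shifted_groups(self):
        out = welch_t([1, 2, 3], [11, 12, 13])
        assert out["mean_diff"] == pytest.approx(-10.0)
        assert out["p"] < 0.01

    def test_constant_equal_groups_convention(self):
        out = welch_t([2.0, 2.0], [2.0, 2.0])
        assert out["p"] == 1.0

    def test_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 4)
        y = rng.normal(1.0, 1, 4)
        obs = abs(np.mean(x) - np.mean(y))
        pooled = np.r_[x, y]
        count = 0
        n_tot = 0
        for idx in combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(idx)] = True
            n_tot += 1
            if abs(pooled[sel].mean() - pooled[~sel].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_tot
        p_welch = welch_t(x, y)["p"]
        assert abs(p_welch - p_perm) < 0.12  # Monte-Carlo-free but approximate


class TestCorrelation:
    def test_affine_pearson(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = correlation(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman(self):
        x = np.array([-2.0, -1, 0.5, 1, 3])
        r_s, _ = correlation(x, x**3, "spearman")
        r_p, _ = correlation(x, x**3, "pearson")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        from scipy.stats import rankdata
        r_s, _ = correlation(x, y, "spearman")
        r_r, _ = correlation(rankdata(x), rankdata(y), "pearson")
        assert r_s == pytest.approx(r_r, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValidationError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
       st.integers(0, 40))
@settings(max_examples=60, deadline=None)
def test_mcc_bounded(tp, fp, tn, fn):
    if tp + fp + tn + fn == 0:
        return
    v = mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    assert -1.0 <= v <= 1.0
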