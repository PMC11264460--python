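import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from armgait.agreement import (AgreementError, BiasTest, ContingencyTable,
                               bias_test, binarize, contingency_metrics,
                               diff_tally, evaluate_agreement, networks_anova,
                               quadratic_weighted_kappa, score_accuracy,
                               score_mse)


def brute_force_kappa(r1, r2, k=5):
    """Pairwise-sum weighted kappa oracle, independent of the confusion matrix."""
    r1, r2 = np.asarray(r1), np.asarray(r2)
    n = len(r1)
    w = lambda i, j: 1 - (i - j) ** 2 / (k - 1) ** 2
    po = sum(w(a, b) for a, b in zip(r1, r2)) / n
    pe = sum(w(a, b) for a in r1 for b in r2) / n ** 2
    return (po - pe) / (1 - pe)


# -- accuracy / MSE / tally ------------------------------------------------

def test_accuracy_perfect_and_half():
    assert score_accuracy([1, 2, 3], [1, 2, 3]) == 100.0
    assert score_accuracy([1, 2], [1, 3]) == 50.0


def test_mse_examples():
    assert score_mse([1, 2, 3], [1, 2, 3]) == 0.0
    assert score_mse([0], [2]) == 4.0


def test_tally_examples():
    assert diff_tally([2] * 7, [2] * 7) == {0: 7, 1: 0, 2: 0, 3: 0, 4: 0}
    assert diff_tally([0, 4], [4, 4]) == {0: 1, 1: 0, 2: 0, 3: 0, 4: 1}


def test_random_vectors_match_counting_oracles():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(1, 40))
        p, r = rng.integers(0, 5, n), rng.integers(0, 5, n)
        assert score_accuracy(p, r) == pytest.approx(
            100.0 * sum(a == b for a, b in zip(p, r)) / n)
        assert score_mse(p, r) == pytest.approx(sum((a - b) ** 2 for a, b in zip(p, r)) / n)
        tally = diff_tally(p, r)
        assert sum(tally.values()) == n
        assert score_accuracy(p, r) == pytest.approx(100.0 * tally[0] / n)


def test_length_mismatch_errors():
    with pytest.raises(AgreementError):
        score_accuracy([1], [1, 2])


# -- kappa -----------------------------------------------------------------

def test_identical_ratings_kappa_one():
    res = quadratic_weighted_kappa([0, 1, 2, 3, 4, 2], [0, 1, 2, 3, 4, 2],
                                   n_bootstrap=50)
    assert res.kappa == pytest.approx(1.0)
    assert not res.undefined


def test_single_category_is_undefined():
    res = quadratic_weighted_kappa([2] * 10, [2] * 10, n_bootstrap=10)
    assert res.undefined


def test_small_instances_match_brute_force_and_sklearn():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(2, 9))
        r1, r2 = rng.integers(0, 5, n), rng.integers(0, 5, n)
        if len(np.unique(np.concatenate([r1, r2]))) < 2:
            continue
        got = quadratic_weighted_kappa(r1, r2, n_bootstrap=2).kappa
        assert got == pytest.approx(brute_force_kappa(r1, r2), abs=1e-12)
        assert got == pytest.approx(
            cohen_kappa_score(r1, r2, labels=list(range(5)), weights="quadratic"),
            abs=1e-12)


def test_independent_raters_kappa_near_zero():
    rng = np.random.default_rng(42)
    r1 = rng.integers(0, 5, 400)
    r2 = rng.permutation(r1)
    res = quadratic_weighted_kappa(r1, r2, n_bootstrap=500, seed=1)
    assert abs(res.kappa) < 3 * res.se


def test_bootstrap_se_is_seeded_and_plausible():
    rng = np.random.default_rng(7)
    r1 = rng.integers(0, 5, 60)
    r2 = np.clip(r1 + rng.integers(-1, 2, 60), 0, 4)
    a = quadratic_weighted_kappa(r1, r2, n_bootstrap=300, seed=5)
    b = quadratic_weighted_kappa(r1, r2, n_bootstrap=300, seed=5)
    assert a == b
    asym = quadratic_weighted_kappa(r1, r2, se_method="asymptotic")
    assert asym.se == pytest.approx(a.se, rel=0.5)  # same order of magnitude
    assert -1 <= a.kappa <= 1


# -- bias test -------------------------------------------------------------

def test_bias_degenerate_when_no_differences():
    bt = bias_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert bt == BiasTest(0.0, 1.0, 0.0, 0.0, degenerate=True)


def test_cohens_d_matches_formula():
    pred = np.array([0, 0, 0, 1])
    ref = np.array([1, 1, 1, 1])
    bt = bias_test(pred, ref)
    diffs = pred - ref
    assert bt.mean_diff == pytest.approx(diffs.mean())
    assert bt.cohens_d == pytest.approx(diffs.mean() / diffs.std(ddof=1))
    assert bt.mean_diff < 0  # under-prediction is negative by convention


def test_bias_test_agrees_with_scipy_on_random_data():
    from scipy import stats
    rng = np.random.default_rng(0)
    pred, ref = rng.integers(0, 5, 30), rng.integers(0, 5, 30)
    bt = bias_test(pred, ref)
    t, p = stats.ttest_1samp(pred.astype(float) - ref, 0.0)
    assert (bt.t_stat, bt.p_value) == pytest.approx((t, p))


# -- ANOVA -----------------------------------------------------------------

def test_identical_groups_give_zero_f():
    g = [0.0, 1.0, -1.0, 0.5]
    F, p = networks_anova([g, g, g, g])
    assert F == pytest.approx(0.0, abs=1e-12)


def test_anova_matches_hand_computed_worked_example():
    # three groups, hand-computed one-way ANOVA
    g1, g2, g3 = [1, 2, 3], [2, 3, 4], [4, 5, 6]
    F, p = networks_anova([g1, g2, g3])
    # grand mean 10/3; SSB = 3*((2-10/3)^2+(3-10/3)^2+(5-10/3)^2) = 14
    # SSW = 6; F = (14/2)/(6/6) = 7
    assert F == pytest.approx(7.0)
    assert 0 < p < 1


def test_anova_null_p_roughly_uniform():
    rng = np.random.default_rng(6)
    ps = []
    for _ in range(400):
        groups = [rng.normal(0, 1, 20) for _ in range(4)]
        ps.append(networks_anova(groups)[1])
    ps = np.asarray(ps)
    assert 0.35 < np.mean(ps < 0.5) < 0.65
    assert np.mean(ps < 0.05) < 0.12


# -- binarisation and contingency -----------------------------------------

def test_binarize_boundary():
    assert binarize([0, 1, 2, 3, 4]).tolist() == [False, False, True, True, True]


def test_contingency_from_scores_matches_independent_recount():
    rng = np.random.default_rng(2)
    pred, ref = rng.integers(0, 5, 80), rng.integers(0, 5, 80)
    ct = ContingencyTable.from_scores(pred, ref)
    tp = sum(p >= 2 and r >= 2 for p, r in zip(pred, ref))
    fp = sum(p >= 2 and r < 2 for p, r in zip(pred, ref))
    fn = sum(p < 2 and r >= 2 for p, r in zip(pred, ref))
    tn = sum(p < 2 and r < 2 for p, r in zip(pred, ref))
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (tp, fp, fn, tn)
    assert ct.total == 80
    m = contingency_metrics(ct)
    assert m.recall == pytest.approx(tp / (tp + fn))
    assert m.precision == pytest.approx(tp / (tp + fp))
    assert m.accuracy == pytest.approx((tp + tn) / 80)
    assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))


def test_all_true_positive_metrics_are_one():
    m = contingency_metrics(ContingencyTable(tp=10, fp=0, fn=0, tn=0))
    assert (m.recall, m.precision, m.accuracy, m.f1) == (1.0, 1.0, 1.0, 1.0)


def test_zero_denominator_flagged():
    m = contingency_metrics(ContingencyTable(tp=0, fp=0, fn=5, tn=5))
    assert m.recall == 0.0
    assert np.isnan(m.precision)
    assert m.accuracy == 0.5
    assert "precision" in m.undefined and "f1" in m.undefined


# -- full battery ----------------------------------------------------------

def test_evaluate_agreement_is_consistent():
    rng = np.random.default_rng(14)
    ref = rng.integers(0, 5, 60)
    pred = np.clip(ref + rng.integers(-1, 2, 60), 0, 4)
    rep = evaluate_agreement(pred, ref, n_bootstrap=200, seed=3)
    assert rep.n == 60
    assert sum(rep.diff_tally.values()) == 60
    assert rep.accuracy_pct == pytest.approx(100 * rep.diff_tally[0] / 60)
    assert -1 <= rep.kappa.kappa <= 1
    d = rep.to_dict()
    assert set(d) >= {"accuracy_pct", "mse", "kappa", "recall", "f1"}
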