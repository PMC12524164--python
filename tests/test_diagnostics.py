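"""Diagnostic-statistics tests: AUC/cutoff oracles, correlation, kappa,
group tests and random-forest importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibroquant import diagnostics as dx


# ---------------------------------------------------------------------------
# brute-force oracles


def auc_pair_counting(scores, labels):
    """AUC as the fraction of positive-negative pairs correctly ordered."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def scan_youden(scores, labels):
    best_c, best_j = None, -np.inf
    for c in sorted(set(scores)):
        se = np.mean([s >= c for s, l in zip(scores, labels) if l == 1])
        sp = np.mean([s < c for s, l in zip(scores, labels) if l == 0])
        if se + sp - 1 > best_j + 1e-12:
            best_j, best_c = se + sp - 1, c
    return best_c


def scan_se(scores, labels, target):
    best = None
    for c in sorted(set(scores)):
        se = np.mean([s >= c for s, l in zip(scores, labels) if l == 1])
        if se >= target:
            best = c
    return best


def scan_sp(scores, labels, target):
    for c in sorted(set(scores)):
        sp = np.mean([s < c for s, l in zip(scores, labels) if l == 0])
        if sp >= target:
            return c
    return None


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_known_example():
    auc, _ = dx.roc_auc([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1], ci=False)
    assert auc == pytest.approx(8 / 9)


def test_auc_perfect_separation_and_symmetry():
    s = [1, 2, 3, 10, 11, 12]
    y = [0, 0, 0, 1, 1, 1]
    assert dx.roc_auc(s, y, ci=False)[0] == 1.0
    y_sw = [1 - v for v in y]
    assert dx.roc_auc(s, y_sw, ci=False)[0] == pytest.approx(0.0)


def test_auc_matches_pair_counting_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(300):
        n = rng.integers(6, 50)
        scores = rng.integers(0, 12, n).astype(float)  # ties guaranteed
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        auc, _ = dx.roc_auc(scores, labels, ci=False)
        assert auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)


def test_auc_mann_whitney_identity_tie_free():
    rng = np.random.default_rng(11)
    scores = rng.permutation(40).astype(float)
    labels = np.r_[np.ones(15, int), np.zeros(25, int)]
    auc, _ = dx.roc_auc(scores, labels, ci=False)
    u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    assert auc * 15 * 25 == pytest.approx(u)


def test_auc_ci_brackets_point_estimate_and_is_seeded():
    rng = np.random.default_rng(2)
    scores = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
    labels = np.r_[np.zeros(40, int), np.ones(40, int)]
    auc, ci1 = dx.roc_auc(scores, labels, n_boot=300, seed=9)
    _, ci2 = dx.roc_auc(scores, labels, n_boot=300, seed=9)
    assert ci1 == ci2
    assert ci1[0] <= auc <= ci1[1]


def test_single_class_errors():
    with pytest.raises(ValueError):
        dx.roc_auc([1, 2, 3], [1, 1, 1], ci=False)


# ---------------------------------------------------------------------------
# cutoffs


def test_youden_simple_case():
    assert dx.cutoff_youden([1, 2, 3, 4], [0, 0, 1, 1]) == 3.0


def test_youden_shift_equivariance():
    rng = np.random.default_rng(8)
    s = rng.normal(0, 1, 60)
    y = (s + rng.normal(0, 0.5, 60) > 0).astype(int)
    c = dx.cutoff_youden(s, y)
    assert dx.cutoff_youden(s + 10.0, y) == pytest.approx(c + 10.0)


def test_youden_degenerate_all_equal_scores():
    assert dx.cutoff_youden([5, 5, 5, 5], [0, 1, 0, 1]) == 5.0


def test_sensitivity_cutoff_example():
    scores = list(range(1, 11))
    labels = [0] * 5 + [1] * 5
    c, ok = dx.cutoff_at_sensitivity(scores, labels, 0.90)
    assert ok and c == 6.0


def test_sensitivity_target_one_forces_min_positive():
    scores = [1, 2, 3, 4, 5, 6]
    labels = [0, 1, 0, 1, 0, 1]
    c, ok = dx.cutoff_at_sensitivity(scores, labels, 1.0)
    assert ok and c == 2.0  # minimum positive score


def test_cutoffs_match_exhaustive_scan_on_random_instances():
    rng = np.random.default_rng(13)
    for _ in range(200):
        n = rng.integers(8, 40)
        scores = rng.integers(0, 15, n).astype(float)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        sl = list(zip(scores, labels))
        assert dx.cutoff_youden(scores, labels) == scan_youden(scores, labels)
        c_se, ok = dx.cutoff_at_sensitivity(scores, labels, 0.9)
        ref = scan_se(scores, labels, 0.9)
        if ref is not None:
            assert ok and c_se == ref
        c_sp, ok = dx.cutoff_at_specificity(scores, labels, 0.9)
        ref = scan_sp(scores, labels, 0.9)
        if ref is not None:
            assert ok and c_sp == ref
        else:
            assert not ok


def test_diagnostic_metrics_hand_table():
    # TP=9, FN=1, TN=8, FP=2 at cutoff 10
    scores = [10] * 9 + [5] + [10] * 2 + [5] * 8
    labels = [1] * 10 + [0] * 10
    m = dx.diagnostic_metrics(scores, labels, 10)
    assert m["Se"] == pytest.approx(90.0)
    assert m["Sp"] == pytest.approx(80.0)
    assert m["PPV"] == pytest.approx(81.8, abs=0.05)
    assert m["NPV"] == pytest.approx(88.9, abs=0.05)


def test_diagnostic_metrics_undefined_ppv_flagged():
    m = dx.diagnostic_metrics([1, 2], [0, 1], cutoff=5)
    assert np.isnan(m["PPV"]) and "PPV" in m["undefined"]


def test_metrics_invariant_under_monotone_transform():
    scores = np.array([1.0, 2, 3, 4, 5, 6])
    labels = np.array([0, 0, 1, 0, 1, 1])
    m1 = dx.diagnostic_metrics(scores, labels, 3.0)
    m2 = dx.diagnostic_metrics(np.exp(scores), labels, np.exp(3.0))
    assert (m1["Se"], m1["Sp"]) == (m2["Se"], m2["Sp"])


def test_evaluate_score_bundle_consistency():
    rng = np.random.default_rng(21)
    scores = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 30)]
    labels = np.r_[np.zeros(50, int), np.ones(30, int)]
    res = dx.evaluate_score(scores, labels, comparison="test", n_boot=200, seed=3)
    assert 0 <= res.auc <= 1
    assert res.ci[0] <= res.auc <= res.ci[1]
    assert set(res.cutoffs) == {"youden", "se90", "sp90"}
    rows = res.to_rows()
    assert len(rows) == 3 and all(0 <= r["Se"] <= 100 for r in rows)


# ---------------------------------------------------------------------------
# correlation / group tests / kappa


def test_spearman_strictly_monotone_is_one():
    left = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]})
    right = pd.DataFrame({"y": np.exp(left["x"])})
    out = dx.spearman_matrix(left, right)
    assert out["rho"].loc["x", "y"] == pytest.approx(1.0)


def test_spearman_midrank_hand_value():
    # mid-rank Pearson: 4.5 / sqrt(4.5 * 5) = 0.9487
    left = pd.DataFrame({"x": [1.0, 2, 2, 3]})
    right = pd.DataFrame({"y": [1.0, 2, 3, 4]})
    out = dx.spearman_matrix(left, right, exact_below_n=0)
    assert out["rho"].loc["x", "y"] == pytest.approx(4.5 / np.sqrt(4.5 * 5), abs=1e-6)


def test_spearman_antisymmetry_and_small_n_flag():
    x = np.arange(12.0)
    out = dx.spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": -x}))
    assert out["rho"].loc["x", "y"] == pytest.approx(-1.0)
    short = dx.spearman_matrix(pd.DataFrame({"x": [1.0, 2]}), pd.DataFrame({"y": [3.0, 4]}))
    assert ("x", "y") in short["flagged"]


def test_spearman_exact_permutation_p_small_n():
    # n = 5, perfectly monotone: exact two-sided p = 2/5! = 1/60
    left = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
    right = pd.DataFrame({"y": [2.0, 4, 6, 8, 10]})
    out = dx.spearman_matrix(left, right)
    assert out["p"].loc["x", "y"] == pytest.approx(2 / 120)


def test_spearman_bonferroni_adjustment():
    rng = np.random.default_rng(4)
    left = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    right = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("xy"))
    out = dx.spearman_matrix(left, right)
    m = 6
    expect = (out["p"] * m).clip(upper=1.0)
    pd.testing.assert_frame_equal(out["p_adjusted"], expect)


def test_group_tests_separated_groups():
    a = np.arange(10.0)
    b = a + 100.0
    out = dx.group_tests(np.r_[a, b], np.r_[["a"] * 10, ["b"] * 10])
    pw = out["pairwise"]
    assert pw.loc[0, "U"] == 0.0
    assert pw.loc[0, "p_raw"] < 0.001


def test_group_tests_bonferroni_multiplies_by_pair_count():
    rng = np.random.default_rng(6)
    vals = rng.normal(size=50)
    groups = np.repeat(list("abcde"), 10)
    out = dx.group_tests(vals, groups)
    pw = out["pairwise"]
    assert len(pw) == 10
    assert np.allclose(pw["p_bonferroni"], np.minimum(pw["p_raw"] * 10, 1.0))


def test_group_tests_identical_distributions():
    vals = np.r_[np.ones(5), np.ones(5)]
    out = dx.group_tests(vals, np.r_[["a"] * 5, ["b"] * 5])
    assert out["omnibus"]["p"] == pytest.approx(1.0)


def test_weighted_kappa_identical_ratings():
    a = [0, 1, 2, 3, 4, 2, 1]
    assert dx.weighted_kappa(a, a) == pytest.approx(1.0)


def test_weighted_kappa_two_category_hand_value():
    # confusion [[40, 10], [10, 40]]: po = 0.8, pe = 0.5, kappa = 0.6
    a = [0] * 50 + [1] * 50
    b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
    assert dx.weighted_kappa(a, b, "linear") == pytest.approx(0.6)
    assert dx.weighted_kappa(a, b, "quadratic") == pytest.approx(0.6)


def test_weighted_kappa_independent_ratings_near_zero():
    rng = np.random.default_rng(17)
    a = rng.integers(0, 5, 10_000)
    b = rng.integers(0, 5, 10_000)
    assert abs(dx.weighted_kappa(a, b)) < 0.03


def test_weighted_kappa_length_mismatch():
    with pytest.raises(ValueError):
        dx.weighted_kappa([1, 2], [1])


# ---------------------------------------------------------------------------
# random forest importance


def _informative_dataset(seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(120, 10)), columns=[f"f{i}" for i in range(10)]
    )
    y = X["f0"].to_numpy() + rng.normal(0, 0.05, 120)
    return X, y


def test_rf_importance_recovers_informative_feature_over_seeds():
    hits = 0
    for seed in range(50):
        X, y = _informative_dataset(seed)
        imp = dx.rf_importance(X, y, n_trees=40, seed=seed)
        top_mse = imp.iloc[0]["feature"]
        top_purity = imp.sort_values("node_purity", ascending=False).iloc[0]["feature"]
        hits += top_mse == "f0" and top_purity == "f0"
    assert hits >= 48


def test_rf_importance_null_feature_near_zero_and_deterministic():
    X, y = _informative_dataset(99)
    imp1 = dx.rf_importance(X, y, n_trees=60, seed=7)
    imp2 = dx.rf_importance(X, y, n_trees=60, seed=7)
    pd.testing.assert_frame_equal(imp1, imp2)
    signal = imp1.set_index("feature")["mse_increase"]["f0"]
    noise = imp1.set_index("feature")["mse_increase"].drop("f0").abs().max()
    assert noise < 0.2 * signal
    assert set(imp1["rank"]) == set(range(1, 11))


def test_rf_importance_constant_target_errors():
    X, _ = _informative_dataset(1)
    with pytest.raises(ValueError):
        dx.rf_importance(X, np.ones(len(X)), n_trees=10, seed=0)
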