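import math

import numpy as np
import pytest

from anthro.stats import (
    DegenerateInputError,
    LogisticFit,
    adjusted_auc,
    auc,
    chi_square,
    fit_logistic,
    mann_whitney_u,
    odds_ratio,
    spearman_rho,
    students_t,
)

from _oracles import pair_count_auc, woolf_or_ci


# ----------------------------------------------------------------- rank tests

def test_spearman_perfect_monotone():
    assert spearman_rho([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)


def test_spearman_closed_form():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1) -> 1 - 24/60 = 0.6
    rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
    assert rho == pytest.approx(0.6)


def test_spearman_monotone_transform_invariant():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    r0, p0 = spearman_rho(x, y)
    r1, p1 = spearman_rho(np.exp(x), y**3 + 5 * y)
    assert r1 == pytest.approx(r0, rel=1e-12)
    assert p1 == pytest.approx(p0, rel=1e-9)


def test_spearman_constant_signalled():
    with pytest.raises(DegenerateInputError):
        spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])


def test_mann_whitney_exact_enumeration():
    # all 6 equally likely splits of ranks {1..4} into two pairs; the
    # observed U=0 arises in 1 of 6 orderings per tail -> two-sided p = 1/3
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0
    assert p == pytest.approx(1 / 3, abs=1e-10)


def test_mann_whitney_identical_sets():
    _, p = mann_whitney_u([1, 2, 3] * 10, [1, 2, 3] * 10)
    assert p == pytest.approx(1.0)


def test_mann_whitney_shifted_normals():
    rng = np.random.default_rng(14)
    a = rng.normal(0, 1, 200)
    b = rng.normal(1, 1, 200)
    _, p = mann_whitney_u(a, b)
    assert p < 1e-3


def test_chi_square_independence_and_closed_form():
    stat, df, _ = chi_square([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0)
    assert df == 1
    # N(ad-bc)^2 / (r1*r2*c1*c2) = 200*(1800-800)^2/(100*100*30*170)
    stat, _, _ = chi_square([[20, 80], [10, 90]])
    assert stat == pytest.approx(3.9216, abs=1e-4)


def test_chi_square_sex_by_bp_counts():
    """Sex x blood-pressure-category counts from the reference cohort show a
    significant imbalance; the statistic matches a manual expected-count
    computation (chi2 = 11.16, p = 0.0038)."""
    table = np.array([[146, 111, 41], [497, 231, 124]], float)
    stat, df, p = chi_square(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    manual = ((table - expected) ** 2 / expected).sum()
    assert df == 2
    assert stat == pytest.approx(manual, rel=1e-12)
    assert stat == pytest.approx(11.162, abs=0.01)
    assert 0.001 < p < 0.01


def test_chi_square_zero_margin():
    with pytest.raises(DegenerateInputError):
        chi_square([[0, 0], [10, 90]])


def test_students_t_identical_groups():
    t, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_students_t_closed_form_3v3():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
    sp2 = (2 * np.var(a, ddof=1) + 2 * np.var(b, ddof=1)) / 4
    expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
    t, _ = students_t(a, b)
    assert t == pytest.approx(expected, rel=1e-12)


def test_students_t_reconstructed_summaries():
    """Groups rebuilt from published mean±SD summaries (5.94±2.54 n=298 vs
    5.25±2.29 n=852) separate decisively."""
    rng = np.random.default_rng(3)
    a = rng.normal(size=298)
    a = (a - a.mean()) / a.std(ddof=1) * 2.54 + 5.94
    b = rng.normal(size=852)
    b = (b - b.mean()) / b.std(ddof=1) * 2.29 + 5.25
    _, p = students_t(a, b)
    assert p < 0.001


# ------------------------------------------------------------------- logistic

def _design_from_2x2(a, b, c, d):
    """exposed cases a, exposed controls b, unexposed cases c, controls d."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, np.column_stack([np.ones_like(x), x])


def test_logistic_matches_woolf_closed_form():
    y, X = _design_from_2x2(20, 80, 10, 90)
    fit = fit_logistic(y, X)
    assert fit.converged
    res = odds_ratio(fit, term=1)
    or_, lo, hi = woolf_or_ci(20, 80, 10, 90)
    assert res.odds_ratio == pytest.approx(or_, abs=1e-6)
    assert res.ci_low == pytest.approx(lo, abs=1e-6)
    assert res.ci_high == pytest.approx(hi, abs=1e-6)
    assert or_ == pytest.approx(2.25)
    assert lo == pytest.approx(0.994, abs=5e-4)
    assert hi == pytest.approx(5.092, abs=5e-4)


def test_logistic_null_balanced():
    y, X = _design_from_2x2(25, 25, 25, 25)
    res = odds_ratio(fit_logistic(y, X), term=1)
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)


def test_logistic_with_noise_covariate_keeps_or():
    rng = np.random.default_rng(9)
    y, X = _design_from_2x2(20, 80, 10, 90)
    Xz = np.column_stack([X, rng.normal(size=len(y))])
    res = odds_ratio(fit_logistic(y, Xz), term=1)
    assert res.odds_ratio == pytest.approx(2.25, rel=0.05)


def test_logistic_agrees_with_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         rng.integers(0, 2, n).astype(float)])
    eta = -0.5 + 0.8 * X[:, 1] - 0.3 * X[:, 2]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(y, X)
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.allclose(fit.coef, ref.params, atol=1e-6)
    assert np.allclose(fit.se(), ref.bse, rtol=1e-4)


def test_logistic_separation_flagged():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()  # perfectly separated
    fit = fit_logistic(y, np.column_stack([np.ones_like(x), x]))
    assert not fit.converged
    assert fit.reason == "separation"
    assert not odds_ratio(fit, term=1).defined


def test_logistic_constant_outcome_rejected():
    with pytest.raises(DegenerateInputError):
        fit_logistic(np.ones(10), np.ones((10, 1)))


def test_odds_ratio_unit_se_interval():
    fit = LogisticFit(coef=np.array([0.0, 0.0]),
                      cov=np.diag([0.1, 0.01]),  # SE of term 1 = 0.1
                      converged=True, n_iter=1, loglik=0.0)
    res = odds_ratio(fit, term=1)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(math.exp(-0.196), abs=1e-3)
    assert res.ci_high == pytest.approx(math.exp(0.196), abs=1e-3)


def test_odds_ratio_degenerate_se_limit():
    fit = LogisticFit(coef=np.array([0.0, math.log(2)]),
                      cov=np.diag([0.1, 1e-20]),
                      converged=True, n_iter=1, loglik=0.0)
    res = odds_ratio(fit, term=1)
    assert res.ci_low == pytest.approx(2.0, rel=1e-6)
    assert res.ci_high == pytest.approx(2.0, rel=1e-6)


# ------------------------------------------------------------------------ AUC

def test_auc_explicit_pair_counting():
    assert auc([3, 5], [1, 2, 4]) == pytest.approx(5 / 6)


def test_auc_identical_distributions():
    v = [1.0, 2.0, 3.0, 4.0]
    assert auc(v, v) == pytest.approx(0.5)


def test_auc_matches_pair_count_oracle():
    """200 random small instances, with and without ties."""
    rng = np.random.default_rng(17)
    for i in range(200):
        n1 = int(rng.integers(1, 12))
        n2 = int(rng.integers(1, 12))
        if i % 2:
            a = rng.integers(0, 5, n1).astype(float)   # heavy ties
            b = rng.integers(0, 5, n2).astype(float)
        else:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
        assert auc(a, b) == pytest.approx(pair_count_auc(a, b), abs=1e-12)
        # complement identity, tie-aware
        assert auc(a, b) + auc(b, a) == pytest.approx(1.0, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    a = rng.normal(1, 1, 100)
    b = rng.normal(0, 1, 150)
    assert auc(np.exp(a), np.exp(b)) == pytest.approx(auc(a, b), abs=1e-14)


def test_auc_agrees_with_sklearn():
    skm = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(6)
    a = rng.normal(0.8, 1, 80)
    b = rng.normal(0, 1, 120)
    y = np.r_[np.ones(80), np.zeros(120)]
    assert auc(a, b) == pytest.approx(
        skm.roc_auc_score(y, np.r_[a, b]), abs=1e-12)


def test_binormal_auc():
    """Cases N(1,1) vs controls N(0,1): population AUC = Phi(1/sqrt(2)) = 0.760."""
    rng = np.random.default_rng(12)
    a = rng.normal(1, 1, 2000)
    b = rng.normal(0, 1, 2000)
    assert abs(auc(a, b) - 0.760) < 0.02


# --------------------------------------------------------------- adjusted AUC

def test_adjusted_auc_no_signal():
    rng = np.random.default_rng(10)
    n = 1000
    flag = (rng.uniform(size=n) < 0.33).astype(float)
    age = rng.uniform(18, 80, n)
    y = (rng.uniform(size=n) < 0.3).astype(float)
    res = adjusted_auc(flag, age, y, bootstrap_reps=0)
    assert res.defined
    assert res.auc == pytest.approx(0.5, abs=0.03)


def test_adjusted_auc_age_driven_beats_flag_alone():
    rng = np.random.default_rng(13)
    n = 1500
    age = rng.uniform(18, 80, n)
    flag = (rng.uniform(size=n) < 0.33).astype(float)   # pure noise
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(age - 50) / 8))).astype(float)
    res = adjusted_auc(flag, age, y, bootstrap_reps=0)
    raw = auc(flag[y == 1], flag[y == 0])
    assert res.auc > raw + 0.1


def test_adjusted_auc_single_class_flagged():
    res = adjusted_auc([0, 1, 0], [40, 50, 60], [0, 0, 0], bootstrap_reps=0)
    assert not res.defined
    assert res.reason == "single_class"


def test_adjusted_auc_bootstrap_ci_reproducible():
    rng = np.random.default_rng(20)
    n = 300
    age = rng.uniform(18, 80, n)
    flag = (rng.uniform(size=n) < 0.4).astype(float)
    y = (rng.uniform(size=n) <
         1 / (1 + np.exp(-(-1 + 0.8 * flag + 0.02 * age)))).astype(float)
    r1 = adjusted_auc(flag, age, y, bootstrap_reps=200, seed=5)
    r2 = adjusted_auc(flag, age, y, bootstrap_reps=200, seed=5)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    assert r1.ci_low <= r1.auc <= r1.ci_high
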