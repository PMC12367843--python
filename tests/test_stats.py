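"""Statistical layer: AUC against a brute-force pairwise oracle, interval
behaviour, likelihood ratios against frozen worked examples, IRLS logistic
regression against the statsmodels oracle, and the descriptive tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneurysmorph import stats
from aneurysmorph.stats import (
    SeparationError,
    auc_ci,
    auc_midrank,
    chi_squared_test,
    critical_value,
    fit_logistic,
    logistic_from_coefficients,
    lr_ci,
    odds_ratio_per_delta,
    percent_difference,
    positive_lr,
    roc_analysis,
    sens_spec_at_cutoff,
    welch_t_test,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    """Exhaustive fraction of (case, control) pairs won, ties counting 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    wins = 0.0
    for c in s[y]:
        for k in s[~y]:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (y.sum() * (~y).sum())


# ---------------------------------------------------------------------------
# AUC


@pytest.mark.parametrize(
    "cases, controls, expected",
    [([3, 4], [1, 2], 1.0), ([1, 3], [2, 4], 0.25), ([1], [1], 0.5)],
)
def test_auc_midrank_small_cases(cases, controls, expected):
    scores = np.array(cases + controls, float)
    labels = np.array([True] * len(cases) + [False] * len(controls))
    assert auc_midrank(scores, labels) == pytest.approx(expected)


@given(
    data=st.lists(
        st.tuples(st.integers(min_value=0, max_value=9), st.booleans()),
        min_size=4,
        max_size=30,
    )
)
@settings(max_examples=200, deadline=None)
def test_auc_matches_pairwise_oracle(data):
    scores = np.array([d[0] for d in data], float)
    labels = np.array([d[1] for d in data])
    if labels.all() or not labels.any():
        return
    assert auc_midrank(scores, labels) == pytest.approx(
        brute_force_auc(scores, labels), rel=1e-12
    )


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        auc_midrank([1.0, 2.0], [True, True])


def test_auc_ci_brackets_and_tightens():
    rng = np.random.default_rng(0)
    for n in (20, 200):
        cases = rng.normal(1.0, 1.0, n)
        controls = rng.normal(0.0, 1.0, n)
        s = np.concatenate([cases, controls])
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        lo, hi = auc_ci(s, y)
        assert lo <= auc_midrank(s, y) <= hi
        if n == 20:
            width_20 = hi - lo
        else:
            assert hi - lo < width_20


def test_auc_ci_label_flip_symmetry():
    rng = np.random.default_rng(1)
    s = rng.normal(size=60)
    y = rng.random(60) < 0.4
    lo, hi = auc_ci(s, y)
    lo_f, hi_f = auc_ci(s, ~y)
    assert lo_f == pytest.approx(1 - hi, abs=1e-12)
    assert hi_f == pytest.approx(1 - lo, abs=1e-12)


def test_delong_vs_bootstrap_agreement():
    rng = np.random.default_rng(2)
    s = np.concatenate([rng.normal(0.8, 1, 100), rng.normal(0, 1, 100)])
    y = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
    d = auc_ci(s, y, method="delong")
    b = auc_ci(s, y, method="bootstrap", n_boot=2000, seed=3)
    assert d[0] == pytest.approx(b[0], abs=0.03)
    assert d[1] == pytest.approx(b[1], abs=0.03)


# ---------------------------------------------------------------------------
# Operating points and likelihood ratios


def test_sens_spec_orientations():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([True, True, False, False])
    assert sens_spec_at_cutoff(scores, labels, 0.5, "lower_is_ruptured") == (1.0, 1.0)
    sens, spec = sens_spec_at_cutoff(scores, labels, 0.05, "lower_is_ruptured")
    assert (sens, spec) == (0.0, 1.0)  # nothing called positive


def test_youden_midpoint_in_separating_gap():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([True, True, False, False])
    assert youden_cutoff(scores, labels, "lower_is_ruptured") == pytest.approx(2.5)


def test_youden_single_value_degenerate():
    scores = np.ones(4)
    labels = np.array([True, False, True, False])
    assert youden_cutoff(scores, labels, "lower_is_ruptured") == 1.0


def test_orientation_coherence():
    """ROC on x with lower_is_ruptured matches ROC on -x with higher_is_ruptured."""
    rng = np.random.default_rng(4)
    s = rng.normal(size=40)
    y = rng.random(40) < 0.5
    a = roc_analysis("i", s, y, "lower_is_ruptured", cutoff=0.0)
    b = roc_analysis("i", -s, y, "higher_is_ruptured", cutoff=0.0)
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert a.sens == b.sens and a.spec == b.spec
    for (ca, sa, pa), (cb, sb, pb) in zip(a.points, sorted(b.points, key=lambda t: -t[0])):
        assert ca == pytest.approx(-cb)
        assert sa == pytest.approx(sb)
        assert pa == pytest.approx(pb)


@pytest.mark.parametrize(
    "sens, spec, expected",
    [
        (0.5, 0.5, 1.0),
        (23 / 28, 32 / 52, 2.1357),  # prints 2.14
        (26 / 28, 24 / 52, 1.7242),  # prints 1.72
    ],
)
def test_positive_lr_values(sens, spec, expected):
    assert positive_lr(sens, spec) == pytest.approx(expected, abs=5e-4)


def test_positive_lr_perfect_specificity_is_inf_not_error():
    assert math.isinf(positive_lr(0.9, 1.0))


def test_lr_ci_worked_example():
    """Confusion counts 23/5/32/20 (sens 82.1%, spec 61.5%): log-method CI
    brackets LR+ = 2.14 and lands near (1.45, 3.14)."""
    lo, hi, corrected = lr_ci(23, 5, 32, 20)
    assert not corrected
    assert lo < 2.1357 < hi
    assert lo == pytest.approx(1.45, abs=0.05)
    assert hi == pytest.approx(3.14, abs=0.05)


def test_lr_ci_contains_one_for_uninformative_test():
    lo, hi, _ = lr_ci(50, 50, 50, 50)
    assert lo < 1.0 < hi


def test_lr_ci_narrows_with_counts():
    lo1, hi1, _ = lr_ci(23, 5, 32, 20)
    lo2, hi2, _ = lr_ci(46, 10, 64, 40)
    assert (hi2 - lo2) < (hi1 - lo1)


def test_lr_ci_zero_cell_continuity_correction():
    lo, hi, corrected = lr_ci(10, 0, 10, 0)
    assert corrected and lo > 0 and math.isfinite(hi)


# ---------------------------------------------------------------------------
# Logistic regression


def test_logistic_symmetric_data_gives_zero_coefficients():
    m = fit_logistic([0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0])
    assert m.beta0 == pytest.approx(0.0, abs=1e-8)
    assert m.beta1 == pytest.approx(0.0, abs=1e-8)
    assert m.converged


def test_logistic_single_class_errors():
    with pytest.raises(SeparationError):
        fit_logistic([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])


def test_logistic_perfect_separation_detected():
    x = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])
    y = np.concatenate([np.zeros(20), np.ones(20)])
    with pytest.raises(SeparationError):
        fit_logistic(x, y)


def test_logistic_matches_statsmodels_oracle():
    """IRLS coefficients and standard errors agree with an independent MLE."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(5)
    x = rng.lognormal(math.log(8e-3), 0.4, 400)
    p = 1 / (1 + np.exp(-(0.577 - 72.8 * x)))
    y = (rng.random(400) < p).astype(float)
    ours = fit_logistic(x, y)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert ours.beta0 == pytest.approx(ref.params[0], rel=1e-6)
    assert ours.beta1 == pytest.approx(ref.params[1], rel=1e-6)
    assert ours.se_beta0 == pytest.approx(ref.bse[0], rel=1e-4)
    assert ours.se_beta1 == pytest.approx(ref.bse[1], rel=1e-4)
    assert ours.p_value == pytest.approx(ref.pvalues[1], rel=1e-3, abs=1e-12)


def test_logistic_parameter_recovery_from_link():
    """Data sampled from the all-site rupture link is recovered within 2 SE."""
    rng = np.random.default_rng(6)
    n = 5000
    x = rng.lognormal(math.log(7.9e-3), 0.45, n)
    p = 1 / (1 + np.exp(-(0.577 - 72.8 * x)))
    y = (rng.random(n) < p).astype(float)
    m = fit_logistic(x, y)
    assert abs(m.beta0 - 0.577) < 2 * m.se_beta0
    assert abs(m.beta1 + 72.8) < 2 * m.se_beta1


def test_logistic_self_consistency_at_critical_value():
    rng = np.random.default_rng(7)
    x = rng.normal(size=300)
    y = (rng.random(300) < 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(float)
    m = fit_logistic(x, y)
    assert m.predict(critical_value(m)) == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize(
    "beta0, beta1, expected",
    [
        (0.577, -72.8, 7.926e-3),  # prints 7.9e-3
        (0.298, -48.3, 6.170e-3),  # prints 6.2e-3
        (0.0, -5.0, 0.0),
    ],
)
def test_critical_value_inversion(beta0, beta1, expected):
    m = logistic_from_coefficients("WTR", beta0, beta1)
    assert critical_value(m) == pytest.approx(expected, abs=5e-6)


def test_critical_value_general_probability():
    m = logistic_from_coefficients("x", 1.0, -2.0)
    x90 = critical_value(m, p=0.9)
    assert m.predict(x90) == pytest.approx(0.9, rel=1e-12)
    with pytest.raises(ValueError):
        critical_value(logistic_from_coefficients("x", 1.0, 0.0))


@pytest.mark.parametrize(
    "beta1, delta, expected",
    [(-72.8, 0.001, 1.0755), (-48.3, 0.001, 1.0495), (0.0, 0.001, 1.0)],
)
def test_odds_ratio_magnitude_per_increment(beta1, delta, expected):
    m = logistic_from_coefficients("WTR", 0.0, beta1)
    assert odds_ratio_per_delta(m, delta) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "reference, computed, expected",
    [(6.1e-3, 7.926e-3, 23.0), (3.0, 3.0, 0.0), (0.0, 5.0, 100.0)],
)
def test_percent_difference_convention(reference, computed, expected):
    assert percent_difference(reference, computed) == pytest.approx(expected, abs=0.05)


# ---------------------------------------------------------------------------
# Descriptive tests


def test_welch_identical_samples():
    c = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.statistic == pytest.approx(0.0)
    assert c.p_value == pytest.approx(1.0)


def test_welch_hand_value():
    c = welch_t_test([1, 2, 3], [4, 5, 6], variable="demo")
    assert c.statistic == pytest.approx(-3.674, abs=1e-3)
    assert c.df == pytest.approx(4.0, rel=1e-12)
    assert c.test == "welch_t"


def test_welch_swap_antisymmetry():
    a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 2.0, 5.0]
    c1, c2 = welch_t_test(a, b), welch_t_test(b, a)
    assert c1.statistic == pytest.approx(-c2.statistic)
    assert c1.p_value == pytest.approx(c2.p_value)


@pytest.mark.parametrize(
    "table, chi2",
    [([[10, 10], [10, 10]], 0.0), ([[20, 10], [10, 20]], 20 / 3)],
)
def test_chi_squared_hand_values(table, chi2):
    c = chi_squared_test(table)
    assert c.statistic == pytest.approx(chi2, rel=1e-9)
    assert c.df == 1


def test_chi_squared_zero_expected_errors():
    with pytest.raises(ValueError):
        chi_squared_test([[0, 0], [5, 5]])
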