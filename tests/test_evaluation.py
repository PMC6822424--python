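"""Kappa, confusion matrices, Deming regression, Bland-Altman, permutation."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.metrics import cohen_kappa_score

from sqsleep import (
    Hypnogram,
    bland_altman,
    cohens_kappa,
    confusion,
    deming_fit,
    evaluate_study,
    exact_permutation_test,
    kappa_from_confusion,
    paired_kappa_test,
    to_sleep_wake,
    two_class_sensitivity_specificity,
)
from sqsleep.evaluation import ConfusionMatrix
from sqsleep.io import WAKE_SLEEP


def _sequences_from_counts(counts, classes):
    a, b = [], []
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            a += [ci] * counts[i][j]
            b += [cj] * counts[i][j]
    return a, b


# --- Cohen's kappa ---------------------------------------------------------


def test_kappa_identical_sequences_is_one():
    assert cohens_kappa(["W", "N2", "R"] * 5, ["W", "N2", "R"] * 5) == 1.0


def test_kappa_hand_computed_two_by_two_table():
    """counts [[45,5],[15,35]]: p_o = 0.8, p_e = 0.5, kappa = 0.6."""
    a, b = _sequences_from_counts([[45, 5], [15, 35]], ["wake", "sleep"])
    assert cohens_kappa(a, b) == pytest.approx(0.6)


def test_kappa_independent_labelings_near_zero(rng):
    a = rng.choice(["W", "N1", "N2"], 10_000).tolist()
    b = rng.choice(["W", "N1", "N2"], 10_000).tolist()
    assert abs(cohens_kappa(a, b)) < 0.05


def test_kappa_matches_sklearn_cross_check(rng):
    for _ in range(5):
        a = rng.choice(["W", "N1", "N2", "N3", "R"], 500).tolist()
        b = rng.choice(["W", "N1", "N2", "N3", "R"], 500).tolist()
        assert cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )


def test_kappa_constant_identical_raters_defined_as_one(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="sqsleep.evaluation"):
        k = cohens_kappa(["W"] * 10, ["W"] * 10)
    assert k == 1.0
    assert any("p_e = 1" in r.message for r in caplog.records)


def test_kappa_from_counts_equals_kappa_from_sequences(rng):
    a = rng.choice(["W", "N2", "R"], 300).tolist()
    b = rng.choice(["W", "N2", "R"], 300).tolist()
    assert kappa_from_confusion(confusion(a, b)) == cohens_kappa(a, b)


# --- confusion matrices ----------------------------------------------------


def test_confusion_identity_pattern():
    a = ["W", "N1", "N2", "N3", "R"] * 4
    cm = confusion(a, a)
    assert np.array_equal(cm.counts, 4 * np.eye(5, dtype=int))
    assert np.allclose(np.diag(cm.percents), 100.0)


def test_confusion_two_class_convention():
    """Diagonal of the wake/sleep matrix is (specificity, sensitivity)."""
    truth = ["wake"] * 10 + ["sleep"] * 20
    pred = ["wake"] * 8 + ["sleep"] * 2 + ["sleep"] * 19 + ["wake"]
    cm = confusion(truth, pred, classes=WAKE_SLEEP)
    sens, spec = two_class_sensitivity_specificity(cm)
    assert spec == pytest.approx(80.0)
    assert sens == pytest.approx(95.0)


def test_confusion_empty_truth_row_is_nan():
    cm = confusion(["sleep"] * 5, ["wake"] * 5, classes=WAKE_SLEEP)
    sens, spec = two_class_sensitivity_specificity(cm)
    assert sens == 0.0
    assert math.isnan(spec)


def test_confusion_pooling_is_concatenation(rng):
    a1 = rng.choice(["W", "N2"], 50).tolist()
    b1 = rng.choice(["W", "N2"], 50).tolist()
    a2 = rng.choice(["W", "N2"], 70).tolist()
    b2 = rng.choice(["W", "N2"], 70).tolist()
    classes = ("W", "N2")
    pooled = confusion(a1, b1, classes) + confusion(a2, b2, classes)
    assert np.array_equal(pooled.counts, confusion(a1 + a2, b1 + b2, classes).counts)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        confusion(["W"], ["W", "W"])


def test_two_class_kappa_consistent_with_merged_confusion(rng):
    """Kappa after merging sequences equals kappa of the merged matrix."""
    t = Hypnogram(stages=rng.choice(["W", "N1", "N2", "N3", "R"], 400).tolist())
    p = Hypnogram(stages=rng.choice(["W", "N1", "N2", "N3", "R"], 400).tolist())
    tw, pw = to_sleep_wake(t), to_sleep_wake(p)
    k_seq = cohens_kappa(tw.states, pw.states)
    cm = confusion(tw.states, pw.states, classes=WAKE_SLEEP)
    assert kappa_from_confusion(cm) == pytest.approx(k_seq, abs=1e-12)


# --- Deming regression -----------------------------------------------------


def test_deming_identity_line():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    fit = deming_fit(x, x)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0)
    assert fit.pearson_r == pytest.approx(1.0)


def test_deming_swap_inverts_slope(rng):
    x = rng.normal(size=20)
    y = 2.0 * x + rng.normal(0, 0.3, 20)
    assert deming_fit(x, y).slope == pytest.approx(
        1.0 / deming_fit(y, x).slope
    )


def test_deming_matches_numerical_minimizer(rng):
    """Orthogonal regression agrees with brute-force perpendicular LS."""
    x = np.array([0.0, 1.1, 1.9, 3.2, 4.1])
    y = np.array([0.3, 0.9, 2.3, 2.8, 4.4])

    def perp_ss(params):
        m, c = params
        return np.sum((y - m * x - c) ** 2) / (1 + m * m)

    res = minimize(perp_ss, x0=[1.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    fit = deming_fit(x, y)
    assert fit.slope == pytest.approx(res.x[0], abs=1e-6)
    assert fit.intercept == pytest.approx(res.x[1], abs=1e-6)


def test_deming_degenerate_input_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        deming_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
    with pytest.raises(ValueError, match="at least 3"):
        deming_fit([1.0, 2.0], [1.0, 2.0])


# --- permutation test ------------------------------------------------------


def _enumerate_p(d):
    """Independent oracle: itertools over all sign assignments."""
    d = np.asarray(d, dtype=float)
    obs = abs(d.mean())
    hits = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        if abs(np.mean(np.array(signs) * d)) >= obs - 1e-12:
            hits += 1
    return hits / 2 ** len(d)


@pytest.mark.parametrize(
    "d,expected",
    [
        ((1.0, 1.0, 1.0), 0.25),  # 2 of 8 sign patterns as extreme
        ((0.0, 0.0, 0.0, 0.0), 1.0),
        ((2.0,), 1.0),  # n=1: both assignments tie on |d|
        (tuple([1.0] * 11), 2.0 / 2048.0),  # minimum attainable at n=11
    ],
)
def test_exact_permutation_known_values(d, expected):
    assert exact_permutation_test(d) == pytest.approx(expected)
    assert _enumerate_p(d) == pytest.approx(expected)


def test_exact_permutation_matches_enumeration_oracle(rng):
    for _ in range(10):
        d = rng.normal(size=int(rng.integers(2, 9)))
        assert exact_permutation_test(d) == pytest.approx(_enumerate_p(d))


def test_permutation_p_is_multiple_of_two_to_minus_n(rng):
    for n in (3, 5, 8, 11):
        d = rng.normal(size=n)
        p = exact_permutation_test(d)
        assert (p * 2**n) == pytest.approx(round(p * 2**n), abs=1e-9)
        assert 0 < p <= 1


def test_monte_carlo_agrees_with_exact(rng):
    """10^5 random sign flips fall within 3 SE of the exact p-value."""
    d = rng.normal(0.4, 1.0, size=11)
    p_exact = exact_permutation_test(d)
    p_mc = exact_permutation_test(d, max_exact_n=0, n_mc=100_000, seed=9)
    se = math.sqrt(p_exact * (1 - p_exact) / 100_000)
    assert abs(p_mc - p_exact) <= 3 * se + 2e-5


# --- Bland-Altman ----------------------------------------------------------


def test_bland_altman_identical_measures():
    x = np.array([400.0, 420.0, 380.0])
    ba = bland_altman(x, x)
    assert ba.mean_diff == 0.0
    assert ba.p_value == 1.0
    assert ba.limits == (0.0, 0.0)


def test_bland_altman_constant_positive_difference():
    x = np.array([10.0, 20.0, 30.0])
    ba = bland_altman(x, x - 1.0)  # estimate one unit below truth
    assert ba.mean_diff == 1.0  # positive = underestimation
    assert ba.p_value == pytest.approx(0.25)


def test_bland_altman_limits_symmetric_and_cover_95pct(rng):
    d = rng.normal(2.0, 5.0, size=10_000)
    x = rng.normal(400, 50, size=10_000)
    ba = bland_altman(x, x - d)
    lo, hi = ba.limits
    assert hi - ba.mean_diff == pytest.approx(ba.mean_diff - lo)
    frac = np.mean((d >= lo) & (d <= hi))
    assert frac == pytest.approx(0.95, abs=0.01)


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError, match="at least 2"):
        bland_altman([1.0], [2.0])


def test_paired_kappa_test_values():
    assert paired_kappa_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]) == 1.0
    ka = [0.8 + 0.01 * i for i in range(11)]
    kb = [k - 0.05 for k in ka]
    assert paired_kappa_test(ka, kb) == pytest.approx(2.0 / 2048.0)


# --- study-level report ----------------------------------------------------


def test_evaluate_study_report_structure(rng):
    truth, pred = {}, {}
    for night in ("A1", "A2", "B1"):
        stages = rng.choice(["W", "N1", "N2", "N3", "R"], 120).tolist()
        noisy = [
            s if rng.random() > 0.2 else rng.choice(["W", "N2"]) for s in stages
        ]
        truth[night] = Hypnogram(stages=stages)
        pred[night] = Hypnogram(stages=noisy)
    rep = evaluate_study(truth, pred)
    assert sorted(rep.kappa5) == ["A1", "A2", "B1"]
    assert rep.confusion5.counts.sum() == 3 * 120
    assert 0 < rep.sensitivity <= 100 and 0 < rep.specificity <= 100
    for name in ("TST", "SE", "WASO"):
        assert "bias" in rep.measures[name]
    d = rep.to_dict()
    assert "kappa5_mean" in d and "measures" in d


def test_evaluate_study_mismatched_nights():
    h = Hypnogram(stages=["W"] * 4)
    with pytest.raises(ValueError, match="different nights"):
        evaluate_study({"A1": h}, {"B1": h})
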