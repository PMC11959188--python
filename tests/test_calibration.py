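"""Scaling fits, DOC threshold fitting, and the classify-or-reject rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defenscan.calibration import (REJECT, CalibratorState, DocThresholds,
                                   apply_calibrator, classify_or_reject,
                                   correct_probs_by_class, fit_affine,
                                   fit_doc_thresholds, fit_temperature)
from defenscan.model import softmax

SOFTMAX_HALVED_123 = [0.18632372322584757702, 0.30719588571849839707,
                      0.50648039105565402590]  # softmax(0.5, 1.0, 1.5), sympy


def _self_calibrated_logits(rng, n_groups=60, k=3, scale=1.0):
    """Logit set whose empirical label frequencies equal the model probabilities
    exactly, so the NLL optimum over T sits at T = 1/scale analytically."""
    logits, labels = [], []
    for _ in range(n_groups):
        z = rng.normal(size=k)
        # use integer-proportional probabilities: z = log of integer counts
        counts = rng.integers(1, 5, size=k)
        z = np.log(counts.astype(float))
        for cls, c in enumerate(counts):
            for _ in range(c):
                logits.append(scale * z)
                labels.append(cls)
    return np.array(logits), np.array(labels)


def test_temperature_identity_when_already_calibrated():
    rng = np.random.default_rng(0)
    logits, labels = _self_calibrated_logits(rng, scale=1.0)
    state = fit_temperature(logits, labels)
    assert state.kind == "temperature"
    assert state.T == pytest.approx(1.0, abs=1e-3)


def test_temperature_recovers_twofold_scale():
    rng = np.random.default_rng(1)
    logits, labels = _self_calibrated_logits(rng, scale=2.0)
    state = fit_temperature(logits, labels)
    assert state.T == pytest.approx(2.0, rel=0.05)


def test_temperature_positive_and_single_class_rejected():
    rng = np.random.default_rng(2)
    z = rng.normal(size=(40, 3))
    y = rng.integers(0, 3, size=40)
    assert fit_temperature(z, y).T > 0
    with pytest.raises(ValueError):
        fit_temperature(z, np.zeros(40, dtype=int))


def test_temperature_never_changes_argmax():
    rng = np.random.default_rng(3)
    z = rng.normal(scale=3, size=(1000, 5))
    for T in (0.1, 0.5, 2.0, 17.0):
        state = CalibratorState(kind="temperature", T=T)
        p = apply_calibrator(z, state)
        np.testing.assert_array_equal(p.argmax(axis=1), z.argmax(axis=1))


def test_apply_temperature_halves_logits_oracle():
    state = CalibratorState(kind="temperature", T=2.0)
    p = apply_calibrator(np.array([[1.0, 2.0, 3.0]]), state)
    np.testing.assert_allclose(p[0], SOFTMAX_HALVED_123, rtol=1e-12)
    # T=1 is plain softmax
    one = CalibratorState(kind="temperature", T=1.0)
    np.testing.assert_allclose(apply_calibrator(np.array([[1.0, 2.0, 3.0]]), one)[0],
                               softmax(np.array([1.0, 2.0, 3.0])), rtol=1e-15)


def test_vector_scaling_recovers_known_scales():
    rng = np.random.default_rng(4)
    k, n = 3, 5000
    true_w = np.array([0.5, 1.5, 2.5])
    raw = rng.normal(size=(n, k))
    p = softmax(raw * true_w)
    labels = np.array([rng.choice(k, p=pi) for pi in p])
    state = fit_affine(raw, labels, kind="vector")
    # recovered diagonal is identifiable up to sampling noise
    np.testing.assert_allclose(state.W, true_w, rtol=0.10)


def test_identity_affine_is_noop():
    rng = np.random.default_rng(5)
    z = rng.normal(size=(20, 4))
    state = CalibratorState(kind="matrix", W=np.eye(4), b=np.zeros(4))
    np.testing.assert_allclose(apply_calibrator(z, state), softmax(z), atol=1e-12)


def test_matrix_scaling_can_change_argmax_temperature_cannot():
    z = np.array([[1.0, 0.9]])
    swap = CalibratorState(kind="matrix", W=np.array([[0.0, 1.0], [1.0, 0.0]]),
                           b=np.zeros(2))
    assert apply_calibrator(z, swap).argmax() == 1
    assert apply_calibrator(z, CalibratorState(kind="temperature", T=3.0)).argmax() == 0


def test_calibrator_shape_mismatch_raises():
    state = CalibratorState(kind="vector", W=np.ones(3), b=np.zeros(3))
    with pytest.raises(ValueError):
        apply_calibrator(np.zeros((2, 4)), state)


# ---------------------------------------------------------------------------
# DOC thresholds
# ---------------------------------------------------------------------------

def test_doc_thresholds_worked_example():
    """probs {0.9, 0.8}: mirror about mean 0.85 -> sigma = 0.05,
    t(alpha=3) = 0.85 and t(alpha=4) = 0.80 (hand arithmetic)."""
    fit = fit_doc_thresholds([np.array([0.9, 0.8])], alpha=3.0)
    assert fit.sigma[0] == pytest.approx(0.05, rel=1e-12)
    assert fit.t[0] == pytest.approx(0.85, rel=1e-12)
    assert fit.with_alpha(4.0).t[0] == pytest.approx(0.80, rel=1e-12)


def test_doc_identical_probs_give_threshold_one():
    fit = fit_doc_thresholds([np.full(5, 0.7)], alpha=3.0)
    assert fit.t[0] == 1.0


def test_doc_floor_engages_for_large_sigma():
    # sigma >= 0.5/alpha forces the 0.5 floor
    fit = fit_doc_thresholds([np.array([0.1, 0.9])], alpha=3.0)
    assert fit.sigma[0] >= 0.5 / 3.0
    assert fit.t[0] == 0.5


def test_doc_empty_class_flagged_at_half():
    fit = fit_doc_thresholds([np.array([0.9, 0.8]), np.array([])], alpha=3.0)
    assert fit.t[1] == 0.5
    assert fit.flagged == [1]


def test_doc_order_invariance_and_mirror_mean():
    rng = np.random.default_rng(6)
    probs = rng.uniform(0.5, 1.0, size=31)
    a = fit_doc_thresholds([probs], alpha=3.0)
    b = fit_doc_thresholds([rng.permutation(probs)], alpha=3.0)
    assert a.t[0] == pytest.approx(b.t[0], rel=1e-12)
    # mirrored set has mean exactly at the mirror center
    center = probs.mean()
    combined = np.concatenate([probs, 2 * center - probs])
    assert combined.mean() == pytest.approx(center, rel=1e-12)


def test_doc_mirror_about_one_variant():
    probs = np.array([0.9, 0.8])
    fit = fit_doc_thresholds([probs], alpha=3.0, mirror_center="one")
    combined = np.concatenate([probs, 2 - probs])
    assert fit.sigma[0] == pytest.approx(combined.std(), rel=1e-12)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
       st.floats(min_value=0.5, max_value=10.0))
def test_doc_threshold_bounds_and_monotonicity(probs, alpha):
    fit = fit_doc_thresholds([np.array(probs)], alpha=alpha)
    assert 0.5 <= fit.t[0] <= 1.0
    higher = fit.with_alpha(alpha + 1.0)
    assert higher.t[0] <= fit.t[0] + 1e-12


# ---------------------------------------------------------------------------
# Classify-or-reject
# ---------------------------------------------------------------------------

def _thr(t):
    t = np.asarray(t, dtype=float)
    return DocThresholds(t=t, mu=t, sigma=t * 0, alpha=3.0)


def test_reject_when_all_below():
    assert classify_or_reject([0.4, 0.3], _thr([0.8, 0.8])) == REJECT


def test_single_class_above_wins():
    assert classify_or_reject([0.4, 0.9], _thr([0.8, 0.8])) == 1


def test_argmax_over_all_classes_when_any_above():
    """p=(0.9, 0.86) with t=(0.85, 0.85): brute-force rule check gives class 0."""
    p, t = np.array([0.9, 0.86]), np.array([0.85, 0.85])
    brute = REJECT if all(pi < ti for pi, ti in zip(p, t)) else int(np.argmax(p))
    assert classify_or_reject(p, _thr(t)) == brute == 0


def test_correct_probs_by_class_grouping():
    probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4], [0.3, 0.7]])
    labels = np.array([0, 1, 1, 1])
    grouped = correct_probs_by_class(probs, labels, 2)
    np.testing.assert_allclose(grouped[0], [0.9])
    np.testing.assert_allclose(grouped[1], [0.8, 0.7])  # the 0.6-argmax one was wrong
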