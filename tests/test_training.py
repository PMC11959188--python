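"""Class weighting, stratified splits, losses, schedules, and the train loop."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defenscan.nn import Tensor, lr_at_epoch
from defenscan.training import (DEFAULT_MILESTONES, ArrayDataset, EarlyStopper, LossSpec,
                                TrainConfig, compute_class_weights, entropy, loss_fn,
                                probs_to_logits, stratified_split, train_ensemble,
                                train_model)

# the ten published per-type counts (Druantia..Zorya)
TYPE_COUNTS = {"Druantia": 1263, "Gabija": 3723, "Hachiman": 1529, "Wadjet": 6882,
               "Lamassu": 637, "Septu": 2807, "Shedu": 647, "Thoeris": 1097,
               "Kiwa": 745, "Zorya": 1866}
ENTROPY_HALF_QUARTER = 1.0397207708399179641  # H(1/2, 1/4, 1/4), sympy
DOC_EXAMPLE_LOSS = 0.57981849525294213468     # -ln(0.8) - ln(0.7), sympy


# ---------------------------------------------------------------------------
# Class weights
# ---------------------------------------------------------------------------

def test_balanced_classes_weight_one():
    assert compute_class_weights({"a": 10, "b": 10}) == {"a": 1.0, "b": 1.0}


def test_published_count_mixture_weight():
    w = compute_class_weights(TYPE_COUNTS)
    assert sum(TYPE_COUNTS.values()) == 21196
    assert w["Wadjet"] == pytest.approx(21196 / (6882 * 10), rel=1e-12)


def test_empty_class_rejected():
    with pytest.raises(ValueError):
        compute_class_weights({"a": 5, "b": 0})


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=12))
def test_weight_conservation_identity(counts):
    """sum_c n_c * w_c == N for any valid count vector."""
    cc = {f"c{i}": n for i, n in enumerate(counts)}
    w = compute_class_weights(cc)
    assert sum(cc[c] * w[c] for c in cc) == pytest.approx(sum(counts))


# ---------------------------------------------------------------------------
# Stratified splits
# ---------------------------------------------------------------------------

def test_split_reproduces_published_sizes():
    labels = np.repeat(np.arange(len(TYPE_COUNTS)), list(TYPE_COUNTS.values()))
    plan = stratified_split(labels, seed=0)
    f = plan.folds[0]
    assert len(f["test"]) == 2119
    assert len(f["val"]) == 1908
    assert len(f["train"]) == 17169


def test_two_balanced_classes_ten_folds():
    labels = np.repeat([0, 1], 10)
    plan = stratified_split(labels, n_folds=10, seed=1)
    for f in plan.folds:
        test_labels = labels[f["test"]]
        assert (test_labels == 0).sum() == 1 and (test_labels == 1).sum() == 1


def test_split_partition_and_stratification_tolerance():
    rng = np.random.default_rng(2)
    labels = rng.choice(4, p=[0.5, 0.25, 0.15, 0.1], size=1000)
    plan = stratified_split(labels, seed=3)
    N = len(labels)
    for f in plan.folds:
        allidx = np.concatenate([f["train"], f["val"], f["test"]])
        assert len(allidx) == N and len(np.unique(allidx)) == N  # exhaustive partition
        for part in ("train", "val", "test"):
            size = len(f[part])
            for c in range(4):
                got = (labels[f[part]] == c).sum()
                expect = size * (labels == c).sum() / N
                assert abs(got - expect) <= 1.0 + 1e-9


def test_split_reproducible_and_small_class_flagged():
    labels = np.array([0] * 50 + [1] * 5)
    plan1 = stratified_split(labels, n_folds=10, seed=4)
    plan2 = stratified_split(labels, n_folds=10, seed=4)
    for f1, f2 in zip(plan1.folds, plan2.folds):
        np.testing.assert_array_equal(f1["train"], f2["train"])
    assert any("5 < 10" in w for w in plan1.warnings)


# ---------------------------------------------------------------------------
# Entropy and losses
# ---------------------------------------------------------------------------

def test_entropy_closed_forms():
    assert entropy([1.0, 0.0, 0.0]) == 0.0
    assert entropy(np.full(5, 0.2)) == pytest.approx(math.log(5), rel=1e-12)
    assert entropy([0.5, 0.25, 0.25]) == pytest.approx(ENTROPY_HALF_QUARTER, rel=1e-12)


def _ce(logits, targets, w, **kw):
    return loss_fn(Tensor(logits), targets, w, LossSpec(**kw)).item()


def test_loss_limit_equivalences():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(8, 4))
    targets = rng.integers(0, 4, size=8)
    w = np.array([1.0, 2.0, 0.5, 1.5])
    base = _ce(logits, targets, w, method="softmax_ce")
    assert _ce(logits, targets, w, method="confidence_penalty", beta=0.0) == \
        pytest.approx(base, abs=1e-9)
    assert _ce(logits, targets, w, method="confidence_penalty", beta=0.7, omega=0.0) == \
        pytest.approx(base, abs=1e-9)
    assert _ce(logits, targets, w, method="label_smoothing", epsilon=0.0) == \
        pytest.approx(base, abs=1e-9)


def test_confidence_hinge_inactive_above_threshold():
    # near-uniform logits: entropy close to ln k, far above a small omega
    logits = np.full((4, 3), 0.01)
    targets = np.array([0, 1, 2, 0])
    w = np.ones(3)
    assert _ce(logits, targets, w, method="confidence_penalty", beta=5.0, omega=0.2) == \
        pytest.approx(_ce(logits, targets, w, method="softmax_ce"), abs=1e-9)


def test_label_smoothing_full_epsilon_is_uniform_target():
    rng = np.random.default_rng(1)
    logits = rng.normal(size=(6, 3))
    targets = rng.integers(0, 3, size=6)
    w = np.ones(3)
    got = _ce(logits, targets, w, method="label_smoothing", epsilon=1.0)
    # uniform target: loss = mean over samples of -(1/k) sum_i log p_i
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    expect = float((-logp.mean(axis=1)).mean())
    assert got == pytest.approx(expect, abs=1e-9)


def test_doc_loss_worked_example():
    """k=2, sigmoid outputs (0.8, 0.3), y=0 -> -ln(0.8) - ln(0.7)."""
    logits = probs_to_logits(np.array([[0.8, 0.3]]), "sigmoid")
    got = loss_fn(Tensor(logits), np.array([0]), np.ones(2), LossSpec(method="doc")).item()
    assert got == pytest.approx(DOC_EXAMPLE_LOSS, rel=1e-9)


def test_probability_floor_keeps_loss_finite():
    logits = probs_to_logits(np.array([[0.0, 1.0]]), "softmax")
    got = _ce(logits, np.array([0]), np.ones(2), method="softmax_ce")
    assert np.isfinite(got)


# ---------------------------------------------------------------------------
# Schedule and early stopping
# ---------------------------------------------------------------------------

def test_lr_schedule_direct_arithmetic():
    assert lr_at_epoch(1, 0.001, 0.9, DEFAULT_MILESTONES) == 0.001
    assert lr_at_epoch(13, 0.001, 0.9, DEFAULT_MILESTONES) == pytest.approx(0.001 * 0.9 ** 2)
    assert lr_at_epoch(100, 0.001, 0.9, DEFAULT_MILESTONES) == \
        pytest.approx(0.001 * 0.9 ** 10)


def test_early_stop_scripted_stream():
    """Validation loss never improves after epoch 60 -> stop at epoch 80
    (patience 20, stopping armed at epoch 50 = ceil(150/3))."""
    stopper = EarlyStopper(patience=20, armed_epoch=math.ceil(150 / 3))
    stop_epoch = None
    for epoch in range(1, 151):
        val = 1.0 / epoch if epoch <= 60 else 1.0
        if stopper.update(epoch, val):
            stop_epoch = epoch
            break
    assert stop_epoch == 80
    assert stopper.best_epoch == 60


def test_early_stop_armed_before_patience():
    stopper = EarlyStopper(patience=20, armed_epoch=50)
    for epoch in range(1, 100):
        if stopper.update(epoch, 1.0):  # never improves after epoch 1
            assert epoch == 50
            break


def test_train_config_armed_epoch():
    assert TrainConfig(epochs=150).armed_epoch == 50
    assert TrainConfig(epochs=60).armed_epoch == 20


# ---------------------------------------------------------------------------
# Training loop (tiny but real)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_training_run(request):
    tiny_dataset = request.getfixturevalue("tiny_dataset")
    tiny_model_config = request.getfixturevalue("tiny_model_config")
    n = len(tiny_dataset)
    rng = np.random.default_rng(0)
    idx = rng.permutation(n)
    train = tiny_dataset.subset(idx[: int(0.8 * n)])
    val = tiny_dataset.subset(idx[int(0.8 * n):])
    cfg = TrainConfig(epochs=8, patience=3, batch_size=32)
    model, history = train_model(train, val, tiny_model_config, cfg, LossSpec(), seed=0)
    return train, val, cfg, model, history


def test_training_reduces_loss_and_records_history(tiny_training_run):
    _, _, _, model, history = tiny_training_run
    assert history["train_loss"][-1] < history["train_loss"][0]
    assert len(history["lr"]) == len(history["epoch"])
    assert history["lr"][0] == 0.001


def test_early_stop_restores_best_validation_weights(tiny_training_run):
    train, val, _, model, history = tiny_training_run
    from defenscan.training import _eval_loss, compute_class_weights
    # class weights as used in training (fitted on the training split)
    counts = {c: int((train.labels == i).sum()) for i, c in enumerate(train.classes)}
    w = compute_class_weights(counts)
    cw = np.array([w[c] for c in train.classes])
    got = _eval_loss(model, val, cw, LossSpec())
    assert got == pytest.approx(min(history["val_loss"]), rel=1e-6)


def test_ensemble_members_differ_and_default_size(tiny_dataset, tiny_model_config):
    n = len(tiny_dataset)
    train = tiny_dataset.subset(np.arange(0, n, 2))
    val = tiny_dataset.subset(np.arange(1, n, 2))
    cfg = TrainConfig(epochs=1, ensemble_size=3, batch_size=64)
    models, hists = train_ensemble(train, val, tiny_model_config, cfg, LossSpec())
    assert len(models) == 3
    sums = [sum(float(np.abs(p.data).sum()) for p in m.parameters().values())
            for m in models]
    assert len(set(np.round(sums, 6))) == 3  # different seeds, different weights


def test_duplicate_seeds_warn(tiny_dataset, tiny_model_config):
    n = len(tiny_dataset)
    train = tiny_dataset.subset(np.arange(0, n, 2))
    val = tiny_dataset.subset(np.arange(1, n, 2))
    cfg = TrainConfig(epochs=1, ensemble_size=2, batch_size=64)
    with pytest.warns(UserWarning, match="duplicate"):
        train_ensemble(train, val, tiny_model_config, cfg, LossSpec(), seeds=[1, 1])
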