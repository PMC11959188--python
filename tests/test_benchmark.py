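"""Ensemble aggregation, mean distance, and the benchmark grid structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defenscan.benchmark import (MODES, SCALINGS, ensemble_class_certainty,
                                 ensemble_predict, ensemble_predict_batch, mean_distance,
                                 run_benchmark)
from defenscan.model import ModelConfig
from defenscan.training import ArrayDataset, TrainConfig


def _brute_force_aggregate(members):
    members = np.asarray(members)
    avg = members.mean(axis=0)
    cls = int(np.argmax(avg))
    agreeing = [m[cls] for m in members if int(np.argmax(m)) == cls]
    cert = min(agreeing) if agreeing else float(avg[cls])
    return cls, cert


def test_all_members_agree_min_confidence():
    members = [(0.7, 0.3), (0.6, 0.4), (0.9, 0.1)]
    pred = ensemble_predict(members)
    assert (pred.class_index, pred.certainty) == _brute_force_aggregate(members) == (0, 0.6)


def test_disagreeing_member_excluded_from_minimum():
    members = [(0.9, 0.1), (0.4, 0.6), (0.8, 0.2)]
    pred = ensemble_predict(members)
    brute = _brute_force_aggregate(members)
    assert (pred.class_index, pred.certainty) == brute
    assert pred.class_index == 0 and pred.certainty == 0.8  # the 0.4 vote is excluded


def test_single_member_identity():
    pred = ensemble_predict([(0.2, 0.5, 0.3)])
    assert pred.class_index == 1 and pred.certainty == 0.5


def test_empty_member_list_rejected():
    with pytest.raises(ValueError):
        ensemble_predict(np.zeros((0, 3)))


@settings(deadline=None, max_examples=80)
@given(st.integers(min_value=1, max_value=5), st.integers(min_value=2, max_value=4),
       st.integers(min_value=0, max_value=10 ** 6))
def test_batch_matches_scalar_and_certainty_bound(m, k, seed):
    rng = np.random.default_rng(seed)
    raw = rng.dirichlet(np.ones(k), size=(m, 7))
    cls, cert = ensemble_predict_batch(raw)
    for i in range(7):
        bc, bcert = _brute_force_aggregate(raw[:, i])
        assert cls[i] == bc
        assert cert[i] == pytest.approx(bcert, rel=1e-12)
        # certainty never exceeds the best member probability for the class
        assert cert[i] <= raw[:, i, bc].max() + 1e-12


def test_fixed_class_certainty_fallback():
    probs = np.array([[[0.9, 0.1]], [[0.2, 0.8]]])  # members disagree
    cert0 = ensemble_class_certainty(probs, 0)
    assert cert0[0] == 0.9  # one member votes class 0 -> its own prob
    cert1 = ensemble_class_certainty(probs, 1)
    assert cert1[0] == 0.8
    none = ensemble_class_certainty(np.array([[[0.9, 0.1]]]), 1)
    assert none[0] == pytest.approx(0.1)  # no member votes class 1 -> averaged prob


# ---------------------------------------------------------------------------
# Mean distance
# ---------------------------------------------------------------------------

def test_mean_distance_examples():
    assert mean_distance([0.5, 0.7], [0.5, 0.7]) == 0.0
    assert mean_distance([1.0, 1.0], [0.7, 0.7]) == pytest.approx(0.30)
    assert mean_distance([0.7], [1.0]) == pytest.approx(-0.30)  # may be negative


def test_mean_distance_antisymmetry_and_permutation_invariance():
    rng = np.random.default_rng(0)
    a, b = rng.uniform(size=20), rng.uniform(size=15)
    d = mean_distance(a, b)
    assert mean_distance(b, a) == pytest.approx(-d)
    assert mean_distance(rng.permutation(a), rng.permutation(b)) == pytest.approx(d)
    with pytest.raises(ValueError):
        mean_distance([], [0.5])


# ---------------------------------------------------------------------------
# Grid structure (tiny end-to-end run)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_grid(request):
    ds = request.getfixturevalue("tiny_dataset")
    cfg = ModelConfig(k=3, l_max=60, conv_channels=8, gru_hidden=6, head_nodes=(6,),
                      linear_widths=(12, 8))
    rng = np.random.default_rng(1)
    unrel_idx = rng.choice(len(ds), size=20, replace=False)
    unrelated = ds.subset(unrel_idx)
    tc = TrainConfig(epochs=2, patience=2, batch_size=64, ensemble_size=2)
    table = run_benchmark(ds, unrelated, cfg, tc, folds=2, test_frac=0.25, seed=0,
                          methods=("softmax", "doc"))
    return table


def test_grid_has_one_row_per_combination(tiny_grid):
    assert len(tiny_grid) == 2 * len(SCALINGS) * len(MODES)
    assert not tiny_grid["failed"].astype(bool).any()
    combos = set(map(tuple, tiny_grid[["method", "scaling", "mode"]].values))
    assert len(combos) == len(tiny_grid)


def test_grid_values_in_range(tiny_grid):
    assert tiny_grid["dist"].between(-1, 1).all()
    assert tiny_grid["acc"].between(0, 1).all()


def test_temperature_preserves_single_mode_accuracy(tiny_grid):
    """Temperature scaling cannot reorder a model's classes, so single-mode
    accuracy is identical to unscaled for every method."""
    for method in ("softmax", "doc"):
        rows = tiny_grid[(tiny_grid["method"] == method) & (tiny_grid["mode"] == "single")]
        unscaled = rows[rows["scaling"] == "unscaled"]["acc"].iloc[0]
        temp = rows[rows["scaling"] == "temperature"]["acc"].iloc[0]
        assert temp == pytest.approx(unscaled, abs=1e-12)


def test_grid_deterministic_under_seed(tiny_dataset):
    cfg = ModelConfig(k=3, l_max=60, conv_channels=4, gru_hidden=4, head_nodes=(4,),
                      linear_widths=(8, 6))
    unrelated = tiny_dataset.subset(np.arange(10))
    tc = TrainConfig(epochs=1, batch_size=64, ensemble_size=1)
    kw = dict(folds=2, test_frac=0.25, seed=5, methods=("softmax",),
              scalings=("unscaled",), modes=("single",))
    t1 = run_benchmark(tiny_dataset, unrelated, cfg, tc, **kw)
    t2 = run_benchmark(tiny_dataset, unrelated, cfg, tc, **kw)
    assert t1["dist"].iloc[0] == t2["dist"].iloc[0]
    assert t1["acc"].iloc[0] == t2["acc"].iloc[0]
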