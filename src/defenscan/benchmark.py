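"""Ensemble aggregation, the related-vs-unrelated mean distance, and the
method x scaling x mode benchmark grid.

The benchmark trains one ensemble per training method (softmax
cross-entropy, DOC, label smoothing, confidence penalty) on each CV
fold, then crosses the resulting logits with every scaling (unscaled,
temperature, vector, matrix) and both prediction modes (single network,
3-member ensemble).  The figure of merit is the mean distance: the mean
top-class confidence on related (in-distribution) test proteins minus
the mean top-class confidence on unrelated proteins — larger means
unrelated proteins are easier to reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibratorState, apply_calibrator, fit_affine, fit_temperature
from .io_features import DescriptorScaler
from .model import ModelConfig, head_probs
from .training import ArrayDataset, LossSpec, TrainConfig, stratified_split, train_ensemble

METHODS = ("softmax", "doc", "smoothing", "penalize")
SCALINGS = ("unscaled", "temperature", "vector", "matrix")
MODES = ("single", "ensemble")

_METHOD_LOSS = {
    "softmax": "softmax_ce",
    "doc": "doc",
    "smoothing": "label_smoothing",
    "penalize": "confidence_penalty",
}


@dataclass
class EnsemblePrediction:
    """Aggregated call: argmax of the member-averaged probabilities, with the
    certainty taken as the lowest member confidence that agrees with it."""

    class_index: int
    certainty: float
    member_probs: np.ndarray  # (M, k)


def ensemble_predict(member_probs) -> EnsemblePrediction:
    """Aggregate one sample's member probability vectors.

    The class is the argmax of the member average; the certainty is the
    minimum, over members whose own argmax equals that class, of their
    probability for it.  If no member agrees (possible, since the
    averaged argmax need not match any member's), the averaged
    probability of the class is used.
    """
    member_probs = np.asarray(member_probs, dtype=np.float64)
    if member_probs.ndim != 2 or member_probs.shape[0] < 1:
        raise ValueError("need at least one member probability vector")
    avg = member_probs.mean(axis=0)
    cls = int(avg.argmax())
    agree = member_probs.argmax(axis=1) == cls
    if agree.any():
        certainty = float(member_probs[agree, cls].min())
    else:
        certainty = float(avg[cls])
    return EnsemblePrediction(class_index=cls, certainty=certainty, member_probs=member_probs)


def ensemble_predict_batch(member_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`ensemble_predict` over (M, N, k) -> (classes, certainties)."""
    member_probs = np.asarray(member_probs, dtype=np.float64)
    M, N, k = member_probs.shape
    avg = member_probs.mean(axis=0)                      # (N, k)
    cls = avg.argmax(axis=1)                             # (N,)
    p_cls = member_probs[:, np.arange(N), cls]           # (M, N)
    agree = member_probs.argmax(axis=2) == cls[None, :]  # (M, N)
    masked = np.where(agree, p_cls, np.inf)
    cert = masked.min(axis=0)
    none_agree = ~agree.any(axis=0)
    cert[none_agree] = avg[np.arange(N), cls][none_agree]
    return cls, cert


def ensemble_class_certainty(member_probs: np.ndarray, class_index: int) -> np.ndarray:
    """Certainty attributed to a fixed class for each sample in (M, N, k).

    Minimum probability over members whose argmax is that class; where no
    member votes for it, the member-averaged probability of the class.
    """
    member_probs = np.asarray(member_probs, dtype=np.float64)
    M, N, k = member_probs.shape
    p_cls = member_probs[:, :, class_index]
    agree = member_probs.argmax(axis=2) == class_index
    masked = np.where(agree, p_cls, np.inf)
    cert = masked.min(axis=0)
    none = ~agree.any(axis=0)
    cert[none] = p_cls.mean(axis=0)[none]
    return cert


def mean_distance(related_certainties, unrelated_certainties) -> float:
    """mean(related top-class confidence) - mean(unrelated top-class confidence)."""
    related = np.asarray(related_certainties, dtype=np.float64)
    unrelated = np.asarray(unrelated_certainties, dtype=np.float64)
    if related.size == 0 or unrelated.size == 0:
        raise ValueError("both certainty lists must be non-empty")
    return float(related.mean() - unrelated.mean())


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------

def _fit_scaler_state(kind: str, val_logits: np.ndarray, val_labels: np.ndarray
                      ) -> CalibratorState:
    if kind == "unscaled":
        return CalibratorState(kind="none")
    if kind == "temperature":
        return fit_temperature(val_logits, val_labels)
    return fit_affine(val_logits, val_labels, kind=kind)


def _standardized(ds: ArrayDataset, scaler: DescriptorScaler) -> ArrayDataset:
    return ArrayDataset(ds.onehot, ds.lengths, scaler.transform(ds.descriptors),
                        ds.labels, ds.classes)


def run_benchmark(related: ArrayDataset, unrelated: ArrayDataset,
                  model_config: ModelConfig, train_config: TrainConfig,
                  folds: int = 5, methods=METHODS, scalings=SCALINGS, modes=MODES,
                  seed: int = 0, loss_params: dict | None = None,
                  test_frac: float | None = None) -> pd.DataFrame:
    """Full benchmark grid; one row per (method, scaling, mode) with fold means/SDs.

    `related` and `unrelated` carry raw (unstandardized) descriptors; the
    descriptor scaler is refitted on each fold's training split.  Scalers
    are fitted per ensemble member by NLL on the in-distribution
    validation split; the unrelated set enters only through the distance.
    Rows whose training fails are flagged and the grid continues.
    """
    plan = stratified_split(related.labels, test_frac=test_frac or 1.0 / folds,
                            n_folds=folds, seed=seed)
    acc: dict[tuple, list[float]] = {}
    dist: dict[tuple, list[float]] = {}
    failed: dict[tuple, str] = {}
    loss_params = loss_params or {}

    for f in range(folds):
        fold = plan.folds[f]
        raw_train = related.subset(fold["train"])
        scaler = DescriptorScaler.fit(raw_train.descriptors)
        train = _standardized(raw_train, scaler)
        val = _standardized(related.subset(fold["val"]), scaler)
        test = _standardized(related.subset(fold["test"]), scaler)
        unrel = _standardized(unrelated, scaler)

        for mi, method in enumerate(methods):
            spec = LossSpec(method=_METHOD_LOSS[method], **loss_params)
            seeds = [(seed * 100003 + f * 1009 + mi * 101 + m) % (2 ** 31 - 1)
                     for m in range(train_config.ensemble_size)]
            try:
                models, _ = train_ensemble(train, val, model_config, train_config,
                                           spec, seeds=seeds)
            except Exception as exc:  # flagged row, grid continues
                for scaling in scalings:
                    for mode in modes:
                        failed[(method, scaling, mode)] = str(exc)
                continue
            head = models[0].config.output_head
            val_logits = [m.predict_logits(val.onehot, val.lengths, val.descriptors)
                          for m in models]
            test_logits = [m.predict_logits(test.onehot, test.lengths, test.descriptors)
                           for m in models]
            unrel_logits = [m.predict_logits(unrel.onehot, unrel.lengths, unrel.descriptors)
                            for m in models]
            for scaling in scalings:
                states = [_fit_scaler_state(scaling, vl, val.labels) for vl in val_logits]
                test_probs = np.stack([apply_calibrator(tl, st, head)
                                       for tl, st in zip(test_logits, states)])
                unrel_probs = np.stack([apply_calibrator(ul, st, head)
                                        for ul, st in zip(unrel_logits, states)])
                for mode in modes:
                    if mode == "single":
                        t_cls = test_probs[0].argmax(axis=1)
                        t_cert = test_probs[0].max(axis=1)
                        u_cert = unrel_probs[0].max(axis=1)
                    else:
                        t_cls, t_cert = ensemble_predict_batch(test_probs)
                        _, u_cert = ensemble_predict_batch(unrel_probs)
                    key = (method, scaling, mode)
                    acc.setdefault(key, []).append(float((t_cls == test.labels).mean()))
                    dist.setdefault(key, []).append(mean_distance(t_cert, u_cert))

    rows = []
    for method in methods:
        for scaling in scalings:
            for mode in modes:
                key = (method, scaling, mode)
                if key in failed:
                    rows.append({"method": method, "scaling": scaling, "mode": mode,
                                 "dist": np.nan, "acc": np.nan, "dist_sd": np.nan,
                                 "acc_sd": np.nan, "failed": failed[key]})
                    continue
                d, a = np.asarray(dist[key]), np.asarray(acc[key])
                rows.append({"method": method, "scaling": scaling, "mode": mode,
                             "dist": d.mean(), "acc": a.mean(),
                             "dist_sd": d.std(), "acc_sd": a.std(), "failed": ""})
    return pd.DataFrame(rows)
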