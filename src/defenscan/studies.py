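"""Desk-scale synthetic study conditions.

Two frozen setups used by the validation suite and the reproduction
script:

* a Zorya-like open-set benchmark family — four related subclasses plus
  an unrelated background class, 300 proteins per class — over which the
  method x scaling x mode grid is run;
* a three-class motif dataset on which the full published training
  schedule (Adam lr 0.001, 150-epoch budget, multi-step 0.9 decay, early
  stopping armed after a third of the budget) is exercised end to end.

Problem sizes (sequence lengths 40-90 residues, reduced layer widths,
2-fold cross-validation for the grid) are desk-scale choices: small
enough to run on one CPU in minutes, large enough that every model
trains to a clear signal.  The generator statistics themselves (class
counts, motif length 8, implant probability 1, uniform background) are
fixed here and not tuned per run.
"""

from __future__ import annotations

import numpy as np

from .io_features import DescriptorScaler, encode_batch
from .model import ModelConfig
from .simulate import BACKGROUND_LABEL, FamilySpec, generate_family_dataset
from .training import ArrayDataset, TrainConfig

BENCHMARK_CLASSES = ["ZorA", "ZorB", "ZorC", "ZorD"]


def benchmark_family_spec(seed: int) -> FamilySpec:
    """Four Zorya-like subclasses + unrelated background, 300 proteins each."""
    return FamilySpec(n_classes=4, n_per_class=300, motif_length=8,
                      length_range=(40, 70), n_unrelated=300,
                      class_names=list(BENCHMARK_CLASSES), seed=seed)


def benchmark_model_config() -> ModelConfig:
    return ModelConfig(k=4, l_max=70, conv_channels=48, gru_hidden=48,
                       head_nodes=(16,), linear_widths=(64, 32))


def benchmark_train_config() -> TrainConfig:
    return TrainConfig(epochs=60, patience=12, batch_size=64, ensemble_size=3)


def benchmark_datasets(seed: int) -> tuple[ArrayDataset, ArrayDataset]:
    """Encoded related/unrelated datasets with raw (per-fold standardized later)
    descriptors."""
    records, labels = generate_family_dataset(benchmark_family_spec(seed))
    rel = [r for r, l in zip(records, labels.label) if l != BACKGROUND_LABEL]
    unrel = [r for r, l in zip(records, labels.label) if l == BACKGROUND_LABEL]
    y = np.array([BENCHMARK_CLASSES.index(l) for l in labels.label
                  if l != BACKGROUND_LABEL])
    l_max = benchmark_model_config().l_max
    oh, ln, de = encode_batch(rel, l_max)
    related = ArrayDataset(oh, ln, de, y, list(BENCHMARK_CLASSES))
    oh, ln, de = encode_batch(unrel, l_max)
    unrelated = ArrayDataset(oh, ln, de, np.zeros(len(unrel), dtype=int),
                             list(BENCHMARK_CLASSES))
    return related, unrelated


def motif_training_spec(seed: int) -> FamilySpec:
    """Three motif classes x 300 proteins for the end-to-end schedule run."""
    return FamilySpec(n_classes=3, n_per_class=300, motif_length=8,
                      length_range=(50, 90), seed=seed)


def motif_model_config() -> ModelConfig:
    return ModelConfig(k=3, l_max=90, conv_channels=48, gru_hidden=64,
                       head_nodes=(16,), linear_widths=(64, 32))


def motif_train_config() -> TrainConfig:
    """The full published schedule; batch 32 so the fixed 150-epoch budget
    delivers enough gradient updates at this dataset scale."""
    return TrainConfig(batch_size=32)


def motif_dataset(seed: int) -> ArrayDataset:
    records, labels = generate_family_dataset(motif_training_spec(seed))
    classes = sorted(set(labels.label))
    y = np.array([classes.index(l) for l in labels.label])
    oh, ln, de = encode_batch(records, motif_model_config().l_max)
    return ArrayDataset(oh, ln, de, y, classes)


def standardize_fold(dataset: ArrayDataset, train_idx: np.ndarray) -> tuple[
        ArrayDataset, DescriptorScaler]:
    scaler = DescriptorScaler.fit(dataset.descriptors[train_idx])
    return ArrayDataset(dataset.onehot, dataset.lengths,
                        scaler.transform(dataset.descriptors), dataset.labels,
                        dataset.classes), scaler
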