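import numpy as np
import pytest

from defenscan import (ArrayDataset, DescriptorScaler, FamilySpec, ModelConfig,
                       encode_batch, generate_family_dataset)


@pytest.fixture(scope="session")
def tiny_family():
    """3 motif classes x 40 proteins plus 30 background proteins."""
    spec = FamilySpec(n_classes=3, n_per_class=40, motif_length=8,
                      length_range=(40, 60), n_unrelated=30, seed=7)
    records, labels = generate_family_dataset(spec)
    return spec, records, labels


@pytest.fixture(scope="session")
def tiny_dataset(tiny_family):
    """Encoded ArrayDataset over the 3 motif classes (background excluded)."""
    _, records, labels = tiny_family
    keep = [i for i, l in enumerate(labels.label) if l != "background"]
    records = [records[i] for i in keep]
    classes = sorted({labels.label[i] for i in keep})
    y = np.array([classes.index(labels.label[i]) for i in keep])
    onehot, lengths, desc = encode_batch(records, 60)
    scaler = DescriptorScaler.fit(desc)
    return ArrayDataset(onehot, lengths, scaler.transform(desc), y, classes)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(k=3, l_max=60, conv_channels=8, gru_hidden=6,
                       head_nodes=(6,), linear_widths=(12, 8))
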