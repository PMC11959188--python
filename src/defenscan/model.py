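"""Classifier architecture and probabilistic output heads.

The trunk follows the published design: a single 1-D convolution
(kernel 7, stride 5) over the one-hot protein, two bidirectional GRU
layers, and three linear layers.  A second head processes the
12-descriptor vector; its output is concatenated with the final GRU
states before the linear stack.  The same trunk serves both output
heads — a softmax over the k logits, or k independent one-vs-rest
sigmoids (the DOC scheme) — only the interpretation of the logits
differs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_features import ALPHABET, N_DESCRIPTORS, DescriptorScaler
from .nn import BiGRU, Conv1d, Linear, Module, Tensor, concat, no_grad

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The published values pin conv kernel 7 / stride 5 and 2 bidirectional
    GRU layers; layer widths were tuned by the original authors but not
    reported, so the defaults here are configurable desk-scale choices.
    `linear_widths` gives the hidden widths of the first two of the three
    linear layers; the third always maps to k logits.
    """

    k: int = 2
    l_max: int = 1000
    conv_kernel: int = 7
    conv_stride: int = 5
    conv_channels: int = 64
    gru_layers: int = 2
    gru_hidden: int = 128
    head_nodes: tuple[int, ...] = (32,)
    linear_widths: tuple[int, ...] = (256, 64)
    output_head: str = "softmax"   # or "sigmoid"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.output_head not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown output head {self.output_head!r}")
        if self.l_max < self.conv_kernel:
            raise ValueError("l_max must be at least the conv kernel size")
        self.head_nodes = tuple(self.head_nodes)
        self.linear_widths = tuple(self.linear_widths)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax: p_i = exp(z_i) / sum_j exp(z_j) with max subtraction."""
    z = np.asarray(z, dtype=np.float64)
    m = z.max(axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Elementwise logistic transform (the one-vs-rest DOC head)."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def head_probs(logits: np.ndarray, output_head: str) -> np.ndarray:
    if output_head == "softmax":
        return softmax(logits)
    if output_head == "sigmoid":
        return sigmoid(logits)
    raise ValueError(f"unknown output head {output_head!r}")


class DefenseClassifier(Module):
    """conv → bi-GRU ×2 → [concat descriptor head] → 3 linear layers → k logits."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        A = len(ALPHABET)
        self.conv = self.add_module(
            "conv", Conv1d(A, config.conv_channels, config.conv_kernel, config.conv_stride, rng))
        self.gru = self.add_module(
            "gru", BiGRU(config.conv_channels, config.gru_hidden, config.gru_layers, rng))
        widths_in = N_DESCRIPTORS
        for i, w in enumerate(config.head_nodes):
            self.add_module(f"head{i}", Linear(widths_in, w, rng))
            widths_in = w
        trunk_in = 2 * config.gru_hidden + widths_in
        dims = [trunk_in, *config.linear_widths, config.k]
        for i in range(len(dims) - 1):
            self.add_module(f"fc{i}", Linear(dims[i], dims[i + 1], rng))
        self.n_fc = len(dims) - 1

    def conv_out_lengths(self, seq_lengths: np.ndarray) -> np.ndarray:
        c = self.config
        t = (np.asarray(seq_lengths) - c.conv_kernel) // c.conv_stride + 1
        return np.maximum(t, 1)

    def forward(self, onehot: np.ndarray, seq_lengths: np.ndarray,
                descriptors: np.ndarray) -> Tensor:
        """Logits for a batch; padded positions never influence the GRU states."""
        x = self.conv(Tensor(onehot)).relu()
        h = self.gru(x, self.conv_out_lengths(seq_lengths))
        d = Tensor(descriptors)
        for i in range(len(self.config.head_nodes)):
            d = self._children[f"head{i}"](d).relu()
        z = concat([h, d], axis=1)
        for i in range(self.n_fc):
            z = self._children[f"fc{i}"](z)
            if i < self.n_fc - 1:
                z = z.relu()
        return z

    def predict_logits(self, onehot: np.ndarray, seq_lengths: np.ndarray,
                       descriptors: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode logits, batched, no graph construction."""
        outs = []
        with no_grad():
            for i in range(0, len(onehot), batch_size):
                sl = slice(i, i + batch_size)
                outs.append(self.forward(onehot[sl], seq_lengths[sl], descriptors[sl]).data)
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.config.k))

    def predict_probs(self, onehot, seq_lengths, descriptors, batch_size: int = 256) -> np.ndarray:
        return head_probs(self.predict_logits(onehot, seq_lengths, descriptors, batch_size),
                          self.config.output_head)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, models: list[DefenseClassifier], classes: list[str],
                    scaler: DescriptorScaler, calibrator: dict | None = None,
                    doc_thresholds: dict | None = None, extra: dict | None = None) -> None:
    """Single-archive checkpoint: ensemble weights, config, label vocabulary,
    descriptor-standardization statistics, and calibrator state."""
    arrays: dict[str, np.ndarray] = {}
    for m, model in enumerate(models):
        for name, data in model.state().items():
            arrays[f"model{m}/{name}"] = data
    arrays["scaler/mean"] = scaler.mean
    arrays["scaler/std"] = scaler.std
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "n_models": len(models),
        "config": asdict(models[0].config),
        "classes": list(classes),
        "calibrator": calibrator,
        "doc_thresholds": doc_thresholds,
        "extra": extra or {},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`; returns (models, classes, scaler, meta)."""
    with np.load(str(path)) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    if meta["schema"] != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
    cfg = dict(meta["config"])
    cfg["head_nodes"] = tuple(cfg["head_nodes"])
    cfg["linear_widths"] = tuple(cfg["linear_widths"])
    config = ModelConfig(**cfg)
    scaler = DescriptorScaler(mean=arrays.pop("scaler/mean"), std=arrays.pop("scaler/std"))
    models = []
    for m in range(meta["n_models"]):
        model = DefenseClassifier(config, seed=0)
        prefix = f"model{m}/"
        state = {k[len(prefix):]: v for k, v in arrays.items() if k.startswith(prefix)}
        model.load_state(state)
        models.append(model)
    return models, meta["classes"], scaler, meta
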