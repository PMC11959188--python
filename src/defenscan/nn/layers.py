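"""Neural-network building blocks on top of the autodiff core.

Layers hold named :class:`Parameter` tensors; a module exposes
``parameters()`` as an ordered ``{name: Tensor}`` dict so optimizers and
checkpoints can address weights by name.  Sequences are padded; every
recurrent update is gated by a per-timestep mask so padding never leaks
into hidden states.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import _GRAD_ENABLED, Tensor, concat

__all__ = ["Parameter", "Module", "Linear", "Conv1d", "GRUCellParams", "BiGRU",
           "gru_scan"]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Tiny parameter container; subclasses register params in ``self._params``."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        p = Parameter(data)
        self._params[name] = p
        return p

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def state(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters().items()}


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param("w", _uniform_init(rng, (in_features, out_features), in_features))
        self.b = self.add_param("b", _uniform_init(rng, (out_features,), in_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """1-D convolution over the sequence axis of (B, L, C_in) input.

    Implemented as window gather + matmul; output length is
    floor((L - kernel) / stride) + 1, matching the usual valid-mode
    geometry.  Inputs shorter than one kernel are expected to be padded
    to at least `kernel` positions by the encoder.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.w = self.add_param("w", _uniform_init(rng, (kernel * in_channels, out_channels), fan_in))
        self.b = self.add_param("b", _uniform_init(rng, (out_channels,), fan_in))

    def out_len(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        T = self.out_len(L)
        starts = np.arange(T) * self.stride
        idx = starts[:, None] + np.arange(self.kernel)[None, :]  # (T, k)
        windows = x[:, idx]                   # (B, T, k, C)
        flat = windows.reshape(B, T, self.kernel * C)
        return flat @ self.w + self.b


class GRUCellParams(Module):
    """Weights of one GRU direction: gate order (reset, update, new)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        H = hidden_size
        self.hidden_size = H
        self.w_ih = self.add_param("w_ih", _uniform_init(rng, (input_size, 3 * H), H))
        self.w_hh = self.add_param("w_hh", _uniform_init(rng, (H, 3 * H), H))
        self.b_ih = self.add_param("b_ih", _uniform_init(rng, (3 * H,), H))
        self.b_hh = self.add_param("b_hh", _uniform_init(rng, (3 * H,), H))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        """Reference single-step recurrence; :func:`gru_scan` implements the
        same math as one fused op over the whole sequence."""
        H = self.hidden_size
        gi = x_t @ self.w_ih + self.b_ih
        gh = h @ self.w_hh + self.b_hh
        r = (gi[:, 0:H] + gh[:, 0:H]).sigmoid()
        z = (gi[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gi[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h


def gru_scan(cell: GRUCellParams, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
    """Run one GRU direction over (B, T, C) input as a single fused op.

    The whole scan — including backpropagation through time — is
    implemented directly in NumPy rather than composed from elementary
    autograd ops: the recurrence would otherwise generate thousands of
    graph nodes per batch.  `mask` is (B, T) with padding at the tail;
    masked steps leave the hidden state unchanged, so for the reversed
    direction (implemented by flipping the time axis) the state stays at
    its initial zeros until the valid region begins.  Returns the (B, T, H)
    per-step hidden states in the original time order.
    """
    H = cell.hidden_size
    W_ih, W_hh = cell.w_ih.data, cell.w_hh.data
    b_ih, b_hh = cell.b_ih.data, cell.b_hh.data
    xd = x.data[:, ::-1] if reverse else x.data
    md = mask[:, ::-1] if reverse else mask
    B, T, C = xd.shape

    gi = xd @ W_ih + b_ih                      # (B, T, 3H)
    h = np.zeros((B, H))
    hs_prev = np.empty((B, T, H))              # h_{t-1}
    rs = np.empty((B, T, H))
    zs = np.empty((B, T, H))
    ns = np.empty((B, T, H))
    ghn = np.empty((B, T, H))                  # h_prev-side input of the n gate
    outs = np.empty((B, T, H))
    for t in range(T):
        hs_prev[:, t] = h
        gh = h @ W_hh + b_hh
        rz = _sigm(gi[:, t, 0:2 * H] + gh[:, 0:2 * H])
        r, z = rz[:, 0:H], rz[:, H:]
        n = np.tanh(gi[:, t, 2 * H:] + r * gh[:, 2 * H:])
        m = md[:, t:t + 1]
        h = m * ((1.0 - z) * n + z * h) + (1.0 - m) * h
        rs[:, t], zs[:, t], ns[:, t], ghn[:, t] = r, z, n, gh[:, 2 * H:]
        outs[:, t] = h

    out_data = outs[:, ::-1].copy() if reverse else outs
    parents = (x, cell.w_ih, cell.w_hh, cell.b_ih, cell.b_hh)
    if not (_GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)):
        return Tensor(out_data)

    def backward(g):
        gd = g[:, ::-1] if reverse else g
        dgi = np.empty((B, T, 3 * H))
        dW_hh = np.zeros_like(W_hh)
        db_hh = np.zeros_like(b_hh)
        carry = np.zeros((B, H))
        dgh = np.empty((B, 3 * H))
        for t in range(T - 1, -1, -1):
            m = md[:, t:t + 1]
            dh = gd[:, t] + carry
            d_cand = m * dh
            dh_prev = (1.0 - m) * dh
            r, z, n = rs[:, t], zs[:, t], ns[:, t]
            h_prev = hs_prev[:, t]
            dz = d_cand * (h_prev - n)
            dn = d_cand * (1.0 - z)
            dh_prev += d_cand * z
            da_n = dn * (1.0 - n * n)
            dr = da_n * ghn[:, t]
            dgh[:, 0:H] = da_r = dr * r * (1.0 - r)
            dgh[:, H:2 * H] = da_z = dz * z * (1.0 - z)
            dgh[:, 2 * H:] = da_n * r
            dgi[:, t, 0:H] = da_r
            dgi[:, t, H:2 * H] = da_z
            dgi[:, t, 2 * H:] = da_n
            dh_prev += dgh @ W_hh.T
            dW_hh += h_prev.T @ dgh
            db_hh += dgh.sum(axis=0)
            carry = dh_prev
        flat = dgi.reshape(B * T, 3 * H)
        dW_ih = xd.reshape(B * T, C).T @ flat
        db_ih = flat.sum(axis=0)
        dX = (flat @ W_ih.T).reshape(B, T, C)
        if reverse:
            dX = dX[:, ::-1].copy()
        return (dX, dW_ih, dW_hh, db_ih, db_hh)

    return Tensor(out_data, requires_grad=True, _parents=parents, _backward=backward)


def _sigm(a: np.ndarray) -> np.ndarray:
    # stable logistic without boolean gather: exp of -|a| never overflows
    e = np.exp(-np.abs(a))
    return np.where(a >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


class BiGRU(Module):
    """Stack of bidirectional GRU layers with masked state updates.

    Padding sits at the end of each sequence.  The update mask freezes a
    sample's hidden state once its valid region ends, so the forward
    direction's state at the last timestep equals its state at the last
    valid position, and the backward direction (scanned from the padded
    tail) stays at its initial zeros until it enters the valid region.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.num_layers = num_layers
        self.hidden_size = hidden_size
        for layer in range(num_layers):
            in_size = input_size if layer == 0 else 2 * hidden_size
            self.add_module(f"l{layer}_fwd", GRUCellParams(in_size, hidden_size, rng))
            self.add_module(f"l{layer}_bwd", GRUCellParams(in_size, hidden_size, rng))

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        """x: (B, T, C); lengths: valid timesteps per sample. Returns (B, 2H)."""
        B, T, _ = x.shape
        steps = np.arange(T)
        mask = (steps[None, :] < np.asarray(lengths)[:, None]).astype(np.float64)
        outs_f = outs_b = None
        for layer in range(self.num_layers):
            outs_f = gru_scan(self._children[f"l{layer}_fwd"], x, mask, reverse=False)
            outs_b = gru_scan(self._children[f"l{layer}_bwd"], x, mask, reverse=True)
            x = concat([outs_f, outs_b], axis=2)
        # forward state freezes at the last valid step; reversed state ends at t=0
        return concat([outs_f[:, T - 1], outs_b[:, 0]], axis=1)
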