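"""Post-hoc calibration and the classify-or-reject decision.

Three logit-scaling families (temperature, vector, matrix — the
multiclass Platt-scaling variants) are fitted by negative log-likelihood
on a validation set.  DOC rejection thresholds are fitted per class from
the predicted probabilities of correctly classified validation examples:
each probability is mirrored about the class center to complete a
Gaussian, and the threshold is t_i = max(0.5, 1 - alpha * sigma_i).
A protein is rejected when every class probability falls below its
threshold, otherwise it is assigned the argmax class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import head_probs, sigmoid, softmax

REJECT = -1


@dataclass
class CalibratorState:
    """Fitted scaling parameters: a temperature T, or an affine map W, b."""

    kind: str = "none"           # none | temperature | vector | matrix
    T: float = 1.0
    W: np.ndarray | None = None  # (k,) for vector, (k, k) for matrix
    b: np.ndarray | None = None
    converged: bool = True
    fitted_on: str = ""

    def __post_init__(self):
        if self.kind not in ("none", "temperature", "vector", "matrix"):
            raise ValueError(f"unknown calibrator kind {self.kind!r}")
        if self.kind == "temperature" and self.T <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "T": self.T,
                "W": None if self.W is None else self.W.tolist(),
                "b": None if self.b is None else self.b.tolist(),
                "converged": self.converged, "fitted_on": self.fitted_on}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratorState":
        return cls(kind=d["kind"], T=d["T"],
                   W=None if d["W"] is None else np.asarray(d["W"]),
                   b=None if d["b"] is None else np.asarray(d["b"]),
                   converged=d.get("converged", True), fitted_on=d.get("fitted_on", ""))


@dataclass
class DocThresholds:
    """Per-class rejection thresholds t_i = max(0.5, 1 - alpha * sigma_i)."""

    t: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    alpha: float
    flagged: list[int] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.t < 0.5) or np.any(self.t > 1.0):
            raise ValueError("thresholds must lie in [0.5, 1]")

    def with_alpha(self, alpha: float) -> "DocThresholds":
        """Recompute thresholds from the same fitted mu/sigma at a different alpha."""
        t = np.maximum(0.5, 1.0 - alpha * self.sigma)
        return DocThresholds(t=t, mu=self.mu, sigma=self.sigma, alpha=alpha,
                             flagged=list(self.flagged))

    def to_dict(self) -> dict:
        return {"t": self.t.tolist(), "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
                "alpha": self.alpha, "flagged": self.flagged}

    @classmethod
    def from_dict(cls, d: dict) -> "DocThresholds":
        return cls(t=np.asarray(d["t"]), mu=np.asarray(d["mu"]),
                   sigma=np.asarray(d["sigma"]), alpha=d["alpha"],
                   flagged=list(d.get("flagged", [])))


# ---------------------------------------------------------------------------
# Scaling fits
# ---------------------------------------------------------------------------

def _nll(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p).mean())


def fit_temperature(logits: np.ndarray, labels: np.ndarray, tol: float = 1e-6
                    ) -> CalibratorState:
    """Scalar T > 0 minimizing validation NLL of softmax(z / T)."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("temperature fitting needs at least 2 classes present")

    def objective(log_t: float) -> float:
        return _nll(softmax(logits / np.exp(log_t)), labels)

    res = optimize.minimize_scalar(objective, bounds=(-6.0, 6.0), method="bounded",
                                   options={"xatol": tol})
    return CalibratorState(kind="temperature", T=float(np.exp(res.x)),
                           converged=bool(res.success))


def _affine_apply(logits: np.ndarray, W: np.ndarray, b: np.ndarray, kind: str) -> np.ndarray:
    if kind == "vector":
        return logits * W[None, :] + b[None, :]
    return logits @ W.T + b[None, :]


def fit_affine(logits: np.ndarray, labels: np.ndarray, kind: str = "vector",
               max_iter: int = 500, seed: int = 0) -> CalibratorState:
    """W, b minimizing cross-entropy of softmax(W z + b); W is diagonal for `vector`.

    L-BFGS with analytic gradients from the identity at W=I, b=0; if the
    iteration cap is hit the best iterate is returned with converged=False.
    """
    if kind not in ("vector", "matrix"):
        raise ValueError("kind must be 'vector' or 'matrix'")
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("affine scaling needs at least 2 classes present")
    n, k = logits.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0

    def unpack(x):
        if kind == "vector":
            return x[:k], x[k:]
        return x[:k * k].reshape(k, k), x[k * k:]

    def objective(x):
        W, b = unpack(x)
        z = _affine_apply(logits, W, b, kind)
        p = softmax(z)
        loss = _nll(p, labels)
        g = (p - onehot) / n      # d loss / d z
        if kind == "vector":
            gW = (g * logits).sum(axis=0)
        else:
            gW = g.T @ logits
        gb = g.sum(axis=0)
        return loss, np.concatenate([gW.ravel(), gb])

    x0 = np.concatenate([np.ones(k) if kind == "vector" else np.eye(k).ravel(), np.zeros(k)])
    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter})
    W, b = unpack(res.x)
    return CalibratorState(kind=kind, W=np.asarray(W), b=np.asarray(b),
                           converged=bool(res.success))


def apply_calibrator(logits: np.ndarray, state: CalibratorState,
                     output_head: str = "softmax") -> np.ndarray:
    """Calibrated probabilities.  For sigmoid-head (DOC) models the scaled
    logits pass through the sigmoid instead of the softmax."""
    logits = np.asarray(logits, dtype=np.float64)
    if state.kind == "none":
        z = logits
    elif state.kind == "temperature":
        z = logits / state.T
    else:
        if state.W is None or state.W.shape[-1] != logits.shape[-1]:
            raise ValueError("calibrator shape does not match logits")
        z = _affine_apply(logits, state.W, state.b, state.kind)
    return head_probs(z, output_head)


# ---------------------------------------------------------------------------
# DOC thresholds
# ---------------------------------------------------------------------------

def fit_doc_thresholds(correct_probs_per_class: list[np.ndarray], alpha: float = 3.0,
                       mirror_center: str = "mean") -> DocThresholds:
    """Fit per-class rejection thresholds from correct-prediction probabilities.

    Each class's probabilities form one half of a Gaussian; the other half
    is constructed by mirroring every point p about the center c
    (the class mean by default, or 1.0 with mirror_center="one") to 2c - p.
    sigma is the population standard deviation of the combined set and
    t_i = max(0.5, 1 - alpha * sigma).  Classes with no correct
    predictions get t_i = 0.5 and are flagged.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if mirror_center not in ("mean", "one"):
        raise ValueError("mirror_center must be 'mean' or 'one'")
    k = len(correct_probs_per_class)
    t = np.empty(k)
    mu = np.empty(k)
    sig = np.empty(k)
    flagged = []
    for i, probs in enumerate(correct_probs_per_class):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.size == 0:
            t[i], mu[i], sig[i] = 0.5, np.nan, np.nan
            flagged.append(i)
            continue
        c = probs.mean() if mirror_center == "mean" else 1.0
        combined = np.concatenate([probs, 2.0 * c - probs])
        mu[i] = c
        sig[i] = combined.std()          # population (N-denominator) formula
        t[i] = max(0.5, 1.0 - alpha * sig[i])
    return DocThresholds(t=t, mu=mu, sigma=sig, alpha=alpha, flagged=flagged)


def correct_probs_by_class(probs: np.ndarray, labels: np.ndarray, k: int
                           ) -> list[np.ndarray]:
    """Top-class probabilities of correctly classified samples, grouped by class."""
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    pred = probs.argmax(axis=1)
    out = []
    for i in range(k):
        hit = (pred == i) & (labels == i)
        out.append(probs[hit, i])
    return out


def classify_or_reject(probs: np.ndarray, thresholds: DocThresholds) -> int:
    """REJECT (-1) iff every p_i < t_i; otherwise the argmax class
    (ties broken by lowest class index, as argmax does)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[-1] != len(thresholds.t):
        raise ValueError("probability vector does not match threshold vocabulary")
    if np.all(probs < thresholds.t):
        return REJECT
    return int(probs.argmax())
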