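"""Sample-adaptive gating: per-sample feature dynamic weights and the
per-modality model-confidence (MCC) scalar.

The feature dynamic transform is S_d = tanh(W * sigmoid(S)) elementwise,
with W produced per sample by a small MLP of the same width as the input.
MCC(S_hat) = sigmoid(S_hat . w) scores one modality's trustworthiness for
one sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._autodiff import Linear, Tensor


@dataclass
class DynamicWeightRecord:
    """Per-sample, per-feature adaptive weights and the gated output."""

    sample_id: str
    modality: str
    weights: np.ndarray
    gated: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.gated = np.asarray(self.gated, dtype=float)
        if self.weights.shape != self.gated.shape:
            raise ValueError("weights and gated output must have equal length")
        if np.any(np.abs(self.gated) >= 1):
            raise ValueError("gated output must lie strictly inside (-1, 1)")


@dataclass
class ModalityConfidence:
    sample_id: str
    modality: str
    mcc: float

    def __post_init__(self):
        if not (0 < self.mcc < 1):
            raise ValueError("mcc must lie in (0, 1)")


def feature_dynamic(S, W):
    """Elementwise gate S_d[i] = tanh(w_i * sigmoid(s_i)).

    Accepts numpy arrays or autodiff Tensors of equal shape.
    """
    if isinstance(S, Tensor) or isinstance(W, Tensor):
        S = Tensor._lift(S)
        W = Tensor._lift(W)
        if S.shape != W.shape:
            raise ValueError(f"shape mismatch: {S.shape} vs {W.shape}")
        return (W * S.sigmoid()).tanh()
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if S.shape != W.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {W.shape}")
    return np.tanh(W * expit(S))


def modality_confidence(S_hat, weights) -> float:
    """MCC = sigmoid(S_hat . weights), strictly inside (0, 1)."""
    S_hat = np.asarray(S_hat, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if S_hat.shape != weights.shape:
        raise ValueError(f"shape mismatch: {S_hat.shape} vs {weights.shape}")
    return float(expit(S_hat @ weights))


class DynamicWeightNet:
    """MLP mapping a sample's feature vector to its dynamic weight vector W.

    One hidden layer of width min(256, k), ReLU, linear output of width k.
    Parameters must be initialized (via an rng) before the net is called.
    """

    def __init__(self, n_features: int, hidden: int | None = None,
                 rng: np.random.Generator | None = None,
                 zero_init_output: bool = False):
        self.n_features = n_features
        self.hidden = min(256, n_features) if hidden is None else hidden
        self._zero_out = zero_init_output
        self.fc1 = None
        self.fc2 = None
        if rng is not None:
            self.initialize(rng)

    def initialize(self, rng: np.random.Generator) -> "DynamicWeightNet":
        self.fc1 = Linear(self.n_features, self.hidden, rng)
        self.fc2 = Linear(self.hidden, self.n_features, rng,
                          zero_init=self._zero_out)
        return self

    def __call__(self, S: Tensor) -> Tensor:
        if self.fc1 is None:
            raise RuntimeError("DynamicWeightNet called before initialization")
        x = S if isinstance(S, Tensor) else Tensor(S)
        return self.fc2(self.fc1(x).relu())

    def parameters(self) -> list:
        if self.fc1 is None:
            return []
        return self.fc1.parameters() + self.fc2.parameters()
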