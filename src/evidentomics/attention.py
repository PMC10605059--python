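"""Methylation-guided cross-attention.

Methylation tokens act as queries over mRNA/miRNA key/value tokens, encoding
the regulatory direction methylation -> expression.  Scores are the bilinear
form d_i^T W_a m_j scaled by sqrt(h) (h = shared embedding width) and
normalized by a softmax over keys; the context c_i = sum_j a_ij m_j.

The final per-modality representation averages the inner-omics encoding of
the gated features with the pooled inter-omics context (expression
modalities); methylation uses its inner-omics encoding alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _np_softmax

from ._autodiff import Tensor, softmax as _t_softmax


@dataclass
class AttentionMap:
    """Row-stochastic query x key attention weights."""

    query_modality: str
    key_modality: str
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        rows = self.weights.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("attention entries must lie in [0, 1]")


def attention_scores(d: np.ndarray, m: np.ndarray, W_a: np.ndarray,
                     scale_dim: int) -> float:
    """score(d, m) = d^T W_a m / sqrt(scale_dim)."""
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    W_a = np.asarray(W_a, dtype=float)
    if d.shape[-1] != W_a.shape[0] or W_a.shape[1] != m.shape[-1]:
        raise ValueError("dimension mismatch between vectors and W_a")
    return float(d @ W_a @ m) / np.sqrt(scale_dim)


def guided_attention(queries: np.ndarray, keys_values: np.ndarray,
                     W_a: np.ndarray, scale_dim: int | None = None) -> tuple:
    """Cross-attention contexts and the attention map (numpy route).

    queries: (k_q, h); keys_values: (k_k, h); W_a: (h, h).
    Returns (contexts (k_q, h), weights (k_q, k_k)); rows sum to 1.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    keys_values = np.atleast_2d(np.asarray(keys_values, dtype=float))
    if keys_values.shape[0] == 0:
        raise ValueError("empty key sequence")
    h = queries.shape[1]
    if scale_dim is None:
        scale_dim = h
    scores = queries @ W_a @ keys_values.T / np.sqrt(scale_dim)
    weights = _np_softmax(scores, axis=-1)
    contexts = weights @ keys_values
    return contexts, weights


def guided_attention_batch(D: Tensor, M: Tensor, W_a: Tensor) -> tuple:
    """Batched autodiff route: D (B, k_q, h), M (B, k_k, h), W_a (h, h).

    Returns (contexts (B, k_q, h), attention Tensor (B, k_q, k_k)).
    """
    h = D.shape[-1]
    scores = (D @ W_a) @ M.swapaxes(-1, -2) * (1.0 / np.sqrt(h))
    attn = _t_softmax(scores, axis=-1)
    contexts = attn @ M
    return contexts, attn


def modality_representation(enc_Sd, context_tokens=None, value_tokens=None,
                            mode: str = "expression"):
    """Combine inner- and inter-omics representations into S_hat.

    expression mode: S_a = 1/2 (mean context token + mean value token);
    S_hat = 1/2 (enc_Sd + S_a).  methylation mode: S_hat = enc_Sd.
    Works on numpy arrays and autodiff Tensors (token axis = -2).
    """
    if mode == "methylation":
        return enc_Sd
    if mode != "expression":
        raise ValueError(f"unknown mode {mode!r}")
    if context_tokens is None or value_tokens is None:
        raise ValueError("expression mode requires context and value tokens")
    pooled_ctx = context_tokens.mean(axis=-2)
    pooled_val = value_tokens.mean(axis=-2)
    S_a = (pooled_ctx + pooled_val) * 0.5
    return (enc_Sd + S_a) * 0.5
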