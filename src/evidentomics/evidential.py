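"""Dirichlet evidential opinions, Dempster-Shafer fusion and the loss terms.

An opinion over K classes holds nonnegative evidence e, belief masses
b_k = e_k / S and uncertainty u = K / S with Dirichlet strength
S = sum_k (e_k + 1), so that u + sum_k b_k = 1 identically.  Two opinions
combine by the reduced Dempster rule

    b_k = (b1_k b2_k + b1_k u2 + b2_k u1) / (1 - C),   u = u1 u2 / (1 - C),
    C = sum_{i != j} b1_i b2_j,

which is commutative and associative with the vacuous opinion (u = 1) as
identity.  Total conflict (C -> 1) raises rather than clamps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from ._autodiff import Tensor

_CONFLICT_TOL = 1e-12


@dataclass
class Opinion:
    """Subjective-logic triple (beliefs, uncertainty, evidence) for K classes."""

    beliefs: np.ndarray
    uncertainty: float
    evidence: np.ndarray

    def __post_init__(self):
        self.beliefs = np.asarray(self.beliefs, dtype=float)
        self.evidence = np.asarray(self.evidence, dtype=float)
        self.uncertainty = float(self.uncertainty)
        if np.any(self.beliefs < 0) or np.any(self.evidence < 0):
            raise ValueError("beliefs and evidence must be nonnegative")
        if not (0 < self.uncertainty <= 1):
            raise ValueError("uncertainty must lie in (0, 1]")
        if abs(self.uncertainty + self.beliefs.sum() - 1.0) > 1e-9:
            raise ValueError("u + sum(b) must equal 1")

    @property
    def n_classes(self) -> int:
        return len(self.beliefs)

    @property
    def dirichlet_strength(self) -> float:
        return self.n_classes / self.uncertainty

    @property
    def alpha(self) -> np.ndarray:
        return self.evidence + 1.0

    def probabilities(self) -> np.ndarray:
        """Beliefs renormalized to a probability vector (b / (1 - u));
        a vacuous opinion maps to the uniform distribution."""
        total = self.beliefs.sum()
        if total <= 1e-12:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return self.beliefs / total


def vacuous_opinion(K: int) -> Opinion:
    return Opinion(np.zeros(K), 1.0, np.zeros(K))


def compute_opinion(e: np.ndarray, K: int | None = None) -> Opinion:
    """Opinion from nonnegative evidence: b = e/S, u = K/S, S = sum(e + 1)."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("evidence must be nonnegative")
    if K is None:
        K = len(e)
    if len(e) != K or K < 2:
        raise ValueError("evidence length must equal K >= 2")
    S = float((e + 1.0).sum())
    b = e / S
    u = K / S
    # enforce the identity exactly against rounding
    return Opinion(b, 1.0 - b.sum(), e)


def ds_fuse_masses(b1, u1, b2, u2, axis: int = -1, keepdims: bool = True):
    """Reduced Dempster combination on raw mass arrays (numpy or Tensor).

    b*: (..., K) beliefs; u*: broadcastable uncertainties.  Returns (b, u, C).
    """
    s1 = b1.sum(axis=axis, keepdims=keepdims)
    s2 = b2.sum(axis=axis, keepdims=keepdims)
    agree = (b1 * b2).sum(axis=axis, keepdims=keepdims)
    C = s1 * s2 - agree
    denom = 1.0 - C
    b = (b1 * b2 + b1 * u2 + b2 * u1) / denom
    u = u1 * u2 / denom
    return b, u, C


def ds_fuse(op1: Opinion, op2: Opinion) -> Opinion:
    """Fuse two opinions over the same K classes."""
    if op1.n_classes != op2.n_classes:
        raise ValueError("opinions must share the same number of classes")
    C = float(op1.beliefs.sum() * op2.beliefs.sum()
              - (op1.beliefs * op2.beliefs).sum())
    if C >= 1.0 - _CONFLICT_TOL:
        raise ValueError(f"total conflict between opinions (C = {C})")
    b, u, _ = ds_fuse_masses(op1.beliefs, op1.uncertainty,
                             op2.beliefs, op2.uncertainty, keepdims=False)
    u = float(u)
    K = op1.n_classes
    e = b * (K / u)                      # S = K / u recovers the evidence scale
    return Opinion(b, 1.0 - b.sum(), e)


def ds_fuse_all(opinions: Sequence[Opinion]) -> Opinion:
    """Left fold of ds_fuse; order-independent up to float rounding."""
    if not opinions:
        raise ValueError("need at least one opinion")
    fused = opinions[0]
    for i, op in enumerate(opinions[1:], start=1):
        try:
            fused = ds_fuse(fused, op)
        except ValueError as err:
            raise ValueError(f"fusion failed at opinion {i}: {err}") from err
    return fused


def dirichlet_pdf(mu: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet density Dir(mu | alpha) = prod mu_i^(alpha_i - 1) / B(alpha).

    Zero off the simplex; alpha entries must be >= 1 (this package's
    evidential parameterization guarantees it).
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 1.0):
        raise ValueError("alpha entries must be >= 1")
    if np.any(mu < -1e-9) or abs(mu.sum() - 1.0) > 1e-9:
        return 0.0
    mu = np.clip(mu, 0.0, 1.0)
    log_b = special.gammaln(alpha).sum() - special.gammaln(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        log_num = np.where(alpha == 1.0, 0.0, (alpha - 1.0) * np.log(mu))
    if np.any(np.isneginf(log_num)):
        return 0.0
    return float(np.exp(log_num.sum() - log_b))


# -- losses ------------------------------------------------------------------

def _digamma(x):
    return x.digamma() if isinstance(x, Tensor) else special.digamma(x)


def _gammaln(x):
    return x.gammaln() if isinstance(x, Tensor) else special.gammaln(x)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def loss_single(beliefs_per_modality, y_onehot, clip: float = 1e-12):
    """Sum over modalities of cross-entropy on belief masses.

    beliefs_per_modality: sequence of (..., K) arrays/Tensors; y_onehot (..., K).
    """
    total = None
    for b in beliefs_per_modality:
        if isinstance(b, Tensor):
            safe = b + clip
        else:
            safe = np.maximum(np.asarray(b, dtype=float), clip)
        term = -(y_onehot * _log(safe)).sum(axis=-1)
        total = term if total is None else total + term
    return total


def dirichlet_kl_uniform(alpha_tilde):
    """KL[ Dir(alpha_tilde) || Dir(1) ] in closed form (numpy or Tensor)."""
    a0 = alpha_tilde.sum(axis=-1, keepdims=True)
    K = alpha_tilde.shape[-1]
    log_norm = (_gammaln(a0.sum(axis=-1)) - special.gammaln(float(K))
                - _gammaln(alpha_tilde).sum(axis=-1))
    centered = _digamma(alpha_tilde) - _digamma(a0)
    return log_norm + ((alpha_tilde - 1.0) * centered).sum(axis=-1)


def loss_integrate(alpha, y_onehot, kl_weight: float = 1.0):
    """Evidential loss on the fused Dirichlet parameters.

    Expected cross-entropy sum_i y_i (psi(sum_j alpha_j) - psi(alpha_i))
    plus kl_weight * KL[Dir(alpha_tilde) || Dir(1)] with the true-class
    parameter replaced by 1 (alpha_tilde = y + (1 - y) * alpha).
    """
    a0 = alpha.sum(axis=-1, keepdims=True)
    ce = (y_onehot * (_digamma(a0) - _digamma(alpha))).sum(axis=-1)
    alpha_tilde = y_onehot + (1.0 - y_onehot) * alpha
    return ce + kl_weight * dirichlet_kl_uniform(alpha_tilde)


def loss_overall(tcl, single, integrate, mean_uncertainty, params_l1,
                 l1_weight: float = 1e-4):
    """L = L_TCL + L_single + L_integrate + u + l1_weight * ||w||_1."""
    parts = {"tcl": tcl, "single": single, "integrate": integrate,
             "uncertainty": mean_uncertainty, "l1": params_l1}
    for name, p in parts.items():
        val = p.data if isinstance(p, Tensor) else np.asarray(p)
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return tcl + single + integrate + mean_uncertainty + l1_weight * params_l1
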