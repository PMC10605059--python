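"""Triple contrastive loss (TCL) and the cross-modality alignment score.

Each sample contributes three L2-normalized modality representations
(x1, x2, x3).  Positives are the three cyclic within-sample pairs
(x1.x2, x2.x3, x3.x1); negatives are all cross-sample modality pairs in the
batch, so a batch of B samples yields K = 3(B-1) negative samples and
3K = 9(B-1) negative similarity terms per anchor.  Every similarity enters
through exp(. / tau) and the loss is

    L = -mean_i log( pos_i / (pos_i + neg_i) )  >= 0.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, l2_normalize


def _cyclic_mask(n_mod: int = 3) -> np.ndarray:
    m = np.zeros((n_mod, n_mod))
    for a in range(n_mod):
        m[a, (a + 1) % n_mod] = 1.0
    return m


def tcl_loss(X, tau: float = 0.5, normalize: bool = True):
    """Triple contrastive loss over a batch.

    X: (B, 3, h) array or Tensor of per-sample modality representations.
    Returns a scalar (Tensor in, Tensor out).
    """
    if tau <= 0:
        raise ValueError("temperature tau must be > 0")
    is_tensor = isinstance(X, Tensor)
    shape = X.shape
    if len(shape) != 3 or shape[1] != 3 or shape[0] < 1:
        raise ValueError("X must have shape (B, 3, h) with B >= 1")
    B, _, h = shape

    if not is_tensor:
        X = Tensor(np.asarray(X, dtype=float))
    if normalize:
        X = l2_normalize(X, axis=-1)

    flat = X.reshape(3 * B, h)
    sims = (flat @ flat.swapaxes(-1, -2)) * (1.0 / tau)
    E = (sims - sims.data.max()).exp()          # global shift cancels in the ratio
    E4 = E.reshape(B, 3, B, 3)

    same = np.eye(B)[:, None, :, None]          # within-sample block indicator
    cyc = _cyclic_mask()[None, :, None, :]
    pos = (E4 * (same * cyc)).sum(axis=3).sum(axis=2).sum(axis=1)       # (B,)
    row_tot = E4.sum(axis=3).sum(axis=2).sum(axis=1)
    within = (E4 * same).sum(axis=3).sum(axis=2).sum(axis=1)
    neg = row_tot - within                                              # (B,)

    loss = -(pos / (pos + neg)).log().mean()
    return loss if is_tensor else float(loss.data)


def alignment_score(X) -> np.ndarray:
    """Per-sample mean pairwise cosine similarity among the 3 modality vectors.

    X: (n, 3, h); returns (n,) values in [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != 3:
        raise ValueError("alignment_score expects 3 representations per sample")
    norms = np.linalg.norm(X, axis=-1)
    if np.any(norms == 0):
        raise ValueError("zero representation vector")
    U = X / norms[..., None]
    pairs = [(0, 1), (1, 2), (0, 2)]
    cos = np.stack([(U[:, a] * U[:, b]).sum(axis=-1) for a, b in pairs], axis=1)
    return cos.mean(axis=1)
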