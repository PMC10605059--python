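"""The end-to-end evidential multiomics classifier.

:class:`EvidentialMultiomicsClassifier` is a scikit-learn-style estimator.
X is the horizontally stacked (samples x sum(k_i)) matrix; `modality_dims`
says how to cut it back into modalities (methylation first when present).
fit() standardizes per feature with training statistics, then minimizes

    L = L_TCL + L_single + L_integrate + mean(u) + 1e-4 ||w||_1

by Adam.  predict() returns the argmax of the fused belief masses;
predict_proba() the fused Dirichlet mean.  Ablation flags switch each
architectural component off independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)
from sklearn.preprocessing import label_binarize
from sklearn.utils.validation import check_X_y, check_array

from ._autodiff import Adam, Linear, Tensor, stack
from .attention import guided_attention_batch, modality_representation
from .contrastive import tcl_loss
from .data_io import MultiomicsDataset, SplitPlan, make_split_plan
from .evidential import (ds_fuse_masses, loss_integrate, loss_overall,
                         loss_single)
from .gating import DynamicWeightNet, feature_dynamic


@dataclass
class FoldMetrics:
    """Metric battery for one validation fold."""

    accuracy: float
    f1_macro: float
    f1_weighted: float
    auroc: Optional[float]
    auprc: Optional[float]
    mean_uncertainty: float      # mean fused u x 100
    fold: int = 0

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1_macro": self.f1_macro,
                "f1_weighted": self.f1_weighted, "auroc": self.auroc,
                "auprc": self.auprc, "mean_uncertainty": self.mean_uncertainty,
                "fold": self.fold}


class _ModalityBlock:
    """Per-modality parameters: gating net, encoder, token embedding,
    evidence head, MCC vector, attention bilinear map."""

    def __init__(self, k: int, h: int, hidden: int, K: int,
                 rng: np.random.Generator, needs_tokens: bool,
                 needs_attention_map: bool):
        self.k = k
        self.gate = DynamicWeightNet(k, hidden=min(hidden, k), rng=rng)
        self.encoder = Linear(k, h, rng)
        self.head = Linear(h, K, rng)
        self.mcc_w = Tensor(rng.normal(0, 1.0 / np.sqrt(h), size=(h, 1)),
                            requires_grad=True)
        self.tok_emb = None
        self.tok_bias = None
        if needs_tokens:
            self.tok_emb = Tensor(rng.normal(0, 1.0 / np.sqrt(h), size=(k, h)),
                                  requires_grad=True)
            self.tok_bias = Tensor(np.zeros((k, h)), requires_grad=True)
        self.W_a = None
        if needs_attention_map:
            self.W_a = Tensor(rng.normal(0, 1.0 / np.sqrt(h), size=(h, h)),
                              requires_grad=True)

    def tokens(self, S_d: Tensor) -> Tensor:
        # one token per gated feature: value x learned vector + learned bias
        return S_d.expand_dims(-1) * self.tok_emb + self.tok_bias

    def parameters(self) -> list:
        params = (self.gate.parameters() + self.encoder.parameters()
                  + self.head.parameters() + [self.mcc_w])
        for p in (self.tok_emb, self.tok_bias, self.W_a):
            if p is not None:
                params.append(p)
        return params


class EvidentialMultiomicsClassifier(ClassifierMixin, BaseEstimator):
    """Evidential multiomics classifier with adaptive gating, methylation-
    guided attention, triple contrastive alignment and DS fusion.

    Parameters
    ----------
    modality_dims : tuple of int or None
        Widths of the stacked modality blocks in X (methylation first when
        present).  None treats X as a single modality.
    methylation_index : int
        Which block holds DNA methylation (the attention query modality).
    embed_dim, hidden_dim : int
        Shared representation width h and gating-MLP hidden width.
    temperature : float
        TCL temperature tau.
    kl_weight_max : float
        Final KL penalty weight; annealed linearly from 0 over the first
        half of training.
    use_* : bool
        Independent ablation switches for each architectural component.
    """

    def __init__(self, modality_dims=None, methylation_index=0,
                 modality_names=None, embed_dim=32, hidden_dim=256,
                 temperature=0.5, learning_rate=1e-3, n_epochs=30,
                 batch_size=64, use_tcl=True, use_attention=True,
                 use_feature_dynamic=True, use_mcc=True, use_ds_fusion=True,
                 kl_weight_max=1.0, l1_weight=1e-4, random_state=None):
        self.modality_dims = modality_dims
        self.methylation_index = methylation_index
        self.modality_names = modality_names
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.use_tcl = use_tcl
        self.use_attention = use_attention
        self.use_feature_dynamic = use_feature_dynamic
        self.use_mcc = use_mcc
        self.use_ds_fusion = use_ds_fusion
        self.kl_weight_max = kl_weight_max
        self.l1_weight = l1_weight
        self.random_state = random_state

    # -- construction -------------------------------------------------------
    def _resolve_dims(self, n_features: int) -> tuple:
        dims = self.modality_dims
        if dims is None:
            return (n_features,)
        dims = tuple(int(d) for d in dims)
        if sum(dims) != n_features:
            raise ValueError(f"modality_dims {dims} do not sum to {n_features}")
        return dims

    def _build(self, dims: tuple, K: int, rng: np.random.Generator) -> None:
        m = len(dims)
        if self.use_attention and m >= 2 and not (0 <= self.methylation_index < m):
            raise ValueError("use_attention requires a valid methylation_index")
        h, hidden = self.embed_dim, self.hidden_dim
        self.blocks_ = []
        for i, k in enumerate(dims):
            is_meth = (i == self.methylation_index)
            needs_attn = self.use_attention and m >= 2
            self.blocks_.append(_ModalityBlock(
                k, h, hidden, K, rng,
                needs_tokens=needs_attn,
                needs_attention_map=needs_attn and not is_meth))

    def _parameters(self) -> list:
        return [p for blk in self.blocks_ for p in blk.parameters()]

    # -- forward ------------------------------------------------------------
    def _forward(self, X_std: np.ndarray, collect: bool = False) -> dict:
        """Run the network on standardized, stacked inputs.

        Returns per-modality beliefs/uncertainty Tensors, fused masses, the
        modality representations, and (optionally) gate weights / attention.
        """
        dims = self.modality_dims_
        m = len(dims)
        K = len(self.classes_)
        splits = np.cumsum(dims)[:-1]
        S_all = [Tensor(x) for x in np.split(X_std, splits, axis=1)]

        gates, S_ds = [], []
        for i, (blk, S) in enumerate(zip(self.blocks_, S_all)):
            if self.use_feature_dynamic:
                W = blk.gate(S)
            else:
                W = Tensor(np.ones_like(S.data))
            gates.append(W)
            S_ds.append(feature_dynamic(S, W))

        attn_maps = [None] * m
        reps = []
        use_attn = self.use_attention and m >= 2
        if use_attn:
            D = self.blocks_[self.methylation_index].tokens(
                S_ds[self.methylation_index])
        for i, (blk, S_d) in enumerate(zip(self.blocks_, S_ds)):
            enc = blk.encoder(S_d)
            if use_attn and i != self.methylation_index:
                M = blk.tokens(S_d)
                ctx, attn = guided_attention_batch(D, M, blk.W_a)
                attn_maps[i] = attn
                reps.append(modality_representation(enc, ctx, M, "expression"))
            else:
                reps.append(modality_representation(enc, mode="methylation"))

        mccs, beliefs, uncerts, evidences = [], [], [], []
        for blk, S_hat in zip(self.blocks_, reps):
            raw = blk.head(S_hat).softplus()
            if self.use_mcc:
                mcc = (S_hat @ blk.mcc_w).sigmoid()        # (B, 1)
                e = mcc * raw
            else:
                mcc = Tensor(np.ones((S_hat.shape[0], 1)))
                e = raw
            S_dir = (e + 1.0).sum(axis=-1, keepdims=True)
            beliefs.append(e / S_dir)
            uncerts.append(K / S_dir)
            evidences.append(e)
            mccs.append(mcc)

        if self.use_ds_fusion or m == 1:
            b, u = beliefs[0], uncerts[0]
            for i in range(1, m):
                b, u, _ = ds_fuse_masses(b, u, beliefs[i], uncerts[i])
        else:
            # ablation: pool evidence additively into one opinion
            e_tot = evidences[0]
            for i in range(1, m):
                e_tot = e_tot + evidences[i]
            S_dir = (e_tot + 1.0).sum(axis=-1, keepdims=True)
            b, u = e_tot / S_dir, K / S_dir

        out = {"beliefs": beliefs, "uncerts": uncerts, "reps": reps,
               "mccs": mccs, "fused_b": b, "fused_u": u}
        if collect:
            out["gates"] = gates
            out["gated"] = S_ds
            out["attn"] = attn_maps
        return out

    # -- fit ----------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        self.modality_dims_ = self._resolve_dims(X.shape[1])

        rng = np.random.default_rng(self.random_state)
        self._build(self.modality_dims_, K, rng)
        params = self._parameters()
        opt = Adam(params, lr=self.learning_rate)

        self.feature_means_ = X.mean(axis=0)
        stds = X.std(axis=0, ddof=0)
        stds[stds == 0] = 1.0
        self.feature_stds_ = stds
        X_std = (X - self.feature_means_) / self.feature_stds_

        n = X.shape[0]
        Y = np.eye(K)[y_idx]
        m = len(self.modality_dims_)
        half = max(1, self.n_epochs // 2)
        history = []
        for epoch in range(self.n_epochs):
            kl_w = self.kl_weight_max * min(1.0, epoch / half)
            order = rng.permutation(n)
            ep = {"tcl": 0.0, "single": 0.0, "integrate": 0.0,
                  "uncertainty": 0.0, "l1": 0.0, "total": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                out = self._forward(X_std[idx])
                y_b = Y[idx]

                if self.use_tcl and m == 3:
                    reps3 = stack(out["reps"], axis=1)
                    l_tcl = tcl_loss(reps3, tau=self.temperature)
                else:
                    l_tcl = Tensor(0.0)
                l_single = loss_single(out["beliefs"], y_b).mean()
                e_fused = out["fused_b"] * (K / out["fused_u"])
                alpha = e_fused + 1.0
                l_int = loss_integrate(alpha, y_b, kl_weight=kl_w).mean()
                mean_u = out["fused_u"].mean()
                l1 = None
                for p in params:
                    term = p.abs().sum()
                    l1 = term if l1 is None else l1 + term
                loss = loss_overall(l_tcl, l_single, l_int, mean_u, l1,
                                    l1_weight=self.l1_weight)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                for key, t in (("tcl", l_tcl), ("single", l_single),
                               ("integrate", l_int), ("uncertainty", mean_u),
                               ("l1", l1), ("total", loss)):
                    ep[key] += float(t.data)
                n_batches += 1
            history.append({k: v / n_batches for k, v in ep.items()}
                           | {"epoch": epoch, "kl_weight": kl_w})
        self.history_ = history
        return self

    # -- inference ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "blocks_"):
            raise NotFittedError("estimator is not fitted; call fit first")

    def _standardize(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.feature_means_) / self.feature_stds_

    def predict_opinion(self, X) -> tuple:
        """Fused (beliefs (n, K), uncertainty (n,)) for each sample."""
        self._check_fitted()
        out = self._forward(self._standardize(X))
        return out["fused_b"].data, out["fused_u"].data[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        b, u = self.predict_opinion(X)
        # beliefs renormalized by their own mass 1 - u; vacuous -> uniform
        total = 1.0 - u[:, None]
        K = len(self.classes_)
        with np.errstate(invalid="ignore", divide="ignore"):
            proba = np.where(total > 1e-12, b / total, 1.0 / K)
        return proba

    def predict(self, X) -> np.ndarray:
        b, _ = self.predict_opinion(X)
        return self.classes_[b.argmax(axis=1)]

    def modality_opinions(self, X) -> list:
        """Per-modality (beliefs, uncertainty) before fusion."""
        self._check_fitted()
        out = self._forward(self._standardize(X))
        return [(b.data, u.data[:, 0])
                for b, u in zip(out["beliefs"], out["uncerts"])]

    def modality_confidences(self, X) -> np.ndarray:
        """MCC scores, shape (n, m)."""
        self._check_fitted()
        out = self._forward(self._standardize(X))
        return np.column_stack([m.data[:, 0] for m in out["mccs"]])

    def dynamic_weights(self, X) -> list:
        """Per-modality dynamic weight matrices W, each (n, k_i)."""
        self._check_fitted()
        out = self._forward(self._standardize(X), collect=True)
        return [w.data for w in out["gates"]]

    def gated_values(self, X) -> list:
        """Per-modality gated feature values S_d = tanh(W * sigmoid(S)),
        each (n, k_i) -- the effective per-sample feature weighting."""
        self._check_fitted()
        out = self._forward(self._standardize(X), collect=True)
        return [s.data for s in out["gated"]]

    def representations(self, X) -> np.ndarray:
        """Per-modality shared-space representations, shape (n, m, h)."""
        self._check_fitted()
        out = self._forward(self._standardize(X))
        return np.stack([r.data for r in out["reps"]], axis=1)

    def attention_maps(self, X) -> list:
        """Per-modality attention maps (None for the query modality)."""
        self._check_fitted()
        out = self._forward(self._standardize(X), collect=True)
        return [a.data if a is not None else None for a in out["attn"]]


# ---------------------------------------------------------------------------

def evaluate(model: EvidentialMultiomicsClassifier, X: np.ndarray,
             y: np.ndarray, fold: int = 0) -> FoldMetrics:
    """Compute the metric battery on an evaluation set.

    AUROC/AUPRC are macro one-vs-rest on the fused Dirichlet-mean
    probabilities; with a single-class evaluation set they are reported as
    missing (None), not zero.
    """
    y = np.asarray(y)
    pred = model.predict(X)
    proba = model.predict_proba(X)
    _, u = model.predict_opinion(X)
    acc = accuracy_score(y, pred)
    f1m = f1_score(y, pred, average="macro", zero_division=0)
    f1w = f1_score(y, pred, average="weighted", zero_division=0)
    auroc = auprc = None
    if len(np.unique(y)) >= 2:
        classes = model.classes_
        if len(classes) == 2:
            pos = proba[:, 1]
            auroc = roc_auc_score(y, pos)
            auprc = average_precision_score(y, pos, pos_label=classes[1])
        else:
            Yb = label_binarize(y, classes=classes)
            mask = Yb.sum(axis=0) > 0
            auroc = roc_auc_score(Yb[:, mask], proba[:, mask], average="macro")
            auprc = average_precision_score(Yb[:, mask], proba[:, mask],
                                            average="macro")
    return FoldMetrics(accuracy=float(acc), f1_macro=float(f1m),
                       f1_weighted=float(f1w),
                       auroc=None if auroc is None else float(auroc),
                       auprc=None if auprc is None else float(auprc),
                       mean_uncertainty=float(u.mean() * 100), fold=fold)


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold metrics, aggregates, fold models."""

    fold_metrics: list
    split: SplitPlan
    models: list = field(default_factory=list)

    def aggregate(self) -> dict:
        keys = ("accuracy", "f1_macro", "f1_weighted", "auroc", "auprc",
                "mean_uncertainty")
        out = {}
        for key in keys:
            vals = [getattr(f, key) for f in self.fold_metrics
                    if getattr(f, key) is not None]
            out[key] = {"mean": float(np.mean(vals)) if vals else None,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        return out


def cross_validate(dataset: MultiomicsDataset, n_folds: int = 5,
                   seed: int = 0, keep_models: bool = True,
                   **estimator_params) -> CVResult:
    """Stratified k-fold CV: one model trained from scratch per fold."""
    split = make_split_plan(dataset, n_folds=n_folds, seed=seed)
    X, dims = dataset.stacked_X()
    y = dataset.y
    index = {s: i for i, s in enumerate(dataset.sample_ids)}
    params = {"modality_dims": dims,
              "modality_names": dataset.modality_names,
              "random_state": seed}
    params.update(estimator_params)
    metrics, models = [], []
    for fold in range(n_folds):
        train_ids, test_ids = split.train_test_ids(fold)
        tr = [index[s] for s in train_ids]
        te = [index[s] for s in test_ids]
        model = EvidentialMultiomicsClassifier(**params)
        model.fit(X[tr], y[tr])
        metrics.append(evaluate(model, X[te], y[te], fold=fold))
        if keep_models:
            models.append(model)
    return CVResult(fold_metrics=metrics, split=split, models=models)
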