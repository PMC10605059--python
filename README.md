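# evident-omics

Trustworthy multiomics classification for cancer subtype analysis.
`evident-omics` integrates DNA methylation, mRNA and miRNA matrices
measured on the same samples into a single classifier that knows when it
does not know: every prediction comes with a subjective-logic uncertainty
derived from Dirichlet evidence, and the per-modality opinions are combined
with a Dempster–Shafer fusion rule that accounts for conflict between
omics layers.

## Who this is for

Computational biologists and method developers who need (i) a multiomics
classifier whose confidence degrades honestly under distribution shift,
(ii) per-sample, per-feature importance weights usable for biomarker
screening, and (iii) survival stratification of the predicted groups — and
who want all of it testable offline on synthetic data with planted ground
truth.

## The model in brief

For each modality m with feature vector S (z-scored):

- **sample-adaptive gating** — a learned MLP produces per-sample dynamic
  weights W and the gated embedding `S_d = tanh(W · σ(S))`;
- **methylation-guided attention** — methylation tokens query each
  expression modality's tokens with scaled bilinear scores
  `d_i' W_a m_j / √h`, encoding the regulatory direction
  methylation → expression; the representation averages inner-omics and
  inter-omics parts;
- **triple contrastive loss** — the three modality representations of a
  sample are pulled together against all in-batch cross-sample pairs
  (`exp(·/τ)` similarities, K = 3(B−1) negatives);
- **modality confidence** — `MCC = σ(Ŝ·w)` rescales each modality's
  evidence;
- **evidential head + fusion** — `e = MCC·softplus(linear(Ŝ))`,
  `b_k = e_k/S`, `u = K/S`, `S = Σ(e_k+1)`, fused across modalities by
  `b_k = (b¹_k b²_k + b¹_k u² + b²_k u¹)/(1−C)`, `u = u¹u²/(1−C)` with
  conflict `C = Σ_{i≠j} b¹_i b²_j`.

Training minimizes
`L = L_TCL + L_single + L_integrate + mean(u) + 1e-4·‖θ‖₁`, where
`L_integrate` is the evidential Dirichlet loss (digamma cross-entropy plus
an annealed KL toward the uniform Dirichlet off the true class).
See `docs/methods.md` for the full account.

The network runs on a small numpy reverse-mode autodiff core shipped with
the package — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from evidentomics import (SyntheticConfig, generate,
                          EvidentialMultiomicsClassifier, evaluate)

cfg = SyntheticConfig(n_samples=300, n_classes=3,
                      features_per_modality=(100, 100, 50),
                      effect_size=2.0, seed=7)
dataset, truth = generate(cfg)          # 3 aligned modalities + labels
X, dims = dataset.stacked_X()           # samples x (100+100+50)
y = dataset.y

clf = EvidentialMultiomicsClassifier(modality_dims=dims, random_state=0)
clf.fit(X[:240], y[:240])

beliefs, u = clf.predict_opinion(X[240:])
metrics = evaluate(clf, X[240:], y[240:])
print(f"accuracy          {metrics.accuracy:.3f}")
print(f"macro F1          {metrics.f1_macro:.3f}")
print(f"mean uncertainty  {metrics.mean_uncertainty:.1f}")
print(f"max |u + sum(b) - 1| = {np.abs(beliefs.sum(1) + u - 1).max():.2e}")
```

prints

```
accuracy          1.000
macro F1          1.000
mean uncertainty  1.5
max |u + sum(b) - 1| = 4.44e-16
```

The held-out fold is classified perfectly at this effect size; the mean
fused uncertainty (reported ×100) stays low on in-distribution data, and
the subjective-logic identity `u + Σb = 1` holds to machine precision.
Adding test-time Gaussian noise raises the uncertainty and lowers the
accuracy monotonically — the behaviour `noise_experiment` quantifies.

A command-line layer wraps the same pipeline:

```bash
evident-omics simulate --seed 7 --out data/
evident-omics train --data data/ --out run/
evident-omics noise --run run/ --data data/ --out noise.tsv
evident-omics biomarkers --run run/ --data data/ --top 5 --out markers.tsv
evident-omics survival --run run/ --data data/ --out km.tsv
```

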