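"""Synthetic multiomics generator with the structure the model assumes.

Emulates: K-class Gaussian class signal in a subset of informative features,
a planted (negative, by default) linear coupling from methylation driver
features to mRNA/miRNA target features, pure-noise uninformative features,
and optional exponential survival times with class-dependent hazards.
Everything is fully determined by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np

from .data_io import FeatureMatrix, MultiomicsDataset


@dataclass
class SurvivalConfig:
    base_hazard: float = 0.1
    class_hazard_ratios: tuple = ()   # one ratio per class; empty -> all 1
    censoring_rate: float = 0.2


@dataclass
class SyntheticConfig:
    n_samples: int = 600
    n_classes: int = 3
    features_per_modality: tuple = (200, 200, 100)   # (meth, mrna, mirna)
    informative_fraction: float = 0.2
    effect_size: float = 2.0          # class-mean separation in SD units
    regulation_strength: float = -0.8  # methylation driver -> expression target
    noise_sd: float = 1.0
    survival: Optional[SurvivalConfig] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < self.n_classes or self.n_classes < 2:
            raise ValueError("need n_samples >= n_classes >= 2")
        if not (0 < self.informative_fraction <= 1):
            raise ValueError("informative_fraction must be in (0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        for k_i in self.features_per_modality:
            if ceil(self.informative_fraction * k_i) < 1:
                raise ValueError("informative_fraction leaves a modality with no signal")


@dataclass
class GroundTruth:
    """Which features carry signal, and the planted driver -> target couplings."""

    informative_masks: dict = field(default_factory=dict)  # modality -> bool array
    couplings: dict = field(default_factory=dict)          # modality -> {target: driver}


_MODALITY_ORDER = ("methylation", "mrna", "mirna")


def generate(config: SyntheticConfig) -> tuple:
    """Generate a (MultiomicsDataset, GroundTruth) pair.

    Informative methylation features are class-dependent Gaussians with means
    spread `effect_size` SD apart; a subset of informative expression features
    equals `regulation_strength` x (its methylation driver) + class effect +
    N(0, noise_sd^2); uninformative features are standard normal.
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_samples, config.n_classes
    k_meth, k_mrna, k_mirna = config.features_per_modality

    # balanced labels up to rounding, shuffled deterministically
    y = np.resize(np.repeat(np.arange(K), ceil(n / K)), n)
    rng.shuffle(y)

    n_inf = {m: ceil(config.informative_fraction * k)
             for m, k in zip(_MODALITY_ORDER, (k_meth, k_mrna, k_mirna))}

    def class_means(n_feat: int) -> np.ndarray:
        # per informative feature, a random direction of separation across classes
        centers = rng.standard_normal((K, n_feat))
        centers -= centers.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centers, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        return config.effect_size * centers / norms * np.sqrt(K)

    truth = GroundTruth()
    matrices = []
    sample_ids = [f"S{i:05d}" for i in range(n)]

    # --- methylation -------------------------------------------------------
    meth = rng.standard_normal((n, k_meth)) * config.noise_sd
    mask = np.zeros(k_meth, dtype=bool)
    mask[: n_inf["methylation"]] = True
    mu = class_means(n_inf["methylation"])
    meth[:, mask] += mu[y]
    truth.informative_masks["methylation"] = mask
    matrices.append(FeatureMatrix("methylation", sample_ids,
                                  [f"meth_{j:04d}" for j in range(k_meth)], meth))

    # --- expression modalities --------------------------------------------
    for modality, k_i in (("mrna", k_mrna), ("mirna", k_mirna)):
        X = rng.standard_normal((n, k_i)) * config.noise_sd
        m_mask = np.zeros(k_i, dtype=bool)
        m_mask[: n_inf[modality]] = True
        mu = class_means(n_inf[modality])
        X[:, m_mask] += mu[y]
        # half of the informative features are regulated targets
        n_reg = max(1, n_inf[modality] // 2)
        drivers = rng.integers(0, n_inf["methylation"], size=n_reg)
        coupling = {}
        for t, j_driver in enumerate(drivers):
            X[:, t] += config.regulation_strength * meth[:, int(j_driver)]
            coupling[int(t)] = int(j_driver)
        truth.informative_masks[modality] = m_mask
        truth.couplings[modality] = coupling
        matrices.append(FeatureMatrix(modality, sample_ids,
                                      [f"{modality}_{j:04d}" for j in range(k_i)], X))

    class_names = [f"class_{c}" for c in range(K)]
    labels = {s: int(c) for s, c in zip(sample_ids, y)}

    survival = None
    if config.survival is not None:
        sc = config.survival
        ratios = np.asarray(sc.class_hazard_ratios if sc.class_hazard_ratios
                            else np.ones(K), dtype=float)
        if len(ratios) != K:
            raise ValueError("need one hazard ratio per class")
        hazard = sc.base_hazard * ratios[y]
        times = rng.exponential(1.0 / hazard)
        censored = rng.random(n) < sc.censoring_rate
        # censoring truncates the observed time uniformly
        obs = np.where(censored, times * rng.random(n), times)
        obs = np.maximum(obs, 1e-8)
        survival = {s: (float(t), int(0 if c else 1))
                    for s, t, c in zip(sample_ids, obs, censored)}

    return MultiomicsDataset(matrices, labels, class_names, survival), truth


def add_gaussian_noise(dataset: MultiomicsDataset, sd: float, seed: int,
                       target_ids=None) -> MultiomicsDataset:
    """Return a copy with N(0, sd^2) perturbations added to every feature of the
    targeted samples (all samples when `target_ids` is None); sd=0 is the identity."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    ids = dataset.sample_ids if target_ids is None else list(target_ids)
    rows = [dataset.sample_ids.index(s) for s in ids]
    matrices = []
    for m in dataset.matrices:
        values = m.values.copy()
        if sd > 0 and rows:
            values[rows] += rng.normal(0.0, sd, size=(len(rows), m.n_features))
        matrices.append(FeatureMatrix(m.modality, list(m.sample_ids),
                                      list(m.feature_names), values))
    surv = dict(dataset.survival) if dataset.survival else None
    return MultiomicsDataset(matrices, dict(dataset.labels),
                             list(dataset.class_names), surv)
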