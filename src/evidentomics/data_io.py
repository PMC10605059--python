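"""Reading, aligning, preselecting and splitting multiomics matrices.

One modality is a samples × features table (TSV or CSV, header row, sample-ID
first column).  A :class:`MultiomicsDataset` carries m such matrices with an
identical, lexicographically sorted sample order, plus class labels and an
optional survival table.  Feature preselection and stratified fold plans wrap
scikit-learn.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

MODALITIES = ("methylation", "mrna", "mirna", "other")


@dataclass
class FeatureMatrix:
    """One modality's samples × features table.

    Values must be finite; duplicate sample or feature names are rejected.
    """

    modality: str
    sample_ids: list
    feature_names: list
    values: np.ndarray

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise ValueError("matrix must have at least one sample and one feature")
        if len(self.sample_ids) != n or len(self.feature_names) != k:
            raise ValueError("name lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids in {self.modality} matrix")
        if len(set(self.feature_names)) != k:
            raise ValueError(f"duplicate feature names in {self.modality} matrix")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value in {self.modality} matrix at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return FeatureMatrix(self.modality, list(ids), list(self.feature_names),
                             self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)


@dataclass
class MultiomicsDataset:
    """Aligned modalities + labels (+ optional survival)."""

    matrices: list
    labels: dict                       # sample_id -> class index 0..K-1
    class_names: list
    survival: Optional[dict] = None    # sample_id -> (time, event)

    def __post_init__(self):
        if not self.matrices:
            raise ValueError("at least one modality required")
        ref = self.matrices[0].sample_ids
        for m in self.matrices[1:]:
            if m.sample_ids != ref:
                raise ValueError("matrices do not share an identical sample order")
        missing = [s for s in ref if s not in self.labels]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        if len(self.class_names) < 2:
            raise ValueError("need at least two classes")

    @property
    def sample_ids(self) -> list:
        return self.matrices[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def modality_names(self) -> list:
        return [m.modality for m in self.matrices]

    @property
    def y(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids], dtype=int)

    def stacked_X(self) -> tuple:
        """Horizontally stacked values and per-modality widths (sklearn layout)."""
        X = np.hstack([m.values for m in self.matrices])
        dims = tuple(m.n_features for m in self.matrices)
        return X, dims

    def subset(self, ids: Sequence[str]) -> "MultiomicsDataset":
        ids = list(ids)
        surv = None
        if self.survival is not None:
            surv = {s: self.survival[s] for s in ids if s in self.survival}
        return MultiomicsDataset(
            [m.subset_samples(ids) for m in self.matrices],
            {s: self.labels[s] for s in ids},
            list(self.class_names),
            surv,
        )


@dataclass
class SplitPlan:
    """A stratified fold assignment, fully determined by its seed."""

    n_folds: int
    assignments: dict = field(default_factory=dict)  # sample_id -> fold
    seed: int = 0

    def fold_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_test_ids(self, fold: int) -> tuple:
        test = [s for s, f in self.assignments.items() if f == fold]
        train = [s for s, f in self.assignments.items() if f != fold]
        return train, test


# ---------------------------------------------------------------------------

def _read_table(path, dialect: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        with open(path) as fh:
            first = fh.readline()
        dialect = "tab" if first.count("\t") >= first.count(",") else "comma"
    sep = {"tab": "\t", "comma": ","}[dialect]
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def read_feature_matrix(path, modality: str, dialect: Optional[str] = None) -> FeatureMatrix:
    """Read one modality table; delimiter auto-detected unless `dialect` forces it."""
    df = _read_table(path, dialect)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        coerced = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(coerced))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-numeric or missing cell in {path} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        values = coerced
    return FeatureMatrix(modality, list(df.index.astype(str)),
                         list(df.columns.astype(str)), values)


def write_feature_matrix(matrix: FeatureMatrix, path, dialect: str = "tab") -> None:
    sep = {"tab": "\t", "comma": ","}[dialect]
    # %.17g round-trips any IEEE double exactly
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id",
                             float_format="%.17g")


def read_labels(path, dialect: Optional[str] = None) -> tuple:
    """Read a two-column (sample_id, class_label) table.

    Returns (labels: id -> class index, class_names sorted).
    """
    df = _read_table(path, dialect)
    raw = df.iloc[:, 0].astype(str)
    class_names = sorted(raw.unique())
    idx = {c: i for i, c in enumerate(class_names)}
    return {str(s): idx[v] for s, v in raw.items()}, class_names


def read_survival(path, dialect: Optional[str] = None) -> dict:
    """Read a three-column (sample_id, time, event) table."""
    df = _read_table(path, dialect)
    out = {}
    for s, row in df.iterrows():
        t, e = float(row.iloc[0]), int(row.iloc[1])
        if t <= 0 or e not in (0, 1):
            raise ValueError(f"invalid survival record for sample {s!r}: time={t}, event={e}")
        out[str(s)] = (t, e)
    return out


def align_dataset(matrices: Sequence[FeatureMatrix],
                  labels: Mapping[str, int],
                  class_names: Sequence[str],
                  survival: Optional[Mapping] = None) -> MultiomicsDataset:
    """Keep the intersection of sample IDs across all matrices and the labels,
    in canonical (lexicographically sorted) order."""
    if len(matrices) < 1 or not labels:
        raise ValueError("need at least one matrix and a nonempty label table")
    common = set(labels)
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across matrices and labels")
    order = sorted(common)
    for m in matrices:
        dropped = m.n_samples - len(order)
        if dropped:
            logger.info("align: dropped %d samples from %s", dropped, m.modality)
    surv = None
    if survival is not None:
        surv = {s: survival[s] for s in order if s in survival}
        n_drop = len(survival) - len(surv)
        if n_drop:
            logger.info("align: dropped %d survival records outside the intersection", n_drop)
    return MultiomicsDataset([m.subset_samples(order) for m in matrices],
                             {s: labels[s] for s in order}, list(class_names), surv)


def preselect_features(matrix: FeatureMatrix, labels: Mapping[str, int],
                       method: str = "variance", top_k: Optional[int] = None) -> FeatureMatrix:
    """Keep the top_k features by variance or ANOVA-F score.

    Ties break deterministically by feature-name order.  With top_k None or
    equal to k the matrix is returned with all features (score-ordered).
    """
    if method not in ("variance", "anova_f"):
        raise ValueError(f"unknown preselection method {method!r}")
    k = matrix.n_features
    if top_k is None:
        top_k = k
    if not (1 <= top_k <= k):
        raise ValueError(f"top_k={top_k} outside [1, {k}]")
    if method == "variance":
        scores = matrix.values.var(axis=0, ddof=1) if matrix.n_samples > 1 \
            else np.zeros(k)
    else:
        y = np.array([labels[s] for s in matrix.sample_ids])
        scores, _ = f_classif(matrix.values, y)
        scores = np.nan_to_num(scores, nan=0.0)
    # stable sort: descending score, ascending name
    order = sorted(range(k), key=lambda j: (-scores[j], matrix.feature_names[j]))
    keep = order[:top_k]
    return FeatureMatrix(matrix.modality, list(matrix.sample_ids),
                         [matrix.feature_names[j] for j in keep],
                         matrix.values[:, keep])


def make_split_plan(dataset: MultiomicsDataset, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Deterministic stratified k-fold assignment over the dataset's samples."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = dataset.y
    counts = np.bincount(y, minlength=dataset.n_classes)
    for c, n_c in enumerate(counts):
        if n_c < n_folds:
            raise ValueError(
                f"class {dataset.class_names[c]!r} has {n_c} samples, fewer than "
                f"{n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = {}
    ids = dataset.sample_ids
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignments[ids[i]] = fold
    return SplitPlan(n_folds=n_folds, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------

def write_dataset_bundle(dataset: MultiomicsDataset, out_dir) -> None:
    """Write the aligned dataset as a TSV bundle + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in dataset.matrices:
        write_feature_matrix(m, out / f"{m.modality}.tsv")
    lab = pd.DataFrame({"class_label": [dataset.class_names[dataset.labels[s]]
                                        for s in dataset.sample_ids]},
                       index=dataset.sample_ids)
    lab.to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
    if dataset.survival:
        sv = pd.DataFrame(
            {"time": [dataset.survival[s][0] for s in dataset.survival],
             "event": [dataset.survival[s][1] for s in dataset.survival]},
            index=list(dataset.survival))
        sv.to_csv(out / "survival.tsv", sep="\t", index_label="sample_id")
    manifest = {
        "modalities": dataset.modality_names,
        "n_samples": dataset.n_samples,
        "n_features": [m.n_features for m in dataset.matrices],
        "class_names": dataset.class_names,
        "has_survival": bool(dataset.survival),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset_bundle(in_dir) -> MultiomicsDataset:
    """Read back a bundle written by :func:`write_dataset_bundle`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    matrices = [read_feature_matrix(src / f"{mod}.tsv", mod)
                for mod in manifest["modalities"]]
    labels, class_names = read_labels(src / "labels.tsv")
    survival = read_survival(src / "survival.tsv") if (src / "survival.tsv").exists() else None
    return align_dataset(matrices, labels, class_names, survival)
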