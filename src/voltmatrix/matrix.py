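"""Cross-voltage classification matrices.

A binary classifier (random forest or RBF-kernel SVM) is trained on events
acquired at one voltage and evaluated — always on held-out splits — at every
voltage of the grid.  The resulting (train voltage x test voltage) grid of
AUC values separates molecule-specific signal (sustained off-diagonal
performance) from acquisition-condition fingerprints (diagonal-only
inflation).

AUC is computed as the Mann-Whitney rank statistic
``P(score_pos > score_neg) + 0.5 * P(tie)``, identical to the trapezoidal
ROC area.  Feature importance uses model-agnostic permutation importance
(mean AUC drop over column permutations) so random-forest and SVM profiles
are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "ALGORITHMS",
    "ClassifierHandle",
    "LabeledDataset",
    "VoltageMatrixResult",
    "ImportanceProfile",
    "auc",
    "train_classifier",
    "make_dataset",
    "build_matrix",
    "permutation_importance",
]

ALGORITHMS = ("random_forest", "svm")


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties half-credited.

    ``labels`` must be boolean-like (True/1 = positive class); raises if a
    class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ClassifierHandle:
    """Opaque trained model exposing a positive-class score in [0, 1]."""

    model: object
    algo: str
    positive_label: object
    feature_names: tuple[str, ...]
    seed: int

    def score(self, features: FeatureTable | pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, FeatureTable):
            X = features.values
        elif isinstance(features, pd.DataFrame):
            X = features[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
        proba = self.model.predict_proba(X)
        pos_idx = list(self.model.classes_).index(1)
        return proba[:, pos_idx]


def train_classifier(
    table: FeatureTable,
    labels: Sequence | None = None,
    algo: str = "random_forest",
    *,
    positive_label: object | None = None,
    seed: int = 0,
    min_per_class: int = 20,
    n_estimators: int = 500,
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
) -> ClassifierHandle:
    """Train a seeded binary classifier with probability scoring.

    The SVM pipeline standardizes features internally (z-scores learned on
    the training data); the random forest consumes raw features.
    ``min_per_class`` is a configurable floor on events per class.
    """
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}; options: {ALGORITHMS}")
    if labels is None:
        labels = table.labels
    if labels is None:
        raise ValueError("labels are required for training")
    y_raw = np.asarray(labels)
    classes = sorted(set(y_raw.tolist()), key=str)
    if len(classes) != 2:
        raise ValueError(f"binary classification needs exactly 2 classes, got {classes}")
    if positive_label is None:
        positive_label = classes[0]
    y = (y_raw == positive_label).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} events per class, got {counts.tolist()} "
            "(lower min_per_class to override)"
        )
    X = table.values
    if algo == "random_forest":
        model = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    else:
        svc = SVC(kernel="rbf", C=svm_c, gamma=svm_gamma, random_state=seed)
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                # Platt-style sigmoid calibration for probability scores
                ("svc", CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)),
            ]
        )
    model.fit(X, y)
    return ClassifierHandle(
        model=model,
        algo=algo,
        positive_label=positive_label,
        feature_names=tuple(table.spec.members),
        seed=seed,
    )


@dataclass
class LabeledDataset:
    """One voltage condition: feature table + labels + a fixed stratified split."""

    table: FeatureTable
    labels: np.ndarray
    voltage: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.table)
        all_idx = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(all_idx, np.arange(n)):
            raise ValueError("train/test split must be disjoint and exhaustive")
        for part, name in ((self.train_idx, "train"), (self.test_idx, "test")):
            if len(set(self.labels[part].tolist())) < 2:
                raise ValueError(f"both classes must be present in the {name} split")

    def subset(self, idx: np.ndarray) -> FeatureTable:
        return FeatureTable(
            self.table.data.iloc[idx].reset_index(drop=True),
            self.table.spec,
            labels=self.labels[idx],
            voltage=self.voltage,
        )


def make_dataset(
    table: FeatureTable,
    labels: Sequence | None = None,
    voltage: int | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> LabeledDataset:
    """Stratified, seeded train/evaluation split of one voltage condition."""
    y = np.asarray(labels if labels is not None else table.labels)
    v = voltage if voltage is not None else table.voltage
    if v is None:
        raise ValueError("dataset voltage is required")
    idx = np.arange(len(table))
    tr, te = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=y, shuffle=True
    )
    return LabeledDataset(table, y, int(v), np.sort(tr), np.sort(te))


@dataclass
class VoltageMatrixResult:
    """AUC grid over all (train voltage, test voltage) pairs."""

    auc: pd.DataFrame  # index = train voltage, columns = test voltage
    n_events: pd.DataFrame  # evaluation event counts per cell
    algo: str
    feature_set: str
    seed: int
    positive_label: object = None

    @property
    def voltages(self) -> list[int]:
        return list(self.auc.index)

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.auc.to_numpy()), index=self.auc.index, name="diagonal_auc")

    def to_tsv(self, path: str | Path) -> Path:
        """Matrix TSV (train voltages as rows) plus a JSON metadata sidecar."""
        path = Path(path)
        self.auc.round(6).to_csv(path, sep="\t", index_label="train_mv")
        sidecar = {
            "algo": self.algo,
            "feature_set": self.feature_set,
            "seed": self.seed,
            "positive_label": str(self.positive_label),
            "train_voltages": [int(v) for v in self.auc.index],
            "test_voltages": [int(v) for v in self.auc.columns],
            "n_events": self.n_events.to_numpy().astype(int).tolist(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VoltageMatrixResult":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="train_mv")
        df.columns = [int(c) for c in df.columns]
        df.index = [int(i) for i in df.index]
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        n_ev = pd.DataFrame(meta["n_events"], index=df.index, columns=df.columns)
        return cls(
            auc=df,
            n_events=n_ev,
            algo=meta["algo"],
            feature_set=meta["feature_set"],
            seed=meta["seed"],
            positive_label=meta.get("positive_label"),
        )


def build_matrix(
    datasets: Mapping[int, LabeledDataset] | Sequence[LabeledDataset],
    algo: str = "random_forest",
    feature_set: str = "A",
    *,
    positive_label: object | None = None,
    seed: int = 0,
    min_per_class: int = 20,
) -> VoltageMatrixResult:
    """Train at each voltage, evaluate on the held-out split of every voltage.

    Every cell — diagonal and off-diagonal — uses the same evaluation
    protocol (the test split of the target voltage).  Cell values are
    invariant to the ordering of ``datasets``.
    """
    if not isinstance(datasets, Mapping):
        datasets = {ds.voltage: ds for ds in datasets}
    voltages = sorted(datasets.keys(), key=abs)  # -50 first, -300 last
    ref_schema = tuple(next(iter(datasets.values())).table.spec.members)
    for v, ds in datasets.items():
        if tuple(ds.table.spec.members) != ref_schema:
            raise ValueError(f"feature schema mismatch at voltage {v} mV")
    if positive_label is None:
        positive_label = sorted(set(next(iter(datasets.values())).labels.tolist()), key=str)[0]

    grid = pd.DataFrame(index=voltages, columns=voltages, dtype=float)
    n_ev = pd.DataFrame(index=voltages, columns=voltages, dtype=int)
    for v_train in voltages:
        ds = datasets[v_train]
        model = train_classifier(
            ds.subset(ds.train_idx),
            algo=algo,
            positive_label=positive_label,
            seed=seed,
            min_per_class=min_per_class,
        )
        for v_test in voltages:
            dt = datasets[v_test]
            eval_table = dt.subset(dt.test_idx)
            scores = model.score(eval_table)
            y = (eval_table.labels == positive_label).astype(int)
            grid.loc[v_train, v_test] = auc(scores, y)
            n_ev.loc[v_train, v_test] = len(eval_table)
    return VoltageMatrixResult(
        auc=grid,
        n_events=n_ev.astype(int),
        algo=algo,
        feature_set=feature_set,
        seed=seed,
        positive_label=positive_label,
    )


@dataclass
class ImportanceProfile:
    """Permutation importance: mean AUC drop per feature (clipped at 0 for reporting)."""

    importance: pd.Series  # clipped at 0
    raw: pd.Series  # unclipped mean drops
    repeats: int
    algo: str

    @property
    def top_feature(self) -> str:
        return str(self.importance.idxmax())


def permutation_importance(
    model: ClassifierHandle,
    table: FeatureTable,
    labels: Sequence | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceProfile:
    """Mean AUC drop over ``repeats`` independent permutations of each column."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y_raw = np.asarray(labels if labels is not None else table.labels)
    y = (y_raw == model.positive_label).astype(int)
    X = table.data[list(model.feature_names)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = auc(model.score(X), y)
    drops = {}
    for j, name in enumerate(model.feature_names):
        vals = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            vals.append(base - auc(model.score(Xp), y))
        drops[name] = float(np.mean(vals))
    raw = pd.Series(drops)
    return ImportanceProfile(importance=raw.clip(lower=0.0), raw=raw, repeats=repeats, algo=model.algo)
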