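"""Feature assembly and the random-subspace ensemble classifier.

Each sweep becomes one row of a features-by-frequency table (134 columns at
the default grid, label = glucose class in mg/dL).  The classifier is a
committee of base learners, each trained on a random subset of feature
columns drawn without replacement; predictions aggregate by plurality of
hard votes, ties breaking toward the lowest concentration.  Evaluation uses
stratified k-fold cross-validation so every row is predicted exactly once by
a model that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .processing import remove_outliers_moving_median
from .spectra import NormalizedSpectrum, SpectrumRecord

__all__ = [
    "FeatureTable",
    "EnsembleConfig",
    "SubspaceEnsemble",
    "assemble_feature_table",
    "preprocess_feature_table",
    "train_subspace_ensemble",
    "predict",
    "kfold_cross_validate",
    "PredictionSet",
    "MetricsBundle",
    "classification_metrics",
]

BASE_LEARNERS = {
    "knn": lambda: KNeighborsClassifier(n_neighbors=1),
    "lda": lambda: LinearDiscriminantAnalysis(),
}


@dataclass(frozen=True)
class FeatureTable:
    """Sweeps-by-frequency matrix with glucose class labels.

    ``features`` columns are frequencies in Hz (ascending); ``labels`` holds
    the class in mg/dL per row; ``meta`` carries (day, sample, round).
    """

    features: pd.DataFrame
    labels: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels) or len(self.features) != len(self.meta):
            raise ValueError("features, labels and meta must have equal length")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([float(c) for c in self.features.columns])

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_frame(self) -> pd.DataFrame:
        out = self.meta.reset_index(drop=True).copy()
        out = pd.concat([out, self.features.reset_index(drop=True)], axis=1)
        out["label"] = self.labels
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        meta_cols = [c for c in ("day", "sample_id", "round") if c in frame.columns]
        feat_cols = [c for c in frame.columns if c not in meta_cols + ["label"]]
        return cls(
            features=frame[feat_cols].astype(float),
            labels=frame["label"].to_numpy(float),
            meta=frame[meta_cols],
        )


def assemble_feature_table(
    records: list[SpectrumRecord] | list[NormalizedSpectrum],
) -> FeatureTable:
    """Stack sweeps into the ML table: one row per scan, one column per frequency.

    Rows are ordered (day, class, round) lexicographically; columns ascend in
    frequency; the label is the phantom's glucose concentration.
    """
    if not records:
        raise ValueError("no records to assemble")
    grid = records[0].grid
    for r in records:
        if not np.array_equal(r.grid.points, grid.points):
            raise ValueError("records are on mixed frequency grids")
    order = sorted(
        range(len(records)),
        key=lambda i: (
            records[i].meta.day,
            records[i].meta.concentration,
            records[i].meta.round_index,
        ),
    )
    recs = [records[i] for i in order]
    features = pd.DataFrame(
        np.vstack([r.amplitudes for r in recs]),
        columns=[f"{f:.6g}" for f in grid.points],
    )
    labels = np.array([r.meta.concentration for r in recs])
    meta = pd.DataFrame(
        {
            "day": [r.meta.day for r in recs],
            "sample_id": [r.meta.sample_id for r in recs],
            "round": [r.meta.round_index for r in recs],
        }
    )
    return FeatureTable(features=features, labels=labels, meta=meta)


def preprocess_feature_table(
    table: FeatureTable,
    window_before: int = 10,
    window_after: int = 2,
    threshold: float = 2.3,
    axis: str = "columns",
) -> FeatureTable:
    """Moving-median outlier removal over the feature table.

    By default the filter runs down each feature column (across sweeps, the
    way matrix-oriented outlier tools operate), so an aberrant scan value at
    one frequency is replaced by the local median of neighbouring scans
    without touching the spectral line shape.  ``axis="rows"`` filters along
    the frequency axis of each sweep instead.
    """
    X = table.features.to_numpy(float)
    if axis == "columns":
        # Filter each frequency column within a glucose class: outliers are
        # aberrant scans among the replicates of one phantom set, so the
        # moving window never spans two different concentrations.
        cleaned = X.copy()
        for label in np.unique(table.labels):
            rows = np.flatnonzero(table.labels == label)
            block = X[rows]
            # clamp the look-back for blocks shorter than the full window
            wb = min(window_before, max(1, len(rows) - window_after - 1))
            cleaned[rows] = np.column_stack(
                [
                    remove_outliers_moving_median(
                        col, window_before=wb,
                        window_after=window_after, threshold=threshold,
                    )[0]
                    for col in block.T
                ]
            )
    elif axis == "rows":
        cleaned = np.vstack(
            [
                remove_outliers_moving_median(
                    row, window_before=window_before, window_after=window_after,
                    threshold=threshold,
                )[0]
                for row in X
            ]
        )
    else:
        raise ValueError("axis must be 'columns' or 'rows'")
    return FeatureTable(
        features=pd.DataFrame(cleaned, columns=table.features.columns),
        labels=table.labels.copy(),
        meta=table.meta.copy(),
    )


@dataclass(frozen=True)
class EnsembleConfig:
    """Random-subspace ensemble hyperparameters.

    Tuning ranges from the study: 20–50 learners, subspace dimension 50–75;
    the reported optimum (30 learners, dimension 67) is the default.
    """

    n_learners: int = 30
    subspace_dim: int = 67
    base_learner: str = "knn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be at least 1")
        if self.subspace_dim < 1:
            raise ValueError("subspace_dim must be at least 1")
        if self.base_learner not in BASE_LEARNERS:
            raise ValueError(
                f"unknown base learner {self.base_learner!r}; "
                f"choose from {sorted(BASE_LEARNERS)}"
            )


class SubspaceEnsemble:
    """Committee of base learners on random feature subsets.

    Each learner sees ``subspace_dim`` columns sampled uniformly without
    replacement (independently across learners).  ``predict`` aggregates
    hard votes; ties resolve to the lowest concentration.
    """

    def __init__(self, cfg: EnsembleConfig):
        self.cfg = cfg
        self.learners_: list = []
        self.subspaces_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SubspaceEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_features = X.shape[1]
        if self.cfg.subspace_dim > n_features:
            raise ValueError(
                f"subspace_dim {self.cfg.subspace_dim} exceeds feature count {n_features}"
            )
        rng = np.random.default_rng(self.cfg.seed)
        proto = BASE_LEARNERS[self.cfg.base_learner]()
        self.learners_, self.subspaces_ = [], []
        for _ in range(self.cfg.n_learners):
            cols = np.sort(rng.choice(n_features, self.cfg.subspace_dim, replace=False))
            learner = clone(proto)
            learner.fit(X[:, cols], y)
            self.learners_.append(learner)
            self.subspaces_.append(cols)
        self.classes_ = np.unique(y)
        self.n_features_ = n_features
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise ValueError("ensemble is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for learner, cols in zip(self.learners_, self.subspaces_):
            pred = learner.predict(X[:, cols])
            for row, p in enumerate(pred):
                votes[row, class_index[p]] += 1
        # argmax returns the first maximum; classes_ ascend, so ties break
        # toward the lowest concentration.
        return self.classes_[np.argmax(votes, axis=1)]


def train_subspace_ensemble(table: FeatureTable, cfg: EnsembleConfig) -> SubspaceEnsemble:
    """Fit the ensemble on the full table (reproducible under ``cfg.seed``)."""
    return SubspaceEnsemble(cfg).fit(table.features.to_numpy(float), table.labels)


def predict(model: SubspaceEnsemble, rows: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Plurality-vote prediction for rows matching the training schema."""
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_numpy(float)
    return model.predict(np.asarray(rows, dtype=float))


@dataclass(frozen=True)
class PredictionSet:
    """Per-row cross-validated predictions with fold indices and metadata."""

    frame: pd.DataFrame  # columns: true, predicted, fold + meta columns

    def __post_init__(self) -> None:
        required = {"true", "predicted", "fold"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"prediction frame must contain {sorted(required)}")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.frame["true"] == self.frame["predicted"]))


def kfold_cross_validate(
    table: FeatureTable,
    cfg: EnsembleConfig,
    k: int = 10,
    group_by_day: bool = False,
) -> PredictionSet:
    """Cross-validate the ensemble; every row is predicted exactly once.

    Folds are stratified by class (near-equal sizes, seeded by ``cfg.seed``).
    With ``group_by_day`` the folds are grouped on the day index instead,
    which keeps each day's replicates out of their own training set — a
    harder, leakage-free protocol when day effects are present.
    """
    X = table.features.to_numpy(float)
    y = table.labels
    if k < 2:
        raise ValueError("k must be at least 2")
    _, counts = np.unique(y, return_counts=True)
    if not group_by_day and counts.min() < k:
        raise ValueError("every class needs at least k rows for stratified folds")
    if group_by_day:
        groups = table.meta["day"].to_numpy()
        splitter = GroupKFold(n_splits=min(k, len(np.unique(groups))))
        splits = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
        splits = splitter.split(X, y)

    true = np.empty(len(y))
    predicted = np.empty(len(y))
    fold_idx = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(splits):
        # derive a per-fold seed from the config seed (kept below 2**31)
        fold_cfg = EnsembleConfig(
            n_learners=cfg.n_learners,
            subspace_dim=cfg.subspace_dim,
            base_learner=cfg.base_learner,
            seed=(cfg.seed * 1009 + fold) % (2**31 - 1),
        )
        model = SubspaceEnsemble(fold_cfg).fit(X[train], y[train])
        predicted[test] = model.predict(X[test])
        true[test] = y[test]
        fold_idx[test] = fold
    frame = table.meta.reset_index(drop=True).copy()
    frame["true"] = true
    frame["predicted"] = predicted
    frame["fold"] = fold_idx
    return PredictionSet(frame=frame)


@dataclass(frozen=True)
class MetricsBundle:
    """Confusion matrix and the derived per-class and overall rates."""

    classes: np.ndarray
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray  # = true-positive rate per class
    f1: np.ndarray
    macro_f1: float

    @property
    def tpr(self) -> np.ndarray:
        return self.recall

    @property
    def fnr(self) -> np.ndarray:
        return 1.0 - self.recall


def classification_metrics(preds: PredictionSet) -> MetricsBundle:
    """Accuracy, per-class precision/recall/F1 (macro-averaged) and confusion.

    With balanced classes the macro and weighted F1 averages coincide, so the
    macro average is reported as "average F1".
    """
    if len(preds.frame) == 0:
        raise ValueError("empty prediction set")
    true = preds.frame["true"].to_numpy()
    pred = preds.frame["predicted"].to_numpy()
    classes = np.unique(true)
    unseen = np.setdiff1d(np.unique(pred), classes)
    if unseen.size:
        raise ValueError(f"predicted labels {unseen} never occur as true labels")
    confusion = _sk_confusion(true, pred, labels=classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        col = confusion.sum(axis=0)
        row = confusion.sum(axis=1)
        diag = np.diag(confusion).astype(float)
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return MetricsBundle(
        classes=classes,
        confusion=confusion,
        accuracy=float(diag.sum() / confusion.sum()),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
    )
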