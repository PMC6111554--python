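"""Classifier families, temporal splitting and cross-validated ROC/AUC.

Four families are compared for the per-breath talking decision, each with
the hyperparameters found best in model selection: a random forest with
200 trees, an RBF support vector machine with gamma = 0.01 and C = 10, a
two-hidden-layer neural network with 30 neurons per layer, and linear
discriminant analysis.  Scale-sensitive families (SVM, neural net) get a
standardization step fitted on training data; trees and LDA take raw
features.  Non-finite feature values are imputed with training-set
medians before any fit.

Model selection uses stratified 15-fold cross-validation on the first 70%
of each participant's breaths (time-ordered — no shuffling across the
split boundary), pooling out-of-fold scores into a single ROC curve whose
trapezoidal area is the AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import StratificationError

FAMILIES = ("random_forest", "svm_rbf", "neural_net", "lda")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"trees": 200},
    "svm_rbf": {"gamma": 0.01, "C": 10.0},
    "neural_net": {"hidden_layers": 2, "neurons_per_layer": 30},
    "lda": {},
}

# families whose inputs are standardized (z-scored on training data)
_SCALED_FAMILIES = frozenset({"svm_rbf", "neural_net"})


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        merged = {**_DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)

    def build(self) -> Pipeline:
        h = self.hyperparameters
        if self.family == "random_forest":
            est = RandomForestClassifier(
                n_estimators=int(h["trees"]), random_state=self.seed
            )
        elif self.family == "svm_rbf":
            est = SVC(
                kernel="rbf", gamma=h["gamma"], C=h["C"],
                probability=True, random_state=self.seed,
            )
        elif self.family == "neural_net":
            layers = (int(h["neurons_per_layer"]),) * int(h["hidden_layers"])
            est = MLPClassifier(
                hidden_layer_sizes=layers, max_iter=500,
                random_state=self.seed,
            )
        else:
            est = LinearDiscriminantAnalysis()
        steps = []
        if self.family in _SCALED_FAMILIES:
            steps.append(("scale", StandardScaler()))
        steps.append(("clf", est))
        return Pipeline(steps)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    pipeline: Pipeline
    feature_names: list[str]
    impute_medians: pd.Series
    n_samples: int
    class_counts: dict[int, int]


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _align(X: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    missing = [c for c in feature_names if c not in X.columns]
    extra = [c for c in X.columns if c not in feature_names]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match the model: missing={missing}, extra={extra}"
        )
    return X[feature_names]


def train(X: pd.DataFrame, y: np.ndarray, spec: ClassifierSpec) -> TrainedModel:
    """Fit one classifier; imputation medians come from this training set only."""
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    medians = X.median()
    Xv = X.fillna(medians)
    pipe = spec.build()
    pipe.fit(Xv.to_numpy(), y)
    return TrainedModel(
        spec=spec,
        pipeline=pipe,
        feature_names=list(X.columns),
        impute_medians=medians,
        n_samples=len(y),
        class_counts=dict(zip(classes.tolist(), counts.tolist())),
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row talking score in [0, 1]; columns aligned by name."""
    Xa = _align(X, model.feature_names).fillna(model.impute_medians)
    proba = model.pipeline.predict_proba(Xa.to_numpy())
    talk_col = list(model.pipeline.classes_).index(1)
    return proba[:, talk_col]


def predict_labels(model: TrainedModel, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    return (predict_scores(model, X) >= threshold).astype(int)


def roc_from_scores(y: np.ndarray, scores: np.ndarray) -> RocResult:
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 15,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> tuple[RocResult, pd.DataFrame, np.ndarray]:
    """Stratified k-fold CV; returns pooled ROC, per-fold metrics and
    out-of-fold scores (aligned with the rows of ``X``).

    When ``groups`` is given (e.g. breath identity for events detected on
    several bands, see ``breathing.group_breath_events``), folds never
    split a group, so near-duplicate windows cannot leak across the
    train/test boundary.
    """
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes required for cross-validation")
    if counts.min() < n_folds:
        raise StratificationError(
            f"minority class ({counts.min()}) smaller than n_folds ({n_folds})"
        )
    if groups is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = skf.split(X.to_numpy(), y)
    else:
        sgkf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = sgkf.split(X.to_numpy(), y, groups=np.asarray(groups))
    oof = np.full(len(y), np.nan)
    fold_rows = []
    for fold, (tr, te) in enumerate(splits):
        model = train(X.iloc[tr], y[tr], spec)
        scores = predict_scores(model, X.iloc[te])
        oof[te] = scores
        pred = (scores >= 0.5).astype(int)
        fold_auc = (
            roc_from_scores(y[te], scores).auc
            if len(np.unique(y[te])) == 2 else np.nan
        )
        fold_rows.append({
            "fold": fold,
            "n_test": len(te),
            "accuracy": float(np.mean(pred == y[te])),
            "auc": fold_auc,
        })
    roc = roc_from_scores(y, oof)
    return roc, pd.DataFrame(fold_rows), oof


def temporal_split(n: int, train_fraction: float = 0.70) -> tuple[np.ndarray, np.ndarray]:
    """First ceil(train_fraction * n) time-ordered rows train, rest test."""
    if n < 2:
        raise ValueError("need at least 2 events to split")
    n_train = math.ceil(train_fraction * n)
    idx = np.arange(n)
    return idx[:n_train], idx[n_train:]
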