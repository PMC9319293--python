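"""Mutual-information feature selection and the random-forest model (P1).

MI against the binary label is estimated with the plug-in contingency
estimator for discrete features and a k-nearest-neighbour estimator (k = 3)
for continuous ones; features with MI above a small noise-clipping epsilon
are kept.  The forest uses 1000 trees, Gini impurity and min-samples-split 2
by default; its malignancy probability P1 is the fraction of trees voting
malignant (a soft vote over hard per-tree predictions, hence a rational
number with denominator n_trees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score

__all__ = ["SelectionResult", "ForestConfig", "mutual_information",
           "select_features", "RadiomicsForest"]

# columns treated as discrete for the MI estimator
DISCRETE_FEATURES = ("clinical_gender", "clinical_smoking", "clinical_lesion_size")


@dataclass
class SelectionResult:
    scores: pd.Series                 # MI per feature name
    selected: list[str]
    rule: str = "mi > epsilon"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.scores.index,
            "mi_score": self.scores.values,
            "selected": [f in self.selected for f in self.scores.index],
        })


@dataclass
class ForestConfig:
    n_trees: int = 1000
    split_criterion: str = "gini"
    min_samples_to_split: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def mutual_information(feature: np.ndarray, labels: np.ndarray, *,
                       discrete: bool | None = None, seed: int = 0) -> float:
    """MI (nats) between one feature column and binary labels.

    Discrete features use the plug-in contingency estimate; continuous ones
    the k-NN estimator with k = 3.  If ``discrete`` is None the column is
    treated as discrete when it has few distinct values.
    """
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if len(feature) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant")
    if discrete is None:
        discrete = len(np.unique(feature)) <= max(8, int(np.sqrt(len(feature))) // 2)
    if discrete:
        return float(mutual_info_score(feature, labels))
    mi = mutual_info_classif(feature.reshape(-1, 1), labels,
                             discrete_features=False, n_neighbors=3,
                             random_state=seed)
    return float(mi[0])


def select_features(matrix: pd.DataFrame, labels: np.ndarray, *,
                    epsilon: float = 1e-6, seed: int = 0) -> SelectionResult:
    """Keep features whose MI estimate exceeds the noise-clipping epsilon.

    If nothing survives, the single best-scoring feature is kept and a
    warning is issued.
    """
    scores = {}
    for col in matrix.columns:
        scores[col] = mutual_information(matrix[col].to_numpy(), labels,
                                         discrete=col in DISCRETE_FEATURES,
                                         seed=seed)
    s = pd.Series(scores)
    selected = list(s.index[s > epsilon])
    if not selected:
        warnings.warn("no feature passed the MI threshold; keeping the top-1",
                      stacklevel=2)
        selected = [s.idxmax()]
    return SelectionResult(scores=s, selected=selected)


@dataclass
class RadiomicsForest:
    """Feature-selected random forest over the 89-entry vectors."""

    config: ForestConfig = field(default_factory=ForestConfig)
    selection: SelectionResult | None = None
    _rf: RandomForestClassifier | None = None

    def fit(self, matrix: pd.DataFrame, labels: np.ndarray) -> "RadiomicsForest":
        labels = np.asarray(labels, dtype=int)
        counts = np.bincount(labels, minlength=2)
        if (counts < 2).any():
            raise ValueError("need at least 2 samples per class")
        self.selection = select_features(matrix, labels, seed=self.config.rng_seed)
        x = matrix[self.selection.selected].to_numpy(dtype=float)
        self._rf = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            criterion=self.config.split_criterion,
            min_samples_split=self.config.min_samples_to_split,
            random_state=self.config.rng_seed,
            n_jobs=1,
        ).fit(x, labels)
        return self

    def predict_p1(self, matrix: pd.DataFrame) -> np.ndarray:
        """Malignancy probability: fraction of trees voting class 1."""
        if self._rf is None or self.selection is None:
            raise RuntimeError("model is not trained")
        missing = [c for c in self.selection.selected if c not in matrix.columns]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        x = matrix[self.selection.selected].to_numpy(dtype=float)
        votes = np.stack([t.predict(x) for t in self._rf.estimators_])
        return votes.mean(axis=0)
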