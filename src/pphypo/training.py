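"""Cost-sensitive training with cross-subject k-fold validation.

The postprandial sample set is heavily imbalanced (roughly 16 negatives
per positive in clinical data), so every classifier is trained
cost-sensitively: the false-negative cost is the exact negative:positive
label-count ratio of the training folds, the false-positive cost is 1, and
correct decisions cost 0.  For forest/SVM/logistic families the costs enter
as per-class weights; the K-nearest-neighbor vote multiplies positive
neighbors by the false-negative cost before the majority comparison.

Validation is *cross-subject*: patients (not series, not samples) are the
fold unit, so no subject contributes to both sides of a split; patients
contributing two sessions keep both series on the same side.
Hyperparameters come from a subject-grouped inner grid search minimizing
the cost-weighted misclassification loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC, LinearSVC

from .features import FEATURE_COLUMNS, ScalerParams, apply_scaler, fit_scaler

FAMILIES = ("RF", "SVM_LN", "SVM_RBF", "KNN", "LR")

#: hyperparameter grids (the study does not publish its grids; overridable)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF": [
        {"n_estimators": n, "max_depth": d}
        for n, d in itertools.product([100, 300], [4, 8, None])
    ],
    "SVM_LN": [{"C": c} for c in [0.1, 1.0, 10.0]],
    "SVM_RBF": [
        {"C": c, "gamma": g}
        for c, g in itertools.product([0.1, 1.0, 10.0], [0.01, 0.1, 1.0])
    ],
    "KNN": [{"n_neighbors": k} for k in [5, 15, 31]],
    "LR": [{"C": c} for c in [0.1, 1.0, 10.0]],
}

#: compact grids for cohort-scale experiments (kept small so a full
#: five-family 5-fold run with inner search stays in the minutes range)
FAST_GRIDS: dict[str, list[dict]] = {
    "RF": [{"n_estimators": 100, "max_depth": d} for d in [8, None]],
    "SVM_LN": [{"C": c} for c in [0.1, 1.0, 10.0]],
    "SVM_RBF": [{"C": 10.0, "gamma": "scale"}],
    "KNN": [{"n_neighbors": k} for k in [5, 15, 31]],
    "LR": [{"C": c} for c in [0.1, 1.0, 10.0]],
}

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class CostSpec:
    """Misclassification costs: FN cost is the exact neg:pos count ratio."""

    cost_fn: Fraction
    cost_fp: int = 1
    cost_tp: int = 0
    cost_tn: int = 0

    @property
    def fn_weight(self) -> float:
        return float(self.cost_fn)


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_series: tuple[str, ...]
    test_series: tuple[str, ...]
    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]


@dataclass
class TrainedModel:
    family: str
    hyperparams: dict
    scaler: ScalerParams
    classifier: object
    cost: CostSpec
    feature_subset: str = "all"

    @property
    def feature_names(self) -> list[str]:
        return FEATURE_COLUMNS[self.feature_subset]


def compute_fn_cost(train: pd.DataFrame) -> CostSpec:
    """False-negative cost = (# negative samples) / (# positive samples)."""
    n_pos = int((train["label"] == 1).sum())
    n_neg = int((train["label"] == 0).sum())
    if n_pos == 0:
        raise ValueError(
            "training folds contain no positive samples; re-split the cohort"
        )
    return CostSpec(cost_fn=Fraction(n_neg, n_pos))


def cross_subject_folds(
    patients_by_series: Mapping[str, str], k: int = 5, seed: int = 0
) -> list[FoldSplit]:
    """Deal patients round-robin into k folds; series follow their patient."""
    patients = sorted(set(patients_by_series.values()))
    if len(patients) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    groups: list[list[str]] = [order[q::k] for q in range(k)]
    splits = []
    for q, test_patients in enumerate(groups, start=1):
        test_set = set(test_patients)
        test_series = tuple(
            s for s, p in sorted(patients_by_series.items()) if p in test_set
        )
        train_series = tuple(
            s for s, p in sorted(patients_by_series.items()) if p not in test_set
        )
        splits.append(
            FoldSplit(
                fold=q,
                train_series=train_series,
                test_series=test_series,
                train_patients=tuple(sorted(set(patients) - test_set)),
                test_patients=tuple(sorted(test_set)),
            )
        )
    return splits


class _CostWeightedKNN:
    """KNN whose positive-neighbor votes are multiplied by the FN cost.

    Score = cost_fn * n_pos_neighbors / (cost_fn * n_pos + n_neg), which is
    >= 0.5 exactly when the cost-weighted positive vote wins.
    """

    def __init__(self, n_neighbors: int, fn_weight: float):
        self.n_neighbors = n_neighbors
        self.fn_weight = fn_weight
        self._nn = NearestNeighbors(n_neighbors=n_neighbors)
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_CostWeightedKNN":
        self._nn.fit(X)
        self._y = np.asarray(y, dtype=int)
        return self

    def score_positive(self, X: np.ndarray) -> np.ndarray:
        _, idx = self._nn.kneighbors(X)
        n_pos = self._y[idx].sum(axis=1)
        n_neg = self.n_neighbors - n_pos
        w = self.fn_weight
        return (w * n_pos) / (w * n_pos + n_neg)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _make_classifier(family: str, hp: dict, cost: CostSpec, seed: int):
    weights = {0: float(cost.cost_fp), 1: cost.fn_weight}
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth"),
            class_weight=weights,
            random_state=seed,
            n_jobs=1,
        )
    if family == "SVM_LN":
        return LinearSVC(C=hp.get("C", 1.0), class_weight=weights, random_state=seed)
    if family == "SVM_RBF":
        return SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            class_weight=weights,
            cache_size=500,
            random_state=seed,
        )
    if family == "KNN":
        return _CostWeightedKNN(hp.get("n_neighbors", 15), cost.fn_weight)
    if family == "LR":
        return LogisticRegression(
            C=hp.get("C", 1.0), class_weight=weights, max_iter=1000, random_state=seed
        )
    raise ValueError(f"unknown model family {family!r}")


def _score_positive(classifier, X: np.ndarray) -> np.ndarray:
    if isinstance(classifier, _CostWeightedKNN):
        return classifier.score_positive(X)
    if hasattr(classifier, "predict_proba"):
        return classifier.predict_proba(X)[:, 1]
    # margin classifiers (SVMs): monotone logistic map of the signed margin,
    # so score >= 0.5 coincides with the decision function's sign
    return _sigmoid(classifier.decision_function(X))


def train_model(
    family: str,
    train: pd.DataFrame,
    cost: CostSpec,
    hyperparams: dict,
    feature_subset: str = "all",
    seed: int = 0,
) -> TrainedModel:
    """Fit one family on (already assembled) training samples.

    The MinMax scaler is fitted on these samples only; the model exposes a
    continuous positive-class score in [0, 1] via :func:`predict`.
    """
    features = FEATURE_COLUMNS[feature_subset]
    scaler = fit_scaler(train, features)
    X = apply_scaler(scaler, train)
    y = train["label"].to_numpy(dtype=int)
    clf = _make_classifier(family, hyperparams, cost, seed)
    clf.fit(X, y)
    return TrainedModel(
        family=family,
        hyperparams=dict(hyperparams),
        scaler=scaler,
        classifier=clf,
        cost=cost,
        feature_subset=feature_subset,
    )


def predict(
    model: TrainedModel, samples: pd.DataFrame, threshold: float = DECISION_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class scores in [0, 1] and hard labels (score >= threshold)."""
    missing = [f for f in model.feature_names if f not in samples.columns]
    if missing:
        raise ValueError(f"samples lack feature columns {missing}")
    if len(samples) == 0:
        return np.array([]), np.array([], dtype=int)
    X = apply_scaler(model.scaler, samples)
    if isinstance(model.classifier, _CostWeightedKNN):
        scores = model.classifier.score_positive(X)
    else:
        scores = _score_positive(model.classifier, X)
    return scores, (scores >= threshold).astype(int)


def _inner_folds(
    train: pd.DataFrame,
    patients_by_series: Mapping[str, str],
    inner_k: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped inner splits over the training samples (row masks)."""
    pbs = {
        s: patients_by_series[s] for s in train["series_id"].unique()
    }
    splits = cross_subject_folds(pbs, k=inner_k, seed=seed)
    out = []
    sid = train["series_id"].to_numpy()
    for sp in splits:
        test_mask = np.isin(sid, sp.test_series)
        out.append((~test_mask, test_mask))
    return out


def grid_search(
    family: str,
    train: pd.DataFrame,
    patients_by_series: Mapping[str, str],
    grid: Sequence[dict] | None = None,
    inner_k: int = 3,
    feature_subset: str = "all",
    seed: int = 0,
) -> dict:
    """Pick the grid point with the lowest mean cost-weighted inner-CV loss.

    loss = (cost_fn * FN + cost_fp * FP) / n on each subject-grouped inner
    test side.  Ties break by declared grid order.  A single-point grid is
    returned immediately.
    """
    grid = list(DEFAULT_GRIDS[family] if grid is None else grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return dict(grid[0])

    folds = _inner_folds(train, patients_by_series, inner_k, seed)
    best_hp, best_loss = None, np.inf
    for hp in grid:
        losses = []
        for train_mask, test_mask in folds:
            inner_train = train[train_mask]
            inner_test = train[test_mask]
            if inner_test.empty or (inner_train["label"] == 1).sum() == 0:
                continue
            cost = compute_fn_cost(inner_train)
            model = train_model(
                family, inner_train, cost, hp, feature_subset, seed=seed
            )
            _, hard = predict(model, inner_test)
            y = inner_test["label"].to_numpy(dtype=int)
            fn = int(np.sum((y == 1) & (hard == 0)))
            fp = int(np.sum((y == 0) & (hard == 1)))
            losses.append((cost.fn_weight * fn + cost.cost_fp * fp) / len(y))
        mean_loss = float(np.mean(losses)) if losses else np.inf
        if mean_loss < best_loss:  # strict: ties keep the earlier grid point
            best_hp, best_loss = dict(hp), mean_loss
    assert best_hp is not None
    return best_hp
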