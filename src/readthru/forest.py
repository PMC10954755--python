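"""Random-forest models of readthrough efficiency.

Regression forests predict log2 readthrough efficiency directly;
classification forests separate the "high" from the "low" extreme groups.
Both use 100 trees by default, with the number of candidate split
features (mtry) tuned by 5-fold cross-validation, mirroring the classic
randomForest/caret workflow.

The ensemble is built explicitly from scikit-learn decision trees with
our own bootstrap so that out-of-bag (OOB) bookkeeping is first-class:
the reported importances are the classic scaled OOB permutation
importances — %IncMSE for regression (increase in OOB MSE when a
feature's OOB values are permuted, averaged over trees and divided by its
standard error) and MDA for classification (mean decrease in OOB
accuracy, same scaling).
"""

from __future__ import annotations

import math
import pickle
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .features import FeatureSchema, encode_feature_matrix

POSITIVE_CLASS = "high"
NEGATIVE_CLASS = "low"


@dataclass
class ModelSpec:
    """Training configuration.

    ``mtry_grid`` defaults to {1, ceil(p/10), ceil(p/3), ceil(sqrt(p)),
    ceil(p/2)} clipped to [1, p] — the regression and classification
    heuristics plus coarse brackets.  ``tune=False`` skips the grid and
    uses the task's default heuristic (p/3 regression, sqrt(p)
    classification), as the model-variant comparisons do.
    ``min_samples_leaf=None`` resolves to 5 for regression and 1 for
    classification (the reference tool's node-size defaults).
    """

    task: str = "regression"  # or "classification"
    n_trees: int = 100
    cv_folds: int = 5
    mtry_grid: tuple[int, ...] | None = None
    seed: int = 0
    tune: bool = True
    min_samples_leaf: int | None = None

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def resolved_leaf(self) -> int:
        if self.min_samples_leaf is not None:
            return self.min_samples_leaf
        return 5 if self.task == "regression" else 1

    def default_mtry(self, p: int) -> int:
        if self.task == "regression":
            return max(1, p // 3)
        return max(1, math.isqrt(p))


def default_mtry_grid(p: int, task: str) -> tuple[int, ...]:
    cands = {1, math.ceil(p / 10), math.ceil(p / 3), math.ceil(math.sqrt(p)),
             math.ceil(p / 2)}
    return tuple(sorted(min(max(m, 1), p) for m in cands))


def nrmse(y: np.ndarray, yhat: np.ndarray, y_range: float | None = None) -> float:
    """RMSE normalized to the range of the response."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    rng = float(np.max(y) - np.min(y)) if y_range is None else float(y_range)
    if rng <= 0:
        raise ValueError("NRMSE undefined: zero response range")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / rng)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random 'high' outranks a random 'low' (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE_CLASS
    neg = labels == NEGATIVE_CLASS
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


class _Forest:
    """Bagged ensemble of decision trees with explicit OOB bookkeeping."""

    def __init__(self, task: str, n_trees: int, mtry: int,
                 min_samples_leaf: int, seed: int):
        self.task = task
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees: list = []
        self.inbag: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        n = len(X)
        rng = np.random.default_rng(self.seed)
        tree_cls = (DecisionTreeRegressor if self.task == "regression"
                    else DecisionTreeClassifier)
        if self.task == "classification":
            self.classes_ = np.unique(y)
        self.trees, self.inbag = [], []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = tree_cls(
                max_features=self.mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.inbag.append(idx)
        self._n_fit = n
        return self

    def oob_mask(self, t: int) -> np.ndarray:
        mask = np.ones(self._n_fit, dtype=bool)
        mask[self.inbag[t]] = False
        return mask

    def _tree_score(self, tree, X: np.ndarray) -> np.ndarray:
        """Per-tree prediction: value for regression, P(high) for classification."""
        if self.task == "regression":
            return tree.predict(X)
        proba = tree.predict_proba(X)
        out = np.zeros(len(X))
        for i, cls in enumerate(tree.classes_):
            if cls == POSITIVE_CLASS:
                out = proba[:, i]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble prediction: mean response, or vote fraction for 'high'."""
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += self._tree_score(tree, X)
        return acc / len(self.trees)


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reuse or audit it."""

    schema: FeatureSchema
    spec: ModelSpec
    forest: _Forest
    mtry: int
    cv_metric: float  # mean CV NRMSE (regression) or AUROC (classification)
    cv_table: pd.DataFrame  # per-mtry mean CV metric
    training_ids: tuple[str, ...]
    y_range: float | None = None
    encode_warnings: tuple[str, ...] = field(default_factory=tuple)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _prepare(table: pd.DataFrame, schema: FeatureSchema):
    X, warns = encode_feature_matrix(table, schema)
    ids = tuple(table["transcript_id"].astype(str))
    return X, ids, warns


def train_regressor(
    table: pd.DataFrame, target: np.ndarray, spec: ModelSpec,
    schema: FeatureSchema,
) -> TrainedModel:
    """Fit a regression forest of log2 RE, tuning mtry by CV NRMSE.

    Fold NRMSEs are normalized by the full training-response range so
    folds are comparable.  The final forest is refit on all data at the
    chosen mtry.
    """
    if spec.task != "regression":
        raise ValueError("spec.task must be 'regression'")
    y = np.asarray(target, dtype=float)
    if len(table) != len(y):
        raise ValueError("feature/target length mismatch")
    if len(y) < 50:
        raise ValueError("need at least 50 training records")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    y_range = float(np.max(y) - np.min(y))
    if y_range <= 0:
        raise ValueError("NRMSE undefined: constant target")

    X, ids, warns = _prepare(table, schema)
    p = X.shape[1]
    grid = (spec.mtry_grid if spec.mtry_grid is not None
            else default_mtry_grid(p, spec.task) if spec.tune
            else (spec.default_mtry(p),))
    if any(not 1 <= m <= p for m in grid):
        raise ValueError(f"mtry grid {grid} outside [1, {p}]")

    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(X))
    rows = []
    for m in grid:
        errs = []
        for f, (tr, te) in enumerate(folds):
            forest = _Forest("regression", spec.n_trees, m,
                             spec.resolved_leaf(),
                             seed=_substream(spec.seed, m, f)).fit(X[tr], y[tr])
            errs.append(nrmse(y[te], forest.predict(X[te]), y_range=y_range))
        rows.append({"mtry": m, "cv_nrmse": float(np.mean(errs))})
    cv_table = pd.DataFrame(rows)
    best = cv_table.loc[cv_table["cv_nrmse"].idxmin()]
    mtry = int(best["mtry"])
    forest = _Forest("regression", spec.n_trees, mtry, spec.resolved_leaf(),
                     seed=spec.seed).fit(X, y)
    return TrainedModel(schema, spec, forest, mtry, float(best["cv_nrmse"]),
                        cv_table, ids, y_range=y_range,
                        encode_warnings=tuple(warns))


def train_classifier(
    table: pd.DataFrame, labels: np.ndarray, spec: ModelSpec,
    schema: FeatureSchema,
) -> TrainedModel:
    """Fit a high-vs-low classification forest, tuning mtry by CV AUROC."""
    if spec.task != "classification":
        raise ValueError("spec.task must be 'classification'")
    y = np.asarray(labels)
    if len(table) != len(y):
        raise ValueError("feature/label length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if set(classes) != {POSITIVE_CLASS, NEGATIVE_CLASS}:
        raise ValueError(f"labels must be exactly {{'high','low'}}, got {set(classes)}")
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"cv_folds={spec.cv_folds} exceeds the smaller class count {counts.min()}"
        )

    X, ids, warns = _prepare(table, schema)
    p = X.shape[1]
    grid = (spec.mtry_grid if spec.mtry_grid is not None
            else default_mtry_grid(p, spec.task) if spec.tune
            else (spec.default_mtry(p),))
    if any(not 1 <= m <= p for m in grid):
        raise ValueError(f"mtry grid {grid} outside [1, {p}]")

    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.seed)
    folds = list(skf.split(X, y))
    rows = []
    for m in grid:
        aucs = []
        for f, (tr, te) in enumerate(folds):
            forest = _Forest("classification", spec.n_trees, m,
                             spec.resolved_leaf(),
                             seed=_substream(spec.seed, m, f)).fit(X[tr], y[tr])
            aucs.append(auroc(forest.predict(X[te]), y[te]))
        rows.append({"mtry": m, "cv_auroc": float(np.mean(aucs))})
    cv_table = pd.DataFrame(rows)
    best = cv_table.loc[cv_table["cv_auroc"].idxmax()]
    mtry = int(best["mtry"])
    forest = _Forest("classification", spec.n_trees, mtry, spec.resolved_leaf(),
                     seed=spec.seed).fit(X, y)
    return TrainedModel(schema, spec, forest, mtry, float(best["cv_auroc"]),
                        cv_table, ids, encode_warnings=tuple(warns))


def _substream(seed: int, *tags: int) -> int:
    """Derive a deterministic sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(seed)] + [int(t) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def permutation_importance(
    model: TrainedModel, table: pd.DataFrame, target: np.ndarray
) -> pd.DataFrame:
    """Classic scaled OOB permutation importance.

    For each tree, the OOB error (MSE for regression, misclassification
    rate for classification) is recomputed with each feature's OOB values
    permuted; the across-tree mean increase divided by its standard error
    is the reported score (%IncMSE / MDA convention).  The unscaled mean
    difference is kept alongside.  Constant features score 0.
    """
    X, _, _ = _prepare(table, model.schema)
    forest = model.forest
    y = np.asarray(target)
    if forest.task == "regression":
        y = y.astype(float)
    n_feat = X.shape[1]
    diffs = np.full((len(forest.trees), n_feat), np.nan)
    rng = np.random.default_rng(_substream(model.spec.seed, 7))
    for t, tree in enumerate(forest.trees):
        oob = forest.oob_mask(t)
        if not oob.any():
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base = _tree_error(forest, tree, X_oob, y_oob)
        Xp = X_oob.copy()
        for j in range(n_feat):
            saved = Xp[:, j].copy()
            Xp[:, j] = saved[rng.permutation(len(saved))]
            diffs[t, j] = _tree_error(forest, tree, Xp, y_oob) - base
            Xp[:, j] = saved
    rows = []
    n_trees = len(forest.trees)
    for j, name in enumerate(model.schema.feature_names):
        d = diffs[:, j]
        d = d[~np.isnan(d)]
        mean = float(d.mean()) if len(d) else 0.0
        sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        if np.ptp(X[:, j]) == 0:
            score, note = 0.0, "constant feature"
        elif sd == 0:
            score, note = mean, "zero variance across trees" if mean else ""
        else:
            score, note = mean / (sd / math.sqrt(len(d))), ""
        rows.append({
            "feature": name,
            "importance": score,
            "raw_mean": mean,
            "group": model.schema.groups[name],
            "note": note,
        })
    out = pd.DataFrame(rows)
    out["rank"] = out["importance"].rank(ascending=False, method="min").astype(int)
    return out


def _tree_error(forest: _Forest, tree, X: np.ndarray, y: np.ndarray) -> float:
    if forest.task == "regression":
        return float(np.mean((tree.predict(X) - y) ** 2))
    return float(np.mean(tree.predict(X) != y))


def predict_readthrough(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict log2 RE (regression) or 'high' vote fraction (classification).

    Unseen categorical levels are bucketed with a warning, never a crash.
    """
    X, warns = encode_feature_matrix(table, model.schema)
    for w in warns:
        _warnings.warn(w, stacklevel=2)
    return model.forest.predict(X)
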