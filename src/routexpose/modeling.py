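"""Mode-choice classification: pruning, rebalancing, tuning, training, evaluation.

The classifier is a bagged random forest predicting the travel mode (car,
bicycle, walk) of each individual trip from its exposure feature vector.
Before training, features with pairwise |Pearson r| above a threshold are
pruned, the training partition is rebalanced to the minority-class size by
near-miss undersampling, and the number of trees / maximum split features
are tuned by cross-validated grid search.  The test partition keeps the
original class distribution.

The three core steps are scikit-learn-style estimators so they compose with
sklearn pipelines and model selection; the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import (
    ClassMissingError,
    InvalidConfigError,
    SchemaError,
    StateError,
    StratificationError,
)
from .synthetic_city import MODES

__all__ = [
    "ModelConfig",
    "EvalReport",
    "CorrelationPruner",
    "NearMissUndersampler",
    "ModeChoiceForest",
    "prune_correlated",
    "nearmiss_undersample",
    "split",
    "tune_forest",
    "train_forest",
    "evaluate",
    "DEFAULT_KEEP_POI",
]

#: POI features always retained by the pruner, mirroring the retained set of
#: the real-city analyses (retail, education, recreation, health).
DEFAULT_KEEP_POI = (
    "mean_poi_retail",
    "mean_poi_educational",
    "mean_poi_recreational",
    "mean_poi_medical",
)

NON_FEATURE_COLUMNS = ("individual_id", "mode", "origin_cell", "dest_cell")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric predictor columns of a trip table (everything but ids/label)."""
    return [c for c in table.columns if c not in NON_FEATURE_COLUMNS]


@dataclass
class ModelConfig:
    """Hyperparameters of the modelling stage."""

    correlation_threshold: float = 0.8
    test_fraction: float = 0.30
    tree_grid: tuple[int, ...] = (500,)
    max_features_grid: tuple[int, ...] | None = None  # None -> 1..p
    n_trees_final: int | None = None
    max_features_final: int | None = None
    nearmiss_variant: str = "keep-closest"
    keep_list: tuple[str, ...] = DEFAULT_KEEP_POI
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise InvalidConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if len(self.tree_grid) == 0:
            raise InvalidConfigError("tree_grid must be non-empty")
        if self.nearmiss_variant not in ("keep-closest", "remove-closest"):
            raise InvalidConfigError(f"unknown nearmiss variant {self.nearmiss_variant!r}")


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Drop features until no retained pair has |Pearson r| above ``threshold``.

    When a correlated pair conflicts, the droppable feature with the larger
    mean absolute correlation to all other retained features is removed
    (ties drop the later column).  Features in ``keep`` are never dropped
    and are exempt from the pairwise constraint among themselves; constant
    columns are excluded with a warning since their correlation is undefined.
    """

    def __init__(self, threshold: float = 0.8, keep: tuple[str, ...] = ()):
        self.threshold = threshold
        self.keep = keep

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] < 2:
            raise InvalidConfigError("need at least 2 feature columns to prune")
        keep = [c for c in self.keep if c in X.columns]
        cols = list(X.columns)
        const = [c for c in cols if X[c].nunique(dropna=False) <= 1]
        for c in const:
            warnings.warn(f"dropping constant column {c!r} (undefined correlation)")
        retained = [c for c in cols if c not in const]
        corr = X[retained].corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)

        while True:
            sub = corr.loc[retained, retained]
            viol = sub > self.threshold
            # pairs entirely inside the keep list are exempt
            droppable = [c for c in retained if c not in keep]
            offenders = [
                c for c in droppable
                if viol.loc[c].any()
            ]
            if not offenders:
                break
            mean_abs = sub.mean(axis=0)
            # larger mean absolute correlation first; ties -> later column
            offenders.sort(key=lambda c: (mean_abs[c], cols.index(c)))
            drop = offenders[-1]
            retained = [c for c in retained if c != drop]

        self.retained_features_ = retained
        self.dropped_features_ = [c for c in cols if c not in retained]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_features_"):
            raise StateError("CorrelationPruner is not fitted")
        return X[self.retained_features_]


class NearMissUndersampler(BaseEstimator):
    """Balance classes to the minority count by distance-based undersampling.

    Distances are computed on a z-scored copy of X (original values are
    returned).  For each majority class, every point's mean Euclidean
    distance to its ``n_neighbors`` nearest minority-class points is ranked;
    the ``keep-closest`` variant retains the majority points closest to the
    minority class (standard near-miss), ``remove-closest`` retains the
    farthest.  Minority-class rows pass through unchanged.
    """

    def __init__(self, variant: str = "keep-closest", n_neighbors: int = 3):
        self.variant = variant
        self.n_neighbors = n_neighbors

    def fit_resample(self, X, y):
        if self.variant not in ("keep-closest", "remove-closest"):
            raise InvalidConfigError(f"unknown nearmiss variant {self.variant!r}")
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        counts = y.value_counts()
        if (counts == 0).any() or counts.size < 2:
            raise ClassMissingError("need at least 2 non-empty classes to rebalance")
        minority = counts.idxmin()
        n_min = int(counts.min())

        Xv = X.to_numpy(dtype=float)
        sd = Xv.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xv - Xv.mean(axis=0)) / sd
        min_mask = (y == minority).to_numpy()
        nn = NearestNeighbors(n_neighbors=min(self.n_neighbors, min_mask.sum()))
        nn.fit(Z[min_mask])

        keep_pos: list[np.ndarray] = [np.nonzero(min_mask)[0]]
        for klass in counts.index:
            if klass == minority:
                continue
            pos = np.nonzero((y == klass).to_numpy())[0]
            d, _ = nn.kneighbors(Z[pos])
            score = d.mean(axis=1)
            order = np.argsort(score, kind="stable")
            if self.variant == "remove-closest":
                order = order[::-1]
            keep_pos.append(pos[np.sort(order[:n_min])])
        sel = np.sort(np.concatenate(keep_pos))
        self.sample_indices_ = X.index.to_numpy()[sel]
        return X.iloc[sel], y.iloc[sel]


class ModeChoiceForest(BaseEstimator, ClassifierMixin):
    """Bagged random forest with a per-class vote-fraction predictor.

    Each of ``n_trees`` trees is grown on a bootstrap resample considering
    ``max_features`` candidate features per split; remaining tree settings
    are the library defaults (unlimited depth, minimum split size 2, Gini
    impurity).  ``vote_fractions`` returns the fraction of trees voting for
    each class — the quantity the partial-dependence logits are built from —
    and the out-of-bag score is recorded at fit time.
    """

    def __init__(self, n_trees: int = 500, max_features="sqrt", seed: int | None = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        if self.n_trees < 1:
            raise InvalidConfigError(f"n_trees must be >= 1, got {self.n_trees}")
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OOB warning on tiny fixtures
            self.forest_ = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=self.max_features,
                oob_score=True,
                random_state=self.seed,
                n_jobs=1,
            ).fit(X.to_numpy(dtype=float), np.asarray(y))
        self.classes_ = self.forest_.classes_
        self.oob_score_ = float(getattr(self.forest_, "oob_score_", np.nan))
        return self

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise StateError("ModeChoiceForest is not fitted")
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_:
            raise SchemaError(
                f"feature columns {list(X.columns)} do not match training "
                f"columns {self.feature_names_}"
            )
        return X.to_numpy(dtype=float)

    @staticmethod
    def _tied_argmax(p: np.ndarray, noise: np.ndarray) -> np.ndarray:
        """Row-wise argmax with exact ties broken by a random preference.

        A deterministic tie-break (e.g. first class) systematically favours
        one class wherever leaf distributions tie, which biases vote counts;
        a seeded random preference keeps them unbiased and reproducible.
        """
        mx = p.max(axis=1, keepdims=True)
        tied = p >= mx - 1e-12
        return np.argmax(np.where(tied, 1.0 + noise, 0.0), axis=1)

    def vote_fractions(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting for each class, rows on the simplex.

        Each tree casts one hard vote per row; a tree's leaf-level ties are
        broken by that tree's own seeded class preference, so the result for
        a row never depends on which other rows share the call.
        """
        Xa = self._check(X)
        rng = np.random.default_rng([0 if self.seed is None else self.seed, 0x7E5])
        votes = np.zeros((Xa.shape[0], len(self.classes_)))
        for tree in self.forest_.estimators_:
            pref = rng.random(len(self.classes_))  # one preference per tree
            idx = self._tied_argmax(tree.predict_proba(Xa), pref)
            np.add.at(votes, (np.arange(Xa.shape[0]), idx), 1.0)
        return votes / len(self.forest_.estimators_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        votes = self.vote_fractions(X)
        rng = np.random.default_rng([0 if self.seed is None else self.seed, 0x9AD])
        return self.classes_[self._tied_argmax(votes, rng.random(votes.shape))]

    @property
    def feature_importances_(self) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise StateError("ModeChoiceForest is not fitted")
        return self.forest_.feature_importances_


@dataclass
class EvalReport:
    """Held-out evaluation: 3x3 confusion matrix (rows = true mode, fixed
    order car/bicycle/walk), overall accuracy, per-class recall."""

    confusion: pd.DataFrame
    accuracy: float
    per_class_recall: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "confusion": {m: self.confusion.loc[m].to_dict() for m in self.confusion.index},
        }


# --------------------------------------------------------------------------
# module-level operation wrappers


def prune_correlated(table: pd.DataFrame, threshold: float = 0.8,
                     keep_list: tuple[str, ...] | None = None) -> list[str]:
    keep = DEFAULT_KEEP_POI if keep_list is None else tuple(keep_list)
    X = table[feature_columns(table)]
    return CorrelationPruner(threshold=threshold, keep=keep).fit(X).retained_features_


def nearmiss_undersample(X, y, variant: str = "keep-closest"):
    return NearMissUndersampler(variant=variant).fit_resample(X, y)


def split(table: pd.DataFrame, test_fraction: float = 0.30, seed: int = 0):
    """Stratified train/test partition on the mode label; disjoint and exhaustive."""
    if len(table) == 0:
        raise InvalidConfigError("cannot split an empty table")
    present = set(table["mode"])
    missing = [m for m in MODES if m not in present]
    if missing:
        raise StratificationError(f"modes {missing} absent; cannot stratify")
    train, test = train_test_split(
        table, test_size=test_fraction, stratify=table["mode"], random_state=seed
    )
    return train, test


def tune_forest(train: pd.DataFrame, config: ModelConfig):
    """Cross-validated grid search over (n_trees, max_features).

    Returns the selected pair and the full accuracy grid.  Selection is the
    highest mean 3-fold accuracy; ties prefer fewer trees, then fewer
    features.  Grid points with max_features > p are skipped with a warning.
    """
    feats = feature_columns(train)
    p = len(feats)
    mf_grid = tuple(config.max_features_grid or range(1, p + 1))
    X, y = train[feats], train["mode"].to_numpy()
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=config.seed)
    folds = list(cv.split(X, y))

    rows = []
    best = None
    for n_trees in sorted(config.tree_grid):
        for mf in sorted(mf_grid):
            if mf > p:
                warnings.warn(f"skipping max_features={mf} > p={p}")
                continue
            accs = []
            for tr, va in folds:
                model = ModeChoiceForest(n_trees=n_trees, max_features=mf, seed=config.seed)
                model.fit(X.iloc[tr], y[tr])
                accs.append(float((model.predict(X.iloc[va]) == y[va]).mean()))
            acc = float(np.mean(accs))
            rows.append({"n_trees": n_trees, "max_features": mf, "cv_accuracy": acc})
            if best is None or acc > best[0]:  # strict: earlier (smaller) wins ties
                best = (acc, n_trees, mf)
    grid = pd.DataFrame(rows)
    return (best[1], best[2]), grid


def train_forest(train: pd.DataFrame, n_trees: int, max_features, seed: int) -> ModeChoiceForest:
    feats = feature_columns(train)
    return ModeChoiceForest(n_trees=n_trees, max_features=max_features, seed=seed).fit(
        train[feats], train["mode"].to_numpy()
    )


def evaluate(model: ModeChoiceForest, test: pd.DataFrame) -> EvalReport:
    """Confusion matrix and accuracy on held-out data (rows = true mode)."""
    feats = feature_columns(test)
    pred = model.predict(test[feats])
    true = test["mode"].to_numpy()
    order = list(MODES)
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for t, q in zip(true, pred):
        mat.loc[t, q] += 1
    total = mat.to_numpy().sum()
    acc = float(np.trace(mat.to_numpy()) / total) if total else float("nan")
    recall = {
        m: float(mat.loc[m, m] / mat.loc[m].sum()) if mat.loc[m].sum() else float("nan")
        for m in order
    }
    return EvalReport(confusion=mat, accuracy=acc, per_class_recall=recall)
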