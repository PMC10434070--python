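"""Cross-validated biomarker regressions: taxa → salinity / drought index.

The workflow mirrors the randomForest/rfcv idiom: rank features by
importance on the full data, evaluate k-fold cross-validated error at
geometrically shrinking feature-set sizes, pick the smallest size whose
error is within a tolerance of the minimum, then refit on a random 70/30
train/test split and report the test-set explained variance as a percent
("prediction accuracy" = 100·(1 − MSE/Var(y_test)); negative values mean
worse-than-mean prediction and are reported as-is).

The regressor is injectable: anything with the sklearn estimator API and a
``feature_importances_`` attribute after fitting works, so the pipeline
logic is testable with a deterministic stub. The default is a 1,000-tree
random forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .io import AbundanceTable


def default_regressor(seed: int = 0, n_trees: int = 1000) -> RandomForestRegressor:
    """The reference ensemble regressor (random forest, 1,000 trees)."""
    return RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)


# ---------------------------------------------------------------------------


def aggregate_rank(table: AbundanceTable, annotation: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Relative-abundance feature matrix at a taxonomic rank.

    ``rank='zotu'`` keeps taxa as-is; otherwise rows are summed within the
    annotation column ``rank`` (missing labels pooled under "unassigned").
    Columns (samples) are renormalised to sum to 1.
    """
    frame = table.to_frame().astype(float)
    if rank != "zotu":
        if rank not in annotation.columns:
            raise ValueError(f"annotation lacks a '{rank}' column")
        labels = annotation.reindex(table.taxon_ids)[rank].fillna("unassigned")
        frame.index = labels.to_numpy()
        frame = frame.groupby(level=0).sum()
    sums = frame.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero-sum sample in feature matrix")
    return frame / sums


# ---------------------------------------------------------------------------


@dataclass
class CvCurve:
    """Cross-validated error across shrinking feature-set sizes."""

    sizes: list  # strictly decreasing feature-set sizes
    cv_error: list  # mean squared error per size (mean over folds × repeats)
    chosen_size: int
    ranked_features: list = field(repr=False)  # importance order, best first


def _halving_sizes(n_features: int) -> list[int]:
    sizes = [n_features]
    while sizes[-1] > 1:
        sizes.append(max(1, sizes[-1] // 2))
    return sizes


def cv_feature_sizes(
    X: pd.DataFrame,
    y,
    regressor=None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    tol: float = 0.05,
) -> CvCurve:
    """rfcv-style feature-size selection.

    Features (rows of ``X``) are ranked by importance from one fit on the
    full data; for each size in a halving schedule the top features are
    evaluated by ``k``-fold CV repeated ``repeats`` times. ``chosen_size``
    is the smallest size whose mean error is within ``tol`` (relative) of
    the minimum.
    """
    y = np.asarray(y, float)
    n_samples = X.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the {n_samples} samples")
    regressor = default_regressor(seed) if regressor is None else regressor
    Xs = X.to_numpy(float).T  # samples × features
    ranker = clone(regressor)
    ranker.fit(Xs, y)
    order = np.argsort(ranker.feature_importances_)[::-1]
    ranked = [X.index[i] for i in order]
    sizes = _halving_sizes(X.shape[0])
    errors = []
    for size in sizes:
        cols = order[:size]
        fold_errors = []
        for rep in range(repeats):
            kf = KFold(n_splits=k, shuffle=True, random_state=seed * repeats + rep)
            for train, test in kf.split(Xs):
                model = clone(regressor)
                model.fit(Xs[np.ix_(train, cols)], y[train])
                pred = model.predict(Xs[np.ix_(test, cols)])
                fold_errors.append(float(np.mean((pred - y[test]) ** 2)))
        errors.append(float(np.mean(fold_errors)))
    best = min(errors)
    chosen = min(s for s, e in zip(sizes, errors) if e <= (1.0 + tol) * best)
    return CvCurve(sizes, errors, chosen, ranked)


@dataclass(frozen=True)
class ModelReport:
    """Held-out evaluation of one biomarker model."""

    taxonomic_rank: str
    n_features_used: int
    train_fraction: float
    accuracy_percent: float  # 100·(1 − MSE_test / Var(y_test))
    seed: int


def train_evaluate(
    X: pd.DataFrame,
    y,
    regressor=None,
    feature_subset=None,
    train_fraction: float = 0.7,
    seed: int = 0,
    rank: str = "zotu",
) -> ModelReport:
    """Random 70/30 split, fit on train, explained-variance accuracy on test."""
    y = np.asarray(y, float)
    regressor = default_regressor(seed) if regressor is None else regressor
    if feature_subset is not None:
        if len(feature_subset) == 0:
            raise ValueError("feature_subset must be nonempty")
        X = X.loc[list(feature_subset)]
    Xs = X.to_numpy(float).T
    n = Xs.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train, test = order[:n_train], order[n_train:]
    if len(test) < 2:
        raise ValueError("test split too small")
    var = float(np.var(y[test]))
    if var == 0:
        raise ValueError("test targets are constant; accuracy undefined")
    model = clone(regressor)
    model.fit(Xs[train], y[train])
    mse = float(np.mean((model.predict(Xs[test]) - y[test]) ** 2))
    return ModelReport(rank, X.shape[0], train_fraction, 100.0 * (1.0 - mse / var), seed)


def compare_ranks(
    table: AbundanceTable,
    annotation: pd.DataFrame,
    y,
    regressor=None,
    ranks=("class", "order", "zotu"),
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> list[ModelReport]:
    """Run feature-size selection + held-out evaluation at each rank."""
    reports = []
    for rank in ranks:
        X = aggregate_rank(table, annotation, rank)
        curve = cv_feature_sizes(X, y, regressor, k=k, repeats=repeats, seed=seed)
        subset = curve.ranked_features[: curve.chosen_size]
        reports.append(
            train_evaluate(X, y, regressor, subset, seed=seed, rank=rank)
        )
    return reports
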