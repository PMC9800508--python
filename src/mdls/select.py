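"""Feature-space reduction: PCA projection, recursive feature elimination,
and a cross-validated sweep over retained feature counts.

The sweep mirrors the experimental protocol: candidate feature counts run
from 5 to 60 in steps of 5, each evaluated with stratified 5-fold
cross-validation, with the reduction refitted inside every training fold so
no information leaks from held-out windows.

Backward elimination removes one feature per iteration, ranking features by
the summed absolute coefficients of linear models (SVM / logistic
regression) or by impurity importance (random forest).  Because single-step
elimination produces nested subsets, one elimination pass per fold serves
every candidate count in the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

DEFAULT_GRID = tuple(range(5, 61, 5))


@dataclass
class SelectionResult:
    method: str  # "pca" or "rfe"
    k: int
    retained: np.ndarray  # feature indices (rfe) or component loadings (pca)
    cv_scores: pd.DataFrame | None = None


def feature_importances(estimator) -> np.ndarray:
    """Per-feature importance: sum of |coef| across linear machines, or tree
    impurity importances."""
    if hasattr(estimator, "coef_"):
        coef = np.atleast_2d(estimator.coef_)
        return np.abs(coef).sum(axis=0)
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_)
    raise ValueError(
        f"estimator {type(estimator).__name__} exposes neither coefficients nor "
        "feature importances; RFE needs one of them"
    )


def pca_reduce(X: np.ndarray, k: int) -> tuple[np.ndarray, PCA, StandardScaler]:
    """Standardize column-wise, then project onto the first ``k`` principal
    components.  Returns (transformed, fitted PCA, fitted scaler)."""
    X = np.asarray(X, dtype=float)
    max_k = min(X.shape)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must lie in [1, {X.shape[1]}], got {k}")
    if k > max_k:
        raise ValueError(
            f"k={k} exceeds the rank bound min(n_samples, n_features)={max_k}"
        )
    scaler = StandardScaler()
    Z = scaler.fit_transform(X)
    pca = PCA(n_components=max_k, svd_solver="full")
    scores = pca.fit_transform(Z)
    return scores[:, :k], pca, scaler

def elimination_order(
    X: np.ndarray,
    y: np.ndarray,
    estimator,
    standardize: bool = True,
    min_features: int = 1,
) -> np.ndarray:
    """Backward-elimination order, one feature per iteration.

    Returns feature indices ordered from first-eliminated to last-surviving;
    the retained set of size ``k >= min_features`` is the last ``k`` entries.
    Elimination stops once ``min_features`` survive (their internal order is
    not ranked further).
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        X = StandardScaler().fit_transform(X)
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > max(1, min_features):
        est = clone(estimator)
        est.fit(X[:, remaining], y)
        imp = feature_importances(est)
        worst = int(np.argmin(imp))  # ties: lowest index, numpy argmin convention
        eliminated.append(remaining.pop(worst))
    eliminated.extend(remaining)
    return np.asarray(eliminated, dtype=int)


def rfe_select(
    X: np.ndarray, y: np.ndarray, k: int, estimator, standardize: bool = True
) -> np.ndarray:
    """Indices of the ``k`` features retained by single-step backward
    elimination, in ascending order."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must lie in [1, {X.shape[1]}], got {k}")
    if k == X.shape[1]:
        return np.arange(X.shape[1])
    order = elimination_order(X, y, estimator, standardize=standardize, min_features=k)
    return np.sort(order[-k:])


def sweep_feature_counts(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    estimators: dict[str, object],
    grid: tuple[int, ...] = DEFAULT_GRID,
    folds: int = 5,
    seed: int = 0,
    rfe_estimators: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy per (classifier, retained feature count).

    For each stratified fold the reduction is fitted on the training split
    only.  PCA components and single-step elimination paths are nested, so
    one fit per fold covers the whole grid.  ``estimators`` maps classifier
    names to unfitted scikit-learn estimators (applied to standardized
    features); ``rfe_estimators`` optionally overrides the model driving the
    elimination ranking (default: the downstream classifier itself).

    Returns a tidy frame: method, classifier, k, mean_score, sd.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if method not in ("pca", "rfe"):
        raise ValueError(f"method must be 'pca' or 'rfe', got {method!r}")
    grid = tuple(sorted(grid))
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if grid[0] < 1 or grid[-1] > X.shape[1]:
        raise ValueError("grid entries must lie within the feature count")
    if folds < 2:
        raise ValueError("need at least 2 folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: dict[tuple[str, int], list[float]] = {
        (name, k): [] for name in estimators for k in grid
    }
    for train_idx, test_idx in skf.split(X, y):
        X_tr, X_te = X[train_idx], X[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        scaler = StandardScaler().fit(X_tr)
        Z_tr, Z_te = scaler.transform(X_tr), scaler.transform(X_te)

        if method == "pca":
            if grid[-1] > min(X.shape[1], len(X_tr)):
                raise ValueError(
                    f"grid max {grid[-1]} exceeds the training-fold rank bound "
                    f"{min(X.shape[1], len(X_tr))}"
                )
            pca = PCA(n_components=min(X.shape[1], len(X_tr)), svd_solver="full")
            P_tr = pca.fit_transform(Z_tr)
            P_te = pca.transform(Z_te)
            for name, est in estimators.items():
                for k in grid:
                    model = clone(est)
                    model.fit(P_tr[:, :k], y_tr)
                    scores[(name, k)].append(float(model.score(P_te[:, :k], y_te)))
        else:
            for name, est in estimators.items():
                ranker = (rfe_estimators or {}).get(name, est)
                order = elimination_order(
                    Z_tr, y_tr, ranker, standardize=False, min_features=grid[0]
                )
                for k in grid:
                    keep = np.sort(order[-k:])
                    model = clone(est)
                    model.fit(Z_tr[:, keep], y_tr)
                    scores[(name, k)].append(float(model.score(Z_te[:, keep], y_te)))

    rows = [
        {
            "method": method,
            "classifier": name,
            "k": k,
            "mean_score": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
        for (name, k), vals in scores.items()
    ]
    return pd.DataFrame(rows).sort_values(["classifier", "k"]).reset_index(drop=True)


def make_planted_features(
    n_samples: int = 300,
    n_informative: int = 3,
    n_noise: int = 57,
    shift: float = 3.0,
    n_classes: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Benchmark design for selection methods: unit-variance Gaussian features
    where informative feature ``i`` is shifted by ``shift`` standard
    deviations for class ``i % n_classes``; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % n_classes
    rng.shuffle(y)
    X = rng.normal(size=(n_samples, n_informative + n_noise))
    for i in range(n_informative):
        X[y == (i % n_classes), i] += shift
    return X, y
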