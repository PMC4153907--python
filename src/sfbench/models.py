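"""Regression models for scoring-function benchmarking.

Two models are provided, mirroring the two philosophies being compared:

* multiple linear regression with intercept (the classical additive
  scoring-function form, generalised to any feature set), and
* a random-forest regressor trained under a fixed protocol: 500 trees per
  forest, one forest per candidate mtry value from 1 to the number of
  features, the winner chosen by lowest RMSE on the out-of-bag (OOB)
  samples, a single random seed for the whole sweep.

The forest keeps its per-tree bootstrap record, so OOB predictions and
permutation variable importance (%IncMSE) can be recomputed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .complexio import FeatureTable

__all__ = [
    "MLRModel",
    "RFModel",
    "ImportanceReport",
    "fit_mlr",
    "fit_rf",
    "predict",
    "permutation_importance",
]


def _as_matrix(features, feature_names=None):
    """Coerce FeatureTable / DataFrame / ndarray to (matrix, names)."""
    if isinstance(features, FeatureTable):
        return features.values, list(features.feature_names)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if feature_names is None:
        feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, list(feature_names)


def _aligned_matrix(features, names: list[str]) -> np.ndarray:
    """Reorder prediction-time features to the training column order, by name."""
    X, got = _as_matrix(features, feature_names=names if not isinstance(
        features, (FeatureTable, pd.DataFrame)) else None)
    if got == names:
        return X
    missing = [n for n in names if n not in got]
    extra = [n for n in got if n not in names]
    if missing or extra:
        raise KeyError(
            f"feature columns do not match training: missing {missing}, "
            f"unknown {extra}"
        )
    order = [got.index(n) for n in names]
    return X[:, order]


@dataclass
class MLRModel:
    """Ordinary least-squares linear model with intercept."""

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    kind: str = "mlr"

    def predict(self, features) -> np.ndarray:
        X = _aligned_matrix(features, self.feature_names)
        return self.intercept + X @ self.coefficients


@dataclass
class RFModel:
    """Regression forest with its bootstrap record and mtry-sweep history.

    ``bootstrap_indices`` has shape (n_trees, n_train); row t lists the
    training rows drawn (with replacement) for tree t.  ``oob_mask`` marks,
    per tree, the training samples that tree never saw.
    """

    feature_names: list[str]
    estimators: list[DecisionTreeRegressor]
    bootstrap_indices: np.ndarray
    oob_mask: np.ndarray  # (n_trees, n_train) bool
    selected_mtry: int
    oob_rmse_by_mtry: dict[int, float]
    seed: int
    n_trees: int
    train_y_range: tuple[float, float]
    kind: str = "rf"

    def predict(self, features) -> np.ndarray:
        X = _aligned_matrix(features, self.feature_names)
        per_tree = np.stack([t.predict(X) for t in self.estimators])
        return per_tree.mean(axis=0)

    def oob_predictions(self, X_train: np.ndarray) -> np.ndarray:
        """Per-sample mean over the trees whose bootstrap excluded it
        (NaN for samples in every bag)."""
        return _oob_predictions(self.estimators, self.oob_mask, X_train)


@dataclass
class ImportanceReport:
    """Permutation variable importance, %IncMSE per feature.

    %IncMSE = 100 * (OOB MSE after permuting the feature - baseline OOB MSE)
    / baseline OOB MSE.  Negative values are possible for noise features.
    """

    incmse: dict[str, float] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.incmse.items(), key=lambda kv: kv[1], reverse=True)

    def top_feature(self) -> str:
        return self.ranked()[0][0]


# ---------------------------------------------------------------------------
# MLR
# ---------------------------------------------------------------------------

def fit_mlr(features, affinities, feature_names=None) -> MLRModel:
    """Ordinary least squares with intercept.

    Raises on a rank-deficient design, naming the offending columns, since a
    collinear scoring-function fit has no interpretable coefficients.
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(affinities, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"affinity vector length {y.shape} does not match {n} rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features and affinities must be finite")
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} samples for MLR, got {n}")

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify columns involved via the small pivots of a QR factorisation
        _, R = np.linalg.qr(design)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[i - 1] if i > 0 else "<intercept>"
               for i in np.nonzero(diag <= tol)[0]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {p + 1}); collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(names, beta[1:], float(beta[0]))


# ---------------------------------------------------------------------------
# RF
# ---------------------------------------------------------------------------

def _tree_seeds(seed: int, n_trees: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_trees) % (2**31 - 1)


def _oob_predictions(estimators, oob_mask: np.ndarray, X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, mask in zip(estimators, oob_mask):
        if mask.any():
            sums[mask] += tree.predict(X[mask])
            counts[mask] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _oob_rmse(pred: np.ndarray, y: np.ndarray) -> float:
    have = np.isfinite(pred)
    if not have.all():
        warnings.warn(
            f"{int((~have).sum())} samples were in every bootstrap and are "
            "excluded from OOB aggregates", stacklevel=3,
        )
    if not have.any():
        return float("nan")
    return float(np.sqrt(np.mean((pred[have] - y[have]) ** 2)))


def fit_rf(
    features,
    affinities,
    n_trees: int = 500,
    seed: int = 0,
    mtry_values=None,
    min_samples_leaf: int = 5,
    feature_names=None,
) -> RFModel:
    """Train a regression forest with OOB-based mtry selection.

    For each candidate mtry (default: every value from 1 to p) an ensemble of
    ``n_trees`` trees is grown on bootstrap samples; the forest with the
    lowest out-of-bag RMSE is returned (ties go to the smallest mtry, i.e.
    the cheaper, more decorrelated forest).  The bootstrap is drawn once from
    ``seed`` and shared across the sweep, so the whole protocol consumes a
    single seed.  Other tree hyperparameters follow classical
    regression-forest defaults (leaf size 5, unlimited depth).
    """
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(affinities, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("no features to train on")
    if y.shape != (n,):
        raise ValueError(f"affinity vector length {y.shape} does not match {n} rows")
    if n < 10:
        raise ValueError(f"need at least 10 training samples, got {n}")

    if mtry_values is None:
        mtry_values = range(1, p + 1)
    mtry_values = sorted({int(m) for m in mtry_values})
    if any(m < 1 or m > p for m in mtry_values):
        raise ValueError(f"mtry values must lie in [1, {p}]")

    rng = np.random.default_rng(seed)
    bootstrap = rng.integers(0, n, size=(n_trees, n))
    oob_mask = np.ones((n_trees, n), dtype=bool)
    for t in range(n_trees):
        oob_mask[t, bootstrap[t]] = False
    seeds = _tree_seeds(seed, n_trees)

    best: tuple[float, int, list] | None = None
    oob_rmse_by_mtry: dict[int, float] = {}
    for mtry in mtry_values:
        estimators = []
        for t in range(n_trees):
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=min_samples_leaf,
                random_state=int(seeds[t]),
            )
            idx = bootstrap[t]
            tree.fit(X[idx], y[idx])
            estimators.append(tree)
        rmse = _oob_rmse(_oob_predictions(estimators, oob_mask, X), y)
        oob_rmse_by_mtry[mtry] = rmse
        # strict '<' keeps the smallest mtry on ties
        if best is None or rmse < best[0]:
            best = (rmse, mtry, estimators)

    _, selected_mtry, estimators = best
    return RFModel(
        feature_names=names,
        estimators=estimators,
        bootstrap_indices=bootstrap,
        oob_mask=oob_mask,
        selected_mtry=selected_mtry,
        oob_rmse_by_mtry=oob_rmse_by_mtry,
        seed=seed,
        n_trees=n_trees,
        train_y_range=(float(y.min()), float(y.max())),
    )


def predict(model, features) -> np.ndarray:
    """Apply a trained model; feature columns are matched by name."""
    return model.predict(features)


def permutation_importance(
    model: RFModel,
    features,
    affinities,
    seed: int = 0,
    permutation: str = "random",
) -> ImportanceReport:
    """Permutation variable importance (%IncMSE) from the stored OOB record.

    For each feature, its values are shuffled among each tree's out-of-bag
    samples (one permutation per feature per tree), tree predictions are
    re-aggregated into forest-level OOB predictions, and the report gives the
    percent increase of the OOB mean squared error over the unpermuted
    baseline.  ``permutation="identity"`` is a test hook that applies the
    identity rearrangement and must yield exactly zero.
    """
    if not isinstance(model, RFModel):
        raise TypeError("permutation importance is defined for RF models only")
    if permutation not in ("random", "identity"):
        raise ValueError("permutation must be 'random' or 'identity'")
    X = _aligned_matrix(features, model.feature_names)
    y = np.asarray(affinities, dtype=float)
    n = X.shape[0]
    if model.oob_mask.shape[1] != n:
        raise ValueError("features/affinities do not match the training set size")

    base_pred = _oob_predictions(model.estimators, model.oob_mask, X)
    have = np.isfinite(base_pred)
    base_mse = float(np.mean((base_pred[have] - y[have]) ** 2))

    rng = np.random.default_rng(seed)
    report: dict[str, float] = {}
    for j, name in enumerate(model.feature_names):
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, mask in zip(model.estimators, model.oob_mask):
            oob_idx = np.nonzero(mask)[0]
            if oob_idx.size == 0:
                continue
            Xp = X[oob_idx].copy()
            if permutation == "random":
                Xp[:, j] = Xp[rng.permutation(oob_idx.size), j]
            sums[oob_idx] += tree.predict(Xp)
            counts[oob_idx] += 1
        perm_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        perm_mse = float(np.mean((perm_pred[have] - y[have]) ** 2))
        report[name] = 100.0 * (perm_mse - base_mse) / base_mse
    return ImportanceReport(report)
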