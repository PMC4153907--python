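"""Evaluation machinery: metrics, deterministic partitioning, and the three
validation regimes (held-out learning curves, round-robin k-fold cross
validation, leave-cluster-out cross validation).

Metrics per test set: RMSE and the three linear-transform-invariant
quantities SD (residual standard error of regressing measured on predicted),
Pearson Rp and Spearman Rs, optionally Kendall Rk.  All affinities are in
pKd/pKi units.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complexio import AffinityRecord, AffinityTable, FeatureTable
from .models import fit_mlr, fit_rf

__all__ = [
    "MetricsReport",
    "PartitionAssignment",
    "ClusterAssignment",
    "ModelSpec",
    "compute_metrics",
    "round_robin_partition",
    "run_crossval",
    "lcocv_group",
    "run_lcocv",
    "learning_curve",
]

_METRIC_COLUMNS = ("rmse", "sd", "rp", "rs")


@dataclass(frozen=True)
class MetricsReport:
    """Test-set performance of one model on one test set."""

    rmse: float
    sd: float
    rp: float
    rs: float
    n: int
    rk: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"rmse": self.rmse, "sd": self.sd, "rp": self.rp, "rs": self.rs, "n": self.n}
        if self.rk is not None:
            d["rk"] = self.rk
        return d


@dataclass
class PartitionAssignment:
    """complex_id -> fold index in {1..k}."""

    assignment: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(1, self.k + 1)):
            raise ValueError(f"fold indices must lie in 1..{self.k}, got {sorted(folds)}")
        sizes = self.fold_sizes()
        if sizes and max(sizes.values()) - min(sizes.values()) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    def fold_sizes(self) -> dict[int, int]:
        sizes = {f: 0 for f in range(1, self.k + 1)}
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]

    def merged_ids(self, folds: Sequence[int]) -> list[str]:
        wanted = set(folds)
        return [cid for cid, f in self.assignment.items() if f in wanted]


@dataclass
class ClusterAssignment:
    """complex -> protein family -> cluster label (A..W individual families,
    X = families of 4-9 complexes, Y = 2-3, Z = singletons)."""

    complex_to_cluster: dict[str, str]
    family_to_cluster: dict[str, str]

    def clusters(self) -> list[str]:
        return sorted(set(self.complex_to_cluster.values()))

    def cluster_ids(self, label: str) -> list[str]:
        return [cid for cid, c in self.complex_to_cluster.items() if c == label]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    measured,
    predicted,
    kendall: bool = False,
    sd_denominator: str = "n-2",
) -> MetricsReport:
    """Compute RMSE, SD, Rp, Rs (optionally Rk) between measured and
    predicted affinities.

    SD is the residual standard error of the simple linear regression of
    measured on predicted (denominator N-2 by default; ``sd_denominator
    ="n-1"`` is available for comparison with studies using that convention).
    Spearman uses average ranks on ties; Kendall is tau-b.  If either vector
    is constant the correlations are undefined and reported as NaN with a
    warning rather than raising.
    """
    y = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("measured and predicted must be 1-D vectors of equal length")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 test samples, got {n}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(p))):
        raise ValueError("measured and predicted must be finite")
    if sd_denominator not in ("n-2", "n-1"):
        raise ValueError("sd_denominator must be 'n-2' or 'n-1'")
    ddof = 2 if sd_denominator == "n-2" else 1

    rmse = float(np.sqrt(np.mean((y - p) ** 2)))

    if np.ptp(p) == 0.0:
        # degenerate regressor: fitted values collapse to the mean of y
        fitted = np.full(n, y.mean())
    else:
        slope, intercept = np.polyfit(p, y, 1)
        fitted = intercept + slope * p
    sd = float(np.sqrt(np.sum((y - fitted) ** 2) / (n - ddof)))

    if np.ptp(y) == 0.0 or np.ptp(p) == 0.0:
        warnings.warn(
            "constant measured or predicted vector: correlations undefined (NaN)",
            stacklevel=2,
        )
        rp = rs = rk = float("nan")
    else:
        rp = float(stats.pearsonr(y, p).statistic)
        rs = float(stats.spearmanr(y, p).statistic)
        rk = float(stats.kendalltau(y, p).statistic) if kendall else None
    return MetricsReport(rmse=rmse, sd=sd, rp=rp, rs=rs, n=n,
                         rk=rk if kendall else None)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def round_robin_partition(
    affinities: Sequence[AffinityRecord] | AffinityTable, k: int = 5
) -> PartitionAssignment:
    """Deterministic affinity-stratified k-fold split.

    Records are sorted in ascending order of affinity (ties broken by
    complex_id, ascending) and dealt out cyclically: the 1st, (k+1)th,
    (2k+1)th ... lowest-affinity complexes form fold 1, the 2nd, (k+2)th ...
    form fold 2, and so on.  Every fold therefore spans nearly the full
    affinity range.
    """
    records = affinities.records if isinstance(affinities, AffinityTable) else list(affinities)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    ordered = sorted(records, key=lambda r: (r.affinity, r.complex_id))
    assignment = {r.complex_id: (i % k) + 1 for i, r in enumerate(ordered)}
    if len(assignment) != len(records):
        raise ValueError("duplicate complex ids in affinity records")
    return PartitionAssignment(assignment, k)


def lcocv_group(family_labels: Mapping[str, str]) -> ClusterAssignment:
    """Group protein families into leave-cluster-out clusters.

    Families with >= 10 complexes become individual clusters labelled A, B,
    ... in order of descending size (ties broken by family name); smaller
    families are pooled: size 4-9 -> X, 2-3 -> Y, singletons -> Z.  More than
    23 individual families exhausts the letter space A..W and is an error.
    """
    if not family_labels:
        raise ValueError("no family labels given")
    sizes: dict[str, int] = {}
    for fam in family_labels.values():
        sizes[fam] = sizes.get(fam, 0) + 1
    big = sorted((f for f, s in sizes.items() if s >= 10),
                 key=lambda f: (-sizes[f], f))
    letters = string.ascii_uppercase[:23]  # A..W
    if len(big) > len(letters):
        raise ValueError(
            f"{len(big)} families with >= 10 complexes exceed the 23 cluster "
            "letters A..W; relabel or merge families"
        )
    family_to_cluster = {f: letters[i] for i, f in enumerate(big)}
    for fam, s in sizes.items():
        if s >= 10:
            continue
        family_to_cluster[fam] = "X" if s >= 4 else ("Y" if s >= 2 else "Z")
    complex_to_cluster = {cid: family_to_cluster[f] for cid, f in family_labels.items()}
    return ClusterAssignment(complex_to_cluster, family_to_cluster)


# ---------------------------------------------------------------------------
# model specification shared by the harnesses
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit in a harness: model kind plus an optional feature-column
    subset (e.g. only the cyscore block) and RF hyperparameters."""

    kind: str  # "mlr" | "rf"
    columns: Sequence[str] | None = None
    n_trees: int = 500
    mtry_values: Sequence[int] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mlr", "rf"):
            raise ValueError(f"model kind must be 'mlr' or 'rf', got {self.kind!r}")
        if self.name is None:
            self.name = self.kind

    def fit(self, features: FeatureTable, y: np.ndarray, seed: int):
        table = features.subset_columns(self.columns) if self.columns else features
        if self.kind == "mlr":
            return fit_mlr(table, y)
        return fit_rf(table, y, n_trees=self.n_trees, seed=seed,
                      mtry_values=self.mtry_values)


def _check_no_leakage(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test leakage: {sorted(overlap)[:10]}")


def _fit_and_score(
    features: FeatureTable,
    aff_by_id: Mapping[str, float],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    model_spec: ModelSpec,
    seed: int,
    kendall: bool = False,
) -> MetricsReport:
    _check_no_leakage(train_ids, test_ids)
    y_train = np.array([aff_by_id[c] for c in train_ids])
    y_test = np.array([aff_by_id[c] for c in test_ids])
    model = model_spec.fit(features.subset_rows(train_ids), y_train, seed)
    test_table = features.subset_rows(test_ids)
    if model_spec.columns:
        test_table = test_table.subset_columns(model_spec.columns)
    pred = model.predict(test_table)
    return compute_metrics(y_test, pred, kendall=kendall)


# ---------------------------------------------------------------------------
# harnesses
# ---------------------------------------------------------------------------

def run_crossval(
    features: FeatureTable,
    affinities: AffinityTable,
    partition: PartitionAssignment,
    model_spec: ModelSpec,
    seed: int = 0,
    kendall: bool = False,
) -> pd.DataFrame:
    """k-fold cross validation over a partition: each fold is tested once
    with the model trained on the other k-1 folds.

    Returns a DataFrame indexed by fold number plus an ``avg`` row holding
    the unweighted mean of each metric over folds.
    """
    aff = {r.complex_id: r.affinity for r in affinities.records}
    rows = {}
    for fold in range(1, partition.k + 1):
        test_ids = partition.fold_ids(fold)
        if len(test_ids) < 3:
            raise ValueError(f"fold {fold} has fewer than 3 test samples")
        train_ids = partition.merged_ids([f for f in range(1, partition.k + 1)
                                          if f != fold])
        report = _fit_and_score(features, aff, train_ids, test_ids,
                                model_spec, seed, kendall)
        rows[fold] = report.as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    avg = df.drop(columns="n").mean(skipna=True)
    avg["n"] = df["n"].sum()
    df.loc["avg"] = avg
    return df


def run_lcocv(
    features: FeatureTable,
    affinities: AffinityTable,
    clusters: ClusterAssignment,
    model_spec: ModelSpec,
    seed: int = 0,
    kendall: bool = False,
) -> pd.DataFrame:
    """Leave-cluster-out cross validation: each cluster is held out in turn
    and scored with the model trained on all other clusters.

    Returns a DataFrame indexed by cluster label plus ``avg`` and ``sd``
    summary rows (unweighted mean and sample standard deviation over
    clusters; NaN metrics from degenerate clusters are excluded, and the
    number of such exclusions is recorded in ``df.attrs['n_nan_excluded']``).
    """
    labels = clusters.clusters()
    if len(labels) < 2:
        raise ValueError("LCOCV needs at least 2 clusters")
    aff = {r.complex_id: r.affinity for r in affinities.records}
    all_ids = set(clusters.complex_to_cluster)
    rows = {}
    for label in labels:
        test_ids = clusters.cluster_ids(label)
        if set(test_ids) == all_ids:
            raise ValueError(f"cluster {label} is the whole data set")
        train_ids = sorted(all_ids - set(test_ids))
        rows[label] = _fit_and_score(features, aff, train_ids, test_ids,
                                     model_spec, seed, kendall).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    body = df.drop(columns="n")
    df.attrs["n_nan_excluded"] = int(body.isna().sum().sum())
    avg = body.mean(skipna=True)
    sd = body.std(ddof=1, skipna=True)
    avg["n"] = df["n"].sum()
    sd["n"] = math.nan
    df.loc["avg"] = avg
    df.loc["sd"] = sd
    return df


def learning_curve(
    features: FeatureTable,
    affinities: AffinityTable,
    nested_training_sets: Sequence[Sequence[str]],
    test_set: Sequence[str],
    model_specs: Sequence[ModelSpec],
    seed: int = 0,
    kendall: bool = False,
) -> pd.DataFrame:
    """Evaluate models on one fixed test set at incremental training sizes.

    ``nested_training_sets`` must be nested (each set a superset of the
    previous) and disjoint from the test set.  Returns a tidy DataFrame with
    one row per (model, training size).
    """
    test_ids = list(test_set)
    prev: set[str] = set()
    for i, ids in enumerate(nested_training_sets):
        s = set(ids)
        if not prev <= s:
            raise ValueError(f"training set {i + 1} is not a superset of set {i}")
        _check_no_leakage(ids, test_ids)
        prev = s
    aff = {r.complex_id: r.affinity for r in affinities.records}
    rows = []
    for spec in model_specs:
        for ids in nested_training_sets:
            report = _fit_and_score(features, aff, list(ids), test_ids,
                                    spec, seed, kendall)
            rows.append({"model": spec.name, "n_train": len(ids),
                         **report.as_dict()})
    return pd.DataFrame(rows)
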