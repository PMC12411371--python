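"""Reproducibility-threshold experiment: partition, model, evaluate, sweep.

The experiment asks whether features that are concordant between replicate
measurements (CCC above a threshold theta) are also the predictive ones.
Per repeat: compute per-feature CCC from the two training replicates,
split features into reproducible (CCC > theta, strict) and nonreproducible
sets, then train a LASSO-selected random-forest classifier on each of
{all, reproducible, nonreproducible} and score it on held-out data with
AUC, AUPRC, F1, sensitivity and specificity (the last three at the
Youden-optimal ROC point). Sweeping theta over a grid with repeated
splits yields mean +/- CI curves per feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from ._seeds import derive_seed
from .concordance import MeanCI, ccc_per_feature, mean_ci
from .synthetic import GeneratorConfig, ReplicateStudy, generate

logger = logging.getLogger(__name__)

#: Default threshold grid: 0.60 to 0.95 in steps of 0.05.
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.60, 0.96, 0.05), 2))

FEATURE_SETS = ("all", "reproducible", "nonreproducible")
METRICS = ("auc", "auprc", "f1", "sensitivity", "specificity", "n_selected")


class EmptyPartitionError(ValueError):
    """Raised when a model is requested on an empty feature set."""


@dataclass(frozen=True)
class FeaturePartition:
    """Feature names split at a CCC threshold (strict CCC > threshold)."""

    threshold: float
    reproducible: frozenset[str]
    nonreproducible: frozenset[str]
    n_undefined: int


@dataclass(frozen=True)
class ModelSpec:
    """LASSO selection + random-forest hyperparameters."""

    lasso_cv_folds: int = 5
    lasso_grid_size: int = 50
    rf_n_trees: int = 100
    inner_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lasso_cv_folds, self.lasso_grid_size, self.rf_n_trees) < 1:
            raise ValueError("all ModelSpec counts must be >= 1")


@dataclass(frozen=True)
class MetricRecord:
    auc: float
    auprc: float
    f1: float
    sensitivity: float
    specificity: float
    n_selected: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"auc": self.auc, "auprc": self.auprc, "f1": self.f1,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "n_selected": float(self.n_selected)}


def partition_features(ccc: pd.Series, threshold: float) -> FeaturePartition:
    """Split features at a CCC threshold; reproducible iff CCC strictly > theta.

    Features with an undefined (NaN) CCC join neither side and are counted.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    defined = ccc.dropna()
    repro = frozenset(defined.index[defined > threshold])
    nonrepro = frozenset(defined.index[defined <= threshold])
    return FeaturePartition(threshold=float(threshold), reproducible=repro,
                            nonreproducible=nonrepro,
                            n_undefined=int(ccc.isna().sum()))


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of samples")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; need both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return y


def select_features_lasso(X: pd.DataFrame, y, spec: ModelSpec) -> list[str]:
    """L1-penalized logistic feature selection on standardized features.

    The penalty is chosen by stratified cross-validation (AUC scoring) over
    a logarithmic grid of ``lasso_grid_size`` points; features with nonzero
    coefficients are returned ordered by decreasing |coefficient|. If no
    coefficient survives, falls back to the single largest-|coefficient|
    feature at the smallest grid penalty yielding any nonzero coefficient.
    Constant features are dropped up front.
    """
    y = _validate_xy(X, y)
    keep = X.columns[X.std(axis=0, ddof=0) > 0]
    dropped = set(X.columns) - set(keep)
    if dropped:
        logger.info("select_features_lasso: dropping %d constant features", len(dropped))
    if len(keep) == 0:
        raise ValueError("all candidate features are constant; nothing to select")
    X = X[keep]

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    Cs = np.logspace(-4, 4, spec.lasso_grid_size)
    n_splits = min(spec.lasso_cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.inner_seed)
    model = LogisticRegressionCV(Cs=Cs, cv=cv, l1_ratios=[1.0], solver="liblinear",
                                 scoring="roc_auc", max_iter=2000,
                                 random_state=spec.inner_seed,
                                 use_legacy_attributes=False)
    model.fit(Xs, y)
    coef = model.coef_.ravel()
    nonzero = np.flatnonzero(coef != 0.0)
    if nonzero.size:
        order = nonzero[np.argsort(-np.abs(coef[nonzero]), kind="stable")]
        return [str(keep[j]) for j in order]

    # Fallback: walk penalties from weakest upward; the first (smallest)
    # penalty giving any nonzero coefficient defines the single feature kept.
    logger.info("select_features_lasso: zero features at CV optimum; using fallback")
    for C in sorted(Cs, reverse=True):
        lr = LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear",
                                max_iter=2000, random_state=spec.inner_seed)
        lr.fit(Xs, y)
        c = lr.coef_.ravel()
        if np.any(c != 0.0):
            return [str(keep[int(np.argmax(np.abs(c)))])]
    raise ValueError("no penalty in the grid yields a nonzero coefficient")


def compute_metrics(scores, labels) -> MetricRecord:
    """Threshold-free and Youden-point metrics for one scored test set.

    AUC is the trapezoidal area under the empirical ROC, AUPRC the
    step-wise precision-recall summation. Sensitivity, specificity and F1
    are evaluated at the ROC point maximizing Youden's J = sens + spec - 1,
    ties broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; metrics undefined")

    auc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    idx = best[np.argmax(tpr[best])]
    preds = (scores >= thresholds[idx]).astype(int)
    return MetricRecord(
        auc=auc, auprc=auprc,
        f1=float(f1_score(labels, preds, zero_division=0)),
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
    )


def fit_evaluate(train_X: pd.DataFrame, y, test_X: pd.DataFrame, y_test,
                 feature_names, spec: ModelSpec) -> MetricRecord:
    """LASSO-select on the training table, fit a seeded random forest on the
    selected features, and score the test table.

    ``feature_names`` restricts both tables before selection; an empty set
    raises :class:`EmptyPartitionError` so callers can record the repeat as
    missing rather than dropping it.
    """
    names = sorted(feature_names)
    if not names:
        raise EmptyPartitionError("empty feature set; nothing to model")
    missing = [f for f in names if f not in train_X.columns or f not in test_X.columns]
    if missing:
        raise ValueError(f"features absent from the tables: {missing[:5]}")
    selected = select_features_lasso(train_X[names], y, spec)
    rf = RandomForestClassifier(n_estimators=spec.rf_n_trees,
                                random_state=spec.inner_seed)
    rf.fit(train_X[selected], np.asarray(y))
    scores = rf.predict_proba(test_X[selected])[:, 1]
    rec = compute_metrics(scores, y_test)
    return replace(rec, n_selected=len(selected))


def _split_fixed_study(study: ReplicateStudy, split_fraction: float, seed: int):
    """Stratified re-split of a fixed study's training samples.

    The training samples carry both replicates, so the CCC remains
    computable on the repeat-level training fold; the repeat-level test
    fold is scored on replicate-1 values (a single measurement).
    """
    y = study.train_labels.to_numpy()
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=split_fraction,
                                      random_state=seed)
    tr, te = next(splitter.split(np.zeros(y.size), y))
    return (study.train_rep1.iloc[tr], study.train_rep2.iloc[tr],
            study.train_labels.iloc[tr],
            study.train_rep1.iloc[te], study.train_labels.iloc[te])


def run_experiment(study_source, grid=DEFAULT_GRID, repeats: int = 100,
                   spec: ModelSpec = ModelSpec(), split_fraction: float = 2 / 3,
                   seed: int | None = None) -> pd.DataFrame:
    """Full threshold-sweep experiment, long-format result table.

    ``study_source`` is either a :class:`GeneratorConfig` (a fresh study is
    generated per repeat under derived seeds) or a fixed
    :class:`ReplicateStudy` (its training samples are stratified-re-split
    per repeat at ``split_fraction``). Output columns:
    repeat, threshold, feature_set, metric, value. Rows for an empty
    partition side carry NaN values; `all`-features rows are computed once
    per repeat and replicated across thresholds for tidy plotting.
    """
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError(f"grid values must lie in [0, 1], got {grid}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    generated = isinstance(study_source, GeneratorConfig)
    if not generated and not isinstance(study_source, ReplicateStudy):
        raise TypeError("study_source must be a GeneratorConfig or a ReplicateStudy")
    root = (study_source.seed if generated else 0) if seed is None else seed

    rows: list[dict] = []

    def record(rep: int, theta: float, fset: str, rec: MetricRecord | None):
        vals = rec.as_dict() if rec is not None else {m: np.nan for m in METRICS}
        for metric in METRICS:
            rows.append({"repeat": rep, "threshold": theta, "feature_set": fset,
                         "metric": metric, "value": vals[metric]})

    for rep in range(repeats):
        if generated:
            cfg = replace(study_source, seed=derive_seed(root, "study", rep))
            study = generate(cfg)
            x1, x2 = study.train_rep1, study.train_rep2
            y_tr = study.train_labels
            x_te, y_te = study.test_features, study.test_labels
        else:
            x1, x2, y_tr, x_te, y_te = _split_fixed_study(
                study_source, split_fraction, derive_seed(root, "split", rep))

        ccc_vec = ccc_per_feature(x1, x2)
        all_rec = fit_evaluate(
            x1, y_tr, x_te, y_te, list(x1.columns),
            replace(spec, inner_seed=derive_seed(root, "model", rep, "all")))

        side_cache: dict[frozenset, MetricRecord | None] = {}
        for theta in grid:
            part = partition_features(ccc_vec, theta)
            record(rep, theta, "all", all_rec)
            for fset, names in (("reproducible", part.reproducible),
                                ("nonreproducible", part.nonreproducible)):
                if names in side_cache:
                    record(rep, theta, fset, side_cache[names])
                    continue
                if not names:
                    logger.info("repeat %d theta %.2f: %s side empty", rep, theta, fset)
                    rec = None
                else:
                    rec = fit_evaluate(
                        x1, y_tr, x_te, y_te, names,
                        replace(spec, inner_seed=derive_seed(root, "model", rep, fset)))
                side_cache[names] = rec
                record(rep, theta, fset, rec)
    return pd.DataFrame(rows)


def summarize(result: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Aggregate an experiment table to mean +/- CI per (threshold,
    feature_set, metric) group, counting missing (empty-partition) repeats.
    """
    if result.empty:
        raise ValueError("experiment result is empty")
    rows = []
    grouped = result.groupby(["metric", "feature_set", "threshold"], sort=True)
    for (metric, fset, theta), g in grouped:
        vals = g["value"].dropna().to_numpy()
        n_missing = int(g["value"].isna().sum())
        if vals.size == 0:
            ci = MeanCI(mean=np.nan, lo=np.nan, hi=np.nan, k=0)
        else:
            ci = mean_ci(vals, level=level)
        rows.append({"threshold": theta, "feature_set": fset, "metric": metric,
                     "mean": ci.mean, "ci_lo": ci.lo, "ci_hi": ci.hi,
                     "k": ci.k, "n_missing": n_missing})
    return pd.DataFrame(rows)
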