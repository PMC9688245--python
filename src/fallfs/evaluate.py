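"""Classifiers, repeated stratified cross-validation, metrics, permutation test.

Four model families are evaluated: Gaussian naive Bayes (``gnb``), a CART
decision tree (``dt``), k-nearest neighbors (``knn``) and an RBF-kernel
support vector machine (``svm``). Hyperparameters are tuned by exhaustive
grid search with stratified 5-fold CV on mean F1 (positive class = faller);
ties go to the simpler candidate, where each family's grid is enumerated
simplest first (shallower/larger-leaf trees, larger-k/uniform/euclidean kNN,
smaller C and gamma SVMs).

Performance is reported as mean +/- SD of F1, recall, precision, specificity
and Cohen's kappa over 10 repetitions of stratified 5-fold CV: within each
repetition the out-of-fold predictions are pooled and scored once, and the
spread is taken across repetitions. Significance against random guessing
comes from a label-permutation test with the add-one rule
``p = (1 + #(null >= observed)) / (n_permutations + 1)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("gnb", "dt", "knn", "svm")
METRICS = ("f1", "recall", "precision", "specificity", "kappa")


@dataclass
class MetricSet:
    f1: float
    recall: float
    precision: float
    specificity: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def compute_metrics(y_true, y_pred) -> MetricSet:
    """Confusion-matrix metrics for the positive (faller) class.

    Zero-denominator ratios are returned as 0 with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fp + fn + tn

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning 0", stacklevel=3)
            return 0.0
        return num / den

    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if p_e == 1.0:
        warnings.warn("kappa undefined (p_e = 1); returning 0", stacklevel=2)
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return MetricSet(f1, recall, precision, specificity, kappa)


def hyper_grid(family: str) -> list[dict]:
    """Exhaustive hyperparameter grid, enumerated simplest candidate first."""
    if family == "gnb":
        return [{}]
    if family == "dt":
        # shallower trees with larger leaves are simpler
        return [
            {"criterion": c, "max_depth": d, "min_samples_leaf": leaf}
            for d in range(2, 11)
            for leaf in range(30, 4, -1)
            for c in ("gini", "entropy")
        ]
    if family == "knn":
        # more neighbors smooth more -> simpler; uniform/euclidean first
        return [
            {"n_neighbors": k, "weights": w, "metric": m}
            for k in range(10, 1, -1)
            for w in ("uniform", "distance")
            for m in ("euclidean", "manhattan")
        ]
    if family == "svm":
        return [
            {"C": c, "gamma": g}
            for c in (0.1, 1.0, 10.0, 100.0)
            for g in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
        ]
    raise ValueError(f"unknown model family {family!r}")


def build_model(family: str, params: dict, seed: int | None = None):
    if family == "gnb":
        return GaussianNB()
    if family == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "svm":
        return SVC(kernel="rbf", **params)
    raise ValueError(f"unknown model family {family!r}")


def _fold_f1(y_true, y_pred) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_metrics(y_true, y_pred).f1


def grid_search_cv(family: str, X, y, folds: int = 5, seed: int = 0, preprocessor=None) -> tuple[dict, float]:
    """Best hyperparameters by mean fold F1 over one stratified k-fold split.

    Ties keep the earlier (simpler) candidate; identical folds are reused for
    every candidate so the comparison is paired.
    """
    y = np.asarray(y, dtype=int)
    _check_stratifiable(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    fold_data = [_fold_arrays(X, y, tr, te, preprocessor) for tr, te in splits]

    best_params, best_score = None, -np.inf
    for params in hyper_grid(family):
        scores = []
        for Xtr, ytr, Xte, yte in fold_data:
            model = build_model(family, params, seed)
            model.fit(Xtr, ytr)
            scores.append(_fold_f1(yte, model.predict(Xte)))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_params, best_score = params, score
        elif abs(score - best_score) <= 1e-12:
            logger.debug("grid tie at F1=%.6f; keeping simpler candidate %r", best_score, best_params)
    return best_params, best_score


@dataclass
class CVReport:
    """Mean +/- SD of each metric over the CV repetitions."""

    means: dict[str, float]
    sds: dict[str, float]
    family: str
    params: dict
    n_features: int
    repetitions: int
    p_value: float | None = None
    per_repetition: list[MetricSet] = field(default_factory=list)


def _check_stratifiable(y: np.ndarray, folds: int) -> None:
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"class too small to stratify: counts {counts.tolist()} with {folds} folds"
        )


def _fold_arrays(X, y, tr, te, preprocessor):
    if preprocessor is not None:
        prep = preprocessor.fit(tr)
        return prep.transform(tr), y[tr], prep.transform(te), y[te]
    X = np.asarray(X, dtype=float)
    return X[tr], y[tr], X[te], y[te]


def repeated_cv_evaluate(
    family: str,
    params: dict,
    X,
    y,
    repetitions: int = 10,
    folds: int = 5,
    seed: int = 0,
    vary_folds: bool = True,
    preprocessor=None,
) -> CVReport:
    """Repeated stratified k-fold evaluation.

    Each repetition draws a fresh fold assignment from ``seed + r``
    (``vary_folds=False`` reuses the same split, useful for isolating model
    stochasticity), pools the out-of-fold predictions, and computes the metric
    set once; the report gives mean and sample SD across repetitions.
    """
    y = np.asarray(y, dtype=int)
    _check_stratifiable(y, folds)
    n_features = X.shape[1] if hasattr(X, "shape") else len(X.features)
    per_rep: list[MetricSet] = []
    for r in range(repetitions):
        fold_seed = seed + (r if vary_folds else 0)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        pred = np.empty(len(y), dtype=int)
        for tr, te in skf.split(np.zeros(len(y)), y):
            Xtr, ytr, Xte, _ = _fold_arrays(X, y, tr, te, preprocessor)
            model = build_model(family, params, seed)
            model.fit(Xtr, ytr)
            pred[te] = model.predict(Xte)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_rep.append(compute_metrics(y, pred))
    means = {m: float(np.mean([getattr(ms, m) for ms in per_rep])) for m in METRICS}
    ddof = 1 if repetitions > 1 else 0
    sds = {m: float(np.std([getattr(ms, m) for ms in per_rep], ddof=ddof)) for m in METRICS}
    return CVReport(means, sds, family, params, n_features, repetitions, per_repetition=per_rep)


@dataclass
class PermutationResult:
    observed: float
    null_scores: np.ndarray
    p_value: float
    n_permutations: int


def permutation_test(evaluator, X, y, n_permutations: int = 1000, seed: int = 0) -> PermutationResult:
    """Label-permutation null for a scalar CV score.

    ``evaluator(X, y) -> float`` is re-run on uniformly permuted labels;
    ``p = (1 + #(null >= observed)) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y, dtype=int)
    observed = float(evaluator(X, y))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = evaluator(X, rng.permutation(y))
    p = (1.0 + float(np.sum(null >= observed))) / (n_permutations + 1.0)
    return PermutationResult(observed, null, p, n_permutations)
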