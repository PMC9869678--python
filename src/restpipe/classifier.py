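"""RBF-SVM classification of patients vs controls.

Pipeline per feature family: stratified 80:20 split, per-feature min-max
rescaling fitted on training rows, nested stratified 5-fold grid search
over the printed C/gamma grids with balanced class weights, then two
evaluations: repeated stratified 5-fold CV over the full table (primary
report) and the single hold-out test set.  All metrics are percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .core import derive_seed
from .group_stats import feature_columns

logger = logging.getLogger(__name__)

C_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3, 1e4)
GAMMA_GRID = (1.0, 0.1, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class HyperGrid:
    C: tuple = C_GRID
    gamma: tuple = GAMMA_GRID


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float
    seed: int


@dataclass
class ClassifierReport:
    """Metrics (percent) plus the chosen hyperparameters.

    ``cv`` holds the repeated stratified 5-fold evaluation over the full
    table (the primary numbers); ``holdout`` the single 80:20 test-set
    evaluation.  Top-level attributes mirror ``cv``.
    """

    family: str
    C: float
    gamma: float
    cv: dict = field(default_factory=dict)
    holdout: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0

    def __getattr__(self, name):
        cv = object.__getattribute__(self, "cv")
        if name in cv:
            return cv[name]
        raise AttributeError(name)


def make_split(labels, ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified train/test split preserving class proportions."""
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, train_size=ratio, stratify=y, random_state=seed
    )
    return SplitPlan(np.sort(train), np.sort(test), ratio, seed)


class MinMaxRescaler:
    """Per-feature (x - min)/(max - min) with ranges from the training rows.

    Zero-range features map to 0 (with a warning); values outside the
    training range are NOT clipped.
    """

    def fit(self, X: np.ndarray) -> "MinMaxRescaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        zero = rng == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-range feature(s) mapped to 0",
                stacklevel=2,
            )
        self.scale_ = np.where(zero, np.inf, rng)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.min_) / self.scale_


def minmax_rescale(train: np.ndarray, apply_to: np.ndarray):
    """Functional form: returns (scaled train, scaled other, fitted scaler)."""
    scaler = MinMaxRescaler().fit(train)
    return scaler.transform(train), scaler.transform(apply_to), scaler


def _svc(C: float, gamma: float) -> SVC:
    return SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced")


def nested_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid = HyperGrid(),
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean inner-fold validation AUC per grid point; argmax (C, gamma).

    Ties break toward smaller C, then smaller gamma.  Scaling is fitted on
    each inner training fold (no leakage into validation folds).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < inner_folds:
        raise ValueError(
            f"need >= {inner_folds} subjects per class for {inner_folds}-fold "
            f"inner CV, got {dict(zip(classes, counts))}"
        )
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (-np.inf, None, None)
    for C in sorted(grid.C):
        for gamma in sorted(grid.gamma):
            aucs = []
            for tr, va in folds:
                assert len(np.unique(y[va])) == 2, "degenerate inner fold"
                Xtr, Xva, _ = minmax_rescale(X[tr], X[va])
                clf = _svc(C, gamma).fit(Xtr, y[tr])
                aucs.append(roc_auc_score(y[va], clf.decision_function(Xva)))
            score = float(np.mean(aucs))
            if score > best[0]:
                best = (score, C, gamma)
    return best[1], best[2], best[0]


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity/PPV/NPV/balanced accuracy, in percent.

    Undefined ratios (zero denominators) come back as NaN.
    """

    def ratio(a, b):
        return 100.0 * a / (a + b) if (a + b) > 0 else np.nan

    sens = ratio(tp, fn)
    spec = ratio(tn, fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(tp, fp),
        "npv": ratio(tn, fn),
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def _fold_metrics(clf, Xva, yva) -> dict:
    scores = clf.decision_function(Xva)
    pred = (scores > 0).astype(int)
    tp = int(((pred == 1) & (yva == 1)).sum())
    fn = int(((pred == 0) & (yva == 1)).sum())
    tn = int(((pred == 0) & (yva == 0)).sum())
    fp = int(((pred == 1) & (yva == 0)).sum())
    m = confusion_metrics(tp, fn, tn, fp)
    m["auc"] = 100.0 * roc_auc_score(yva, scores)
    return m


METRIC_KEYS = ("auc", "balanced_accuracy", "sensitivity", "specificity", "ppv", "npv")


def _average_folds(folds: list[dict]) -> dict:
    out = {}
    for key in METRIC_KEYS:
        vals = np.asarray([f[key] for f in folds], dtype=float)
        ok = np.isfinite(vals)
        if not ok.all():
            logger.info("%d fold(s) with undefined %s excluded", (~ok).sum(), key)
        out[key] = float(vals[ok].mean()) if ok.any() else np.nan
    # keep the balanced-accuracy identity exact after averaging
    out["balanced_accuracy"] = (out["sensitivity"] + out["specificity"]) / 2.0
    return out


def evaluate_repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    outer_folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Repeated stratified k-fold evaluation at fixed hyperparameters."""
    y = np.asarray(y)
    folds = []
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=outer_folds, shuffle=True, random_state=seed + rep
        )
        for tr, va in skf.split(X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue
            Xtr, Xva, _ = minmax_rescale(X[tr], X[va])
            clf = _svc(C, gamma).fit(Xtr, y[tr])
            folds.append(_fold_metrics(clf, Xva, y[va]))
    return _average_folds(folds)


def evaluate_holdout(Xtr, ytr, Xte, yte, C, gamma) -> dict:
    """Single train/test evaluation (paper-style 80:20 hold-out)."""
    Xtr_s, Xte_s, _ = minmax_rescale(Xtr, Xte)
    clf = _svc(C, gamma).fit(Xtr_s, ytr)
    return _fold_metrics(clf, Xte_s, np.asarray(yte))


def family_columns(table: pd.DataFrame, family: str) -> list[str]:
    """Columns for 'single:<metric-or-network>', 'combined_local' or
    'combined_network'."""
    cols = feature_columns(table)
    local = [c for c in cols if not c.startswith("seedFC:")]
    network = [c for c in cols if c.startswith("seedFC:")]
    if family == "combined_local":
        chosen = local
    elif family == "combined_network":
        chosen = network
    elif family.startswith("single:"):
        name = family.split(":", 1)[1]
        chosen = [c for c in cols if c.split("@")[0] in (name, f"seedFC:{name}")]
    else:
        raise ValueError(
            f"unknown family {family!r}; expected 'single:<name>', "
            f"'combined_local' or 'combined_network'"
        )
    if not chosen:
        raise ValueError(f"no feature columns for family {family!r}")
    return chosen


def run_model_family(
    table: pd.DataFrame,
    family: str,
    seed: int = 0,
    split_ratio: float = 0.8,
    inner_folds: int = 5,
    repeats: int = 100,
    grid: HyperGrid = HyperGrid(),
) -> ClassifierReport:
    """Full per-family pipeline: split, rescale, nested search, evaluate."""
    cols = family_columns(table, family)
    X = table[cols].to_numpy(dtype=float)
    y = (table["group"] == "patient").to_numpy().astype(int)

    plan = make_split(y, split_ratio, derive_seed(seed, "split"))
    C, gamma, _ = nested_grid_search(
        X[plan.train_idx],
        y[plan.train_idx],
        grid,
        inner_folds,
        derive_seed(seed, "grid"),
    )
    cv = evaluate_repeated_cv(
        X, y, C, gamma, repeats=repeats, seed=derive_seed(seed, "cv")
    )
    holdout = evaluate_holdout(
        X[plan.train_idx], y[plan.train_idx], X[plan.test_idx], y[plan.test_idx], C, gamma
    )
    return ClassifierReport(
        family=family,
        C=C,
        gamma=gamma,
        cv=cv,
        holdout=holdout,
        n_train=len(plan.train_idx),
        n_test=len(plan.test_idx),
    )
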