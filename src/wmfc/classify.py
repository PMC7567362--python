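"""Disease staging from WM FC features: RF feature selection + RBF-SVM.

Feature selection follows a two-step protocol: a 200-tree random forest
scores every feature by out-of-bag permutation importance (how much the
forest's OOB accuracy — or OOB MSE for regression — deteriorates when that
feature's values are shuffled); features with non-positive importance are
discarded, the rest are ranked in descending order and added five at a
time, and the cumulative set with the lowest 10-fold cross-validated error
of the downstream model is retained.

Classification uses an RBF-kernel SVM tuned over a small C/gamma grid with
a misclassification-penalty (class-weight) grid to compensate for group
imbalance.  Out-of-fold decision values from stratified 10-fold CV are
pooled into a single ROC curve; AUC is the trapezoidal area, and
sensitivity/specificity are read at the Youden-optimal operating point.

Contrasts are CN versus cumulative patient sets in order of stage:
ADD; lMCI+ADD; MCI+lMCI+ADD; eMCI+...; SMC+... .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureSelectionResult",
    "StagingResult",
    "rf_importance",
    "select_features",
    "train_svm",
    "cumulative_contrasts",
    "stage_classification",
    "CUMULATIVE_STAGE_SETS",
]

#: patient-group unions in the order difficulty is expected to increase
CUMULATIVE_STAGE_SETS = (
    ("ADD",),
    ("lMCI", "ADD"),
    ("MCI", "lMCI", "ADD"),
    ("eMCI", "MCI", "lMCI", "ADD"),
    ("SMC", "eMCI", "MCI", "lMCI", "ADD"),
)


# ---------------------------------------------------------------------------
# out-of-bag permutation importance
# ---------------------------------------------------------------------------

def _oob_indices(tree, n_samples: int) -> np.ndarray:
    """Indices not drawn into a tree's bootstrap sample.

    Reconstructs the bootstrap draw from the tree's stored random state:
    an unweighted forest fit (no sample weights, max_samples=None) samples
    n uniform indices with replacement via RandomState.randint.
    """
    rnd = np.random.RandomState(tree.random_state)
    sampled = rnd.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def _tree_score(pred: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "classification":
        return float(np.mean(pred == y))
    return -float(np.mean((pred - y) ** 2))  # negative MSE


def rf_importance(X: np.ndarray, y: np.ndarray, n_trees: int = 200,
                  seed: int = 0, task: str = "classification",
                  feature_chunk: int = 64) -> np.ndarray:
    """Out-of-bag permutation importance per feature.

    For each tree, the drop in OOB accuracy (classification) or the rise in
    OOB MSE (regression) when one feature's OOB values are permuted is
    measured; importances average these drops over trees.  Noise features
    score near zero (either sign); informative features score positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes for importance")
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                        bootstrap=True, n_jobs=1)
    elif task == "regression":
        y = np.asarray(y, dtype=float)
        forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                       bootstrap=True, n_jobs=1)
    else:
        raise ValueError(f"unknown task {task!r}")
    forest.fit(X, y)

    rng = np.random.default_rng(seed)
    imp = np.zeros(f)
    used_trees = 0
    for tree in forest.estimators_:
        oob = _oob_indices(tree, n)
        if oob.size == 0:
            continue
        used_trees += 1
        X_oob = X[oob]
        y_oob = y[oob]
        base = _tree_score(tree.predict(X_oob), y_oob, task)
        # evaluate all permuted-feature copies for this tree in batched calls
        for start in range(0, f, feature_chunk):
            cols = range(start, min(start + feature_chunk, f))
            big = np.tile(X_oob, (len(cols), 1))
            m = len(oob)
            for bi, j in enumerate(cols):
                big[bi * m:(bi + 1) * m, j] = X_oob[rng.permutation(m), j]
            pred = tree.predict(big)
            for bi, j in enumerate(cols):
                imp[j] += base - _tree_score(pred[bi * m:(bi + 1) * m], y_oob, task)
    if used_trees == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return imp / used_trees


# ---------------------------------------------------------------------------
# cumulative feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionResult:
    importance: np.ndarray          # per original feature
    ordered_features: np.ndarray    # surviving features, descending importance
    set_sizes: np.ndarray           # cumulative sizes evaluated (5, 10, ...)
    cv_errors: np.ndarray           # CV error at each size
    optimal_features: np.ndarray    # the argmin cumulative set

    @property
    def n_selected(self) -> int:
        return len(self.optimal_features)


def _default_curve_estimator(task: str, seed: int):
    if task == "classification":
        return SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    # a lighter forest suffices to rank cumulative sets on the curve
    return RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)


def _cv_error(X: np.ndarray, y: np.ndarray, estimator, task: str,
              n_folds: int, seed: int) -> float:
    """Mean 10-fold CV error: 0/1 misclassification rate for classification,
    MSE for regression."""
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        folds = StratifiedKFold(n_splits=min(n_folds, counts.min()),
                                shuffle=True, random_state=seed)
    else:
        folds = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    errs = []
    for tr, te in folds.split(X, y if task == "classification" else None):
        from sklearn.base import clone

        est = clone(estimator).fit(X[tr], y[tr])
        pred = est.predict(X[te])
        if task == "classification":
            errs.append(np.mean(pred != y[te]))
        else:
            errs.append(np.mean((pred - y[te]) ** 2))
    return float(np.mean(errs))


def select_features(X: np.ndarray, y: np.ndarray, importance: np.ndarray,
                    chunk: int = 5, n_folds: int = 10, seed: int = 0,
                    task: str = "classification",
                    estimator=None) -> FeatureSelectionResult:
    """Cumulative forward selection over importance-ranked features.

    Features with importance <= 0 are dropped; the rest are sorted in
    descending importance (ties keep original index order) and evaluated as
    cumulative sets of size ``chunk``, 2*``chunk``, ... (plus the full
    remainder).  The optimal set minimizes 10-fold CV error of the
    downstream model, with ties resolved toward the smaller set.
    """
    importance = np.asarray(importance, dtype=float)
    X = np.asarray(X, dtype=float)
    survivors = np.flatnonzero(importance > 0)
    if survivors.size == 0:
        raise ValueError("no feature has positive importance")
    order = survivors[np.argsort(-importance[survivors], kind="stable")]
    sizes = list(range(chunk, len(order) + 1, chunk))
    if not sizes or sizes[-1] != len(order):
        sizes.append(len(order))
    est = estimator if estimator is not None else _default_curve_estimator(task, seed)
    errors = np.array([
        _cv_error(X[:, order[:k]], y, est, task, n_folds, seed) for k in sizes
    ])
    best = int(np.argmin(errors))  # first minimum -> smallest set on ties
    return FeatureSelectionResult(
        importance=importance,
        ordered_features=order,
        set_sizes=np.asarray(sizes),
        cv_errors=errors,
        optimal_features=order[: sizes[best]],
    )


# ---------------------------------------------------------------------------
# RBF-SVM with ROC summaries
# ---------------------------------------------------------------------------

@dataclass
class StagingResult:
    contrast: str
    C: float
    gamma: float
    class_weight_ratio: float
    cv_error: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    n_control: int
    n_patient: int
    n_features: int
    selected_features: np.ndarray | None = None
    protocol: str = "pooled out-of-fold decision values"


def _weight_ratios(y: np.ndarray) -> tuple[float, ...]:
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    r = n_neg / n_pos
    return (1.0, r, 2.0 * r)


def _grid_search(X: np.ndarray, y: np.ndarray, C_grid, gamma_grid,
                 weight_ratios, n_folds: int, seed: int) -> tuple[float, float, float, float]:
    """Lowest-CV-error (C, gamma, weight ratio); ties keep grid order."""
    _, counts = np.unique(y, return_counts=True)
    folds = StratifiedKFold(n_splits=min(n_folds, counts.min()),
                            shuffle=True, random_state=seed)
    splits = list(folds.split(X, y))
    best = None
    for C in C_grid:
        for g in gamma_grid:
            for w in weight_ratios:
                errs = []
                for tr, te in splits:
                    clf = SVC(kernel="rbf", C=C, gamma=g,
                              class_weight={0: 1.0, 1: w})
                    clf.fit(X[tr], y[tr])
                    errs.append(np.mean(clf.predict(X[te]) != y[te]))
                err = float(np.mean(errs))
                if best is None or err < best[0]:
                    best = (err, C, g, w)
    err, C, g, w = best
    return C, g, w, err


def train_svm(X: np.ndarray, y: np.ndarray,
              C_grid=(0.1, 1.0, 10.0, 100.0),
              gamma_grid=None,
              weight_ratios=None,
              n_folds: int = 10, seed: int = 0,
              contrast: str = "") -> StagingResult:
    """Tune and evaluate the RBF-SVM for one binary contrast.

    ``y`` codes controls as 0 and patients as 1.  Hyper-parameters (C,
    gamma, misclassification-penalty ratio for the patient class) are tuned
    by stratified 10-fold CV error; out-of-fold decision values at the
    tuned setting are pooled for the ROC, AUC (trapezoid) and the
    Youden-optimal sensitivity/specificity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0 (control) / 1 (patient)")
    d = X.shape[1]
    if gamma_grid is None:
        gamma_grid = tuple(s / d for s in (0.1, 1.0, 10.0))
    if weight_ratios is None:
        weight_ratios = _weight_ratios(y)

    C, g, w, _ = _grid_search(X, y, C_grid, gamma_grid, weight_ratios, n_folds, seed)

    _, counts = np.unique(y, return_counts=True)
    folds = StratifiedKFold(n_splits=min(n_folds, counts.min()),
                            shuffle=True, random_state=seed)
    decision = np.empty(len(y))
    pred = np.empty(len(y), dtype=int)
    for tr, te in folds.split(X, y):
        clf = SVC(kernel="rbf", C=C, gamma=g, class_weight={0: 1.0, 1: w})
        clf.fit(X[tr], y[tr])
        decision[te] = clf.decision_function(X[te])
        pred[te] = clf.predict(X[te])
    cv_error = float(np.mean(pred != y))

    fpr, tpr, thr = roc_curve(y, decision)
    roc_auc = float(trapezoid_auc(fpr, tpr))
    youden = int(np.argmax(tpr - fpr))
    return StagingResult(
        contrast=contrast, C=float(C), gamma=float(g), class_weight_ratio=float(w),
        cv_error=cv_error, fpr=fpr, tpr=tpr, thresholds=thr, auc=roc_auc,
        sensitivity=float(tpr[youden]), specificity=float(1 - fpr[youden]),
        n_control=int(np.sum(y == 0)), n_patient=int(np.sum(y == 1)),
        n_features=d,
    )


# ---------------------------------------------------------------------------
# staging across cumulative contrasts
# ---------------------------------------------------------------------------

def cumulative_contrasts(groups_present) -> list[tuple[str, tuple[str, ...]]]:
    """Ordered CN-vs-cumulative-patient contrasts, skipping (with a warning)
    any contrast whose patient union references an absent group."""
    present = set(groups_present)
    if "CN" not in present:
        warnings.warn("no CN group present; no contrasts to run", stacklevel=2)
        return []
    out = []
    for union in CUMULATIVE_STAGE_SETS:
        missing = [g for g in union if g not in present]
        if missing:
            warnings.warn(
                f"skipping contrast CN vs {'+'.join(union)}: missing {missing}",
                stacklevel=2)
            continue
        out.append((f"CN_vs_{'+'.join(union)}", union))
    return out


def _stage_one_pooled(X, y, name, n_trees, chunk, n_folds, seed):
    imp = rf_importance(X, y, n_trees=n_trees, seed=seed)
    sel = select_features(X, y, imp, chunk=chunk, n_folds=n_folds, seed=seed)
    res = train_svm(X[:, sel.optimal_features], y, n_folds=n_folds,
                    seed=seed, contrast=name)
    res.selected_features = sel.optimal_features
    return res, sel


def _stage_one_nested(X, y, name, n_trees, chunk, n_folds, seed):
    """Selection and tuning repeated inside each outer fold; outer
    out-of-fold decision values pooled for the ROC."""
    _, counts = np.unique(y, return_counts=True)
    outer = StratifiedKFold(n_splits=min(n_folds, counts.min()),
                            shuffle=True, random_state=seed)
    decision = np.empty(len(y))
    pred = np.empty(len(y), dtype=int)
    params = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        imp = rf_importance(X[tr], y[tr], n_trees=n_trees, seed=seed + k)
        sel = select_features(X[tr], y[tr], imp, chunk=chunk,
                              n_folds=n_folds, seed=seed + k)
        feats = sel.optimal_features
        gamma_grid = tuple(s / len(feats) for s in (0.1, 1.0, 10.0))
        C, g, w, _ = _grid_search(X[tr][:, feats], y[tr], (0.1, 1.0, 10.0, 100.0),
                                  gamma_grid, _weight_ratios(y[tr]), n_folds, seed + k)
        clf = SVC(kernel="rbf", C=C, gamma=g, class_weight={0: 1.0, 1: w})
        clf.fit(X[tr][:, feats], y[tr])
        decision[te] = clf.decision_function(X[te][:, feats])
        pred[te] = clf.predict(X[te][:, feats])
        params.append((C, g, w, len(feats)))
    fpr, tpr, thr = roc_curve(y, decision)
    roc_auc = float(trapezoid_auc(fpr, tpr))
    youden = int(np.argmax(tpr - fpr))
    C_mode, g_mode, w_mode, nf = max(set(params), key=params.count)
    res = StagingResult(
        contrast=name, C=float(C_mode), gamma=float(g_mode),
        class_weight_ratio=float(w_mode),
        cv_error=float(np.mean(pred != y)),
        fpr=fpr, tpr=tpr, thresholds=thr, auc=roc_auc,
        sensitivity=float(tpr[youden]), specificity=float(1 - fpr[youden]),
        n_control=int(np.sum(y == 0)), n_patient=int(np.sum(y == 1)),
        n_features=int(nf),
        protocol="nested selection and tuning, pooled outer out-of-fold decisions",
    )
    return res, None


def stage_classification(features: np.ndarray, groups: np.ndarray,
                         seed: int = 0, n_trees: int = 200, chunk: int = 5,
                         n_folds: int = 10,
                         nested: bool = False) -> list[StagingResult]:
    """Run every available CN-vs-cumulative contrast.

    ``nested=False`` (default) reproduces the straightforward protocol —
    feature selection and hyper-parameter tuning on the full contrast data,
    then 10-fold out-of-fold ROC — whose error estimate is optimistic
    because selection sees the evaluation subjects.  ``nested=True`` repeats
    selection and tuning inside every outer CV fold for an unbiased
    generalization estimate.
    """
    features = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    results = []
    for name, union in cumulative_contrasts(np.unique(groups)):
        mask = (groups == "CN") | np.isin(groups, union)
        X = features[mask]
        y = np.isin(groups[mask], union).astype(int)
        if nested:
            res, _ = _stage_one_nested(X, y, name, n_trees, chunk, n_folds, seed)
        else:
            res, _ = _stage_one_pooled(X, y, name, n_trees, chunk, n_folds, seed)
        results.append(res)
    return results
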