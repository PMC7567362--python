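"""FC-behavior association: element-wise score correlations with FDR,
tract-averaged coefficients, and RF regression predicting each score.

Each FCM element is Pearson-correlated with each neuropsychological score
across subjects (pairwise-complete over missing scores), BH-FDR is applied
per score over the element matrix, and a display copy zeroes coefficients
with adjusted p > 0.05.  Coefficients are then averaged along each WM
tract.  Finally a random-forest regression, after the same cumulative
importance-based feature selection used for classification, predicts the
score from all WM FC elements; fit quality is the Pearson correlation r
between true scores and out-of-fold predictions, with R^2 = r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .classify import rf_importance, select_features
from .group_stats import fdr_adjust, tractwise_fc

__all__ = [
    "ScoreAssociation",
    "ScoreRegressionResult",
    "elementwise_score_correlation",
    "tract_average_correlation",
    "rf_score_regression",
    "score_associations",
]


@dataclass
class ScoreAssociation:
    score: str
    r: np.ndarray          # element-wise Pearson r
    p: np.ndarray          # two-sided p per element
    p_fdr: np.ndarray      # BH-adjusted, family = this score's element matrix
    r_zeroed: np.ndarray   # r with entries set to 0 where p_fdr > alpha
    alpha: float
    n_complete: np.ndarray  # complete pairs per element


@dataclass
class ScoreRegressionResult:
    score: str
    selected_features: np.ndarray
    predicted: np.ndarray   # out-of-fold predictions, aligned with `observed`
    observed: np.ndarray
    r: float
    r2: float
    p: float
    n: int


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of x against each column of Y,
    pairwise-complete; columns with < 3 complete pairs or zero variance are NaN."""
    n_sub, n_el = Y.shape
    ok_x = np.isfinite(x)
    ok = ok_x[:, None] & np.isfinite(Y)
    n = ok.sum(axis=0).astype(float)

    xs = np.where(ok, x[:, None], 0.0)
    ys = np.where(ok, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        cov = (xs * ys).sum(axis=0) / n - mx * my
        vx = (xs**2).sum(axis=0) / n - mx**2
        vy = (ys**2).sum(axis=0) / n - my**2
        r = cov / np.sqrt(vx * vy)
    bad = (n < 3) | ~np.isfinite(r)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p, n


def elementwise_score_correlation(stack: np.ndarray, score: np.ndarray,
                                  score_name: str = "score",
                                  alpha: float = 0.05) -> ScoreAssociation:
    """Pearson r between each FCM element and a score across subjects.

    Uses pairwise-complete data (subjects missing the score, or missing
    the element, are dropped for that pair); a constant score yields NaN
    everywhere.  FDR is BH over this score's full element matrix.
    """
    stack = np.asarray(stack, dtype=float)
    score = np.asarray(score, dtype=float)
    shape = stack.shape[1:]
    Y = stack.reshape(stack.shape[0], -1)
    finite = score[np.isfinite(score)]
    if finite.size >= 1 and np.all(finite == finite[0]):
        nan = np.full(shape, np.nan)
        return ScoreAssociation(score_name, nan, nan.copy(), nan.copy(),
                                nan.copy(), alpha, np.zeros(shape))
    r, p, n = _pearson_with_p(score, Y)
    p_fdr = fdr_adjust(p.reshape(shape), alpha=alpha)
    r = r.reshape(shape)
    r_zeroed = np.where(p_fdr <= alpha, r, 0.0)
    r_zeroed[np.isnan(r)] = np.nan
    return ScoreAssociation(score_name, r, p.reshape(shape), p_fdr,
                            r_zeroed, alpha, n.reshape(shape))


def tract_average_correlation(r_matrix: np.ndarray, kind: str = "WG") -> np.ndarray:
    """Mean coefficient along each WM tract's row (same element sets as
    tract-wise FC: WW excludes the self-correlation diagonal)."""
    return tractwise_fc(r_matrix, kind=kind)


def rf_score_regression(features: np.ndarray, score: np.ndarray,
                        score_name: str = "score", seed: int = 0,
                        n_trees: int = 200, chunk: int = 5, n_folds: int = 10,
                        min_subjects: int = 20, nested: bool = True,
                        r2_mode: str = "corr") -> ScoreRegressionResult:
    """RF regression of one score on WM FC features, with feature selection.

    Subjects missing the score are dropped (< ``min_subjects`` remaining is
    refused).  Importance-ranked cumulative selection (regression
    criterion) picks the reported feature set; a ``n_trees``-tree forest
    produces out-of-fold predictions from ``n_folds``-fold CV.  With
    ``nested=True`` (default) the selection is repeated inside every fold
    so the evaluation carries no selection leakage — under a null score the
    estimated R^2 stays near zero.  ``nested=False`` selects once on all
    subjects (simpler, but optimistic on small cohorts).  ``r`` is the
    Pearson correlation of true vs predicted scores, ``r2`` its square
    (``r2_mode="score"`` instead reports 1 - SSE/SST of the predictions).
    """
    features = np.asarray(features, dtype=float)
    score = np.asarray(score, dtype=float)
    ok = np.isfinite(score)
    if ok.sum() < min_subjects:
        raise ValueError(
            f"{score_name}: only {int(ok.sum())} subjects with the score "
            f"(minimum {min_subjects})"
        )
    X, y = features[ok], score[ok]

    imp = rf_importance(X, y, n_trees=n_trees, seed=seed, task="regression")
    sel = select_features(X, y, imp, chunk=chunk, n_folds=n_folds,
                          seed=seed, task="regression")

    pred = np.full(len(y), y.mean())
    folds = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(folds.split(X)):
        if nested:
            try:
                imp_k = rf_importance(X[tr], y[tr], n_trees=n_trees,
                                      seed=seed + k, task="regression")
                sel_k = select_features(X[tr], y[tr], imp_k, chunk=chunk,
                                        n_folds=n_folds, seed=seed + k,
                                        task="regression")
                feats = sel_k.optimal_features
            except ValueError:
                # nothing informative in this training fold: predict the mean
                pred[te] = y[tr].mean()
                continue
        else:
            feats = sel.optimal_features
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[tr][:, feats], y[tr])
        pred[te] = rf.predict(X[te][:, feats])

    if np.std(pred) == 0 or np.std(y) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(y, pred)
    if r2_mode == "corr":
        r2 = float(r) ** 2
    elif r2_mode == "score":
        r2 = float(1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return ScoreRegressionResult(score_name, sel.optimal_features, pred, y,
                                 float(r), r2, float(p), int(len(y)))


def score_associations(stack: np.ndarray, scores: pd.DataFrame,
                       kind: str = "WG", alpha: float = 0.05) -> dict[str, ScoreAssociation]:
    """Element-wise association of every score column with the FCM stack.

    Subjects lacking all scores are excluded up front; per-score missing
    values are then handled pairwise-complete.
    """
    stack = np.asarray(stack, dtype=float)
    has_any = scores.notna().any(axis=1).to_numpy()
    stack = stack[has_any]
    scores = scores.loc[has_any]
    out = {}
    for name in scores.columns:
        assoc = elementwise_score_correlation(
            stack, scores[name].to_numpy(dtype=float), score_name=name, alpha=alpha)
        out[name] = assoc
    return out
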