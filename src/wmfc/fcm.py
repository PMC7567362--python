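"""Functional correlation matrices (FCM) with motion censoring and covariate partialling.

Per subject, the mean ROI time courses are Pearson-correlated over the
frames that survive FD censoring, and the full correlation matrix is cut
into the three labelled blocks: WM x GM (``WG``, 48 x 82 for the packaged
registry), WM x WM (``WW``, 48 x 48) and GM x GM (``GG``, 82 x 82).
Across subjects, each FCM element can then be residualized on nuisance
covariates (age, sex, education, acquisition site) by element-wise OLS.

Raw correlations are kept on their natural scale throughout (no Fisher
z-transform by default; a transform helper is provided).  Residualized
elements may leave [-1, 1] and are deliberately not re-clipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import RoiRegistry
from .roi_extraction import RoiTimeSeries, framewise_displacement

__all__ = [
    "FCMatrix",
    "TooFewRetainedFramesError",
    "censored_correlation",
    "assemble_fcm",
    "subject_fcms",
    "build_covariate_design",
    "partial_out_covariates",
    "fisher_z",
]

logger = logging.getLogger("wmfc")

KINDS = ("WG", "WW", "GG")


class TooFewRetainedFramesError(ValueError):
    """Raised when censoring leaves fewer frames than the configured floor."""


@dataclass
class FCMatrix:
    """Labelled correlation matrix of one kind (WG, WW or GG)."""

    kind: str
    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    subject: str | None = None
    n_retained_frames: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")

    @property
    def n_elements(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.8g")


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher variance-stabilizing transform, arctanh(r) (optional; off by
    default everywhere in the pipeline, which averages raw coefficients)."""
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


# ---------------------------------------------------------------------------
# censored correlation
# ---------------------------------------------------------------------------

def censored_correlation(series: RoiTimeSeries,
                         fd: np.ndarray | None = None,
                         motion: np.ndarray | pd.DataFrame | None = None,
                         fd_threshold: float = 0.5,
                         min_frames: int = 10) -> tuple[np.ndarray, int]:
    """All-pairs Pearson correlation over retained (low-motion) frames.

    Frames are retained when the series' own retention mask is set and
    FD <= ``fd_threshold`` (FD computed from ``motion`` if ``fd`` is not
    given; with neither, no motion censoring is applied).  Equals textbook
    Pearson correlation on the physically truncated series.  Columns that
    are NaN or constant over the retained frames yield NaN rows/columns.

    Returns ``(corr, n_retained)``; raises TooFewRetainedFramesError below
    the ``min_frames`` floor.
    """
    if fd is None and motion is not None:
        fd = framewise_displacement(motion)
    keep = series.retained.copy()
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.shape != (series.n_frames,):
            raise ValueError("FD length must equal frame count")
        keep &= fd <= fd_threshold
    n_retained = int(keep.sum())
    if n_retained < min_frames:
        raise TooFewRetainedFramesError(
            f"subject {series.subject!r}: only {n_retained} retained frames "
            f"(floor {min_frames})"
        )
    sub = series.values[keep]
    valid = ~np.isnan(sub).any(axis=0)
    valid &= np.nanstd(sub, axis=0) > 0
    n_roi = series.n_rois
    corr = np.full((n_roi, n_roi), np.nan)
    if valid.any():
        block = np.corrcoef(sub[:, valid], rowvar=False)
        block = np.clip(block, -1.0, 1.0)  # guard fp overshoot
        block = (block + block.T) / 2.0    # enforce exact symmetry
        np.fill_diagonal(block, 1.0)
        ix = np.flatnonzero(valid)
        corr[np.ix_(ix, ix)] = block
    return corr, n_retained


# ---------------------------------------------------------------------------
# FCM assembly
# ---------------------------------------------------------------------------

def assemble_fcm(correlations: np.ndarray, roi_order: list[str],
                 registry: RoiRegistry, kind: str,
                 subject: str | None = None,
                 n_retained_frames: int | None = None) -> FCMatrix:
    """Cut the labelled block of ``kind`` out of an all-ROI correlation matrix.

    ``roi_order`` names the rows/columns of ``correlations``; the output is
    reordered to registry order, so a permuted input yields an identical
    matrix.  Unknown or missing labels are a hard error.
    """
    correlations = np.asarray(correlations, dtype=float)
    if correlations.shape != (len(roi_order), len(roi_order)):
        raise ValueError("correlation matrix shape does not match roi_order")
    pos = {a: i for i, a in enumerate(roi_order)}
    wm = registry.wm_abbreviations
    gm = registry.gm_abbreviations
    if kind == "WG":
        rows, cols = wm, gm
    elif kind == "WW":
        rows, cols = wm, wm
    elif kind == "GG":
        rows, cols = gm, gm
    else:
        raise ValueError(f"unknown FCM kind {kind!r}")
    missing = [a for a in {*rows, *cols} if a not in pos]
    if missing:
        raise KeyError(f"ROI labels absent from input series: {sorted(missing)}")
    ri = [pos[a] for a in rows]
    ci = [pos[a] for a in cols]
    values = correlations[np.ix_(ri, ci)]
    return FCMatrix(kind, values, list(rows), list(cols),
                    subject=subject, n_retained_frames=n_retained_frames)


def subject_fcms(series: RoiTimeSeries, registry: RoiRegistry,
                 motion: np.ndarray | pd.DataFrame | None = None,
                 fd: np.ndarray | None = None,
                 fd_threshold: float = 0.5, min_frames: int = 10,
                 kinds: tuple[str, ...] = ("WG", "WW")) -> dict[str, FCMatrix]:
    """Censored correlation + assembly for one subject, for each kind."""
    corr, n_ret = censored_correlation(series, fd=fd, motion=motion,
                                       fd_threshold=fd_threshold,
                                       min_frames=min_frames)
    return {k: assemble_fcm(corr, series.roi_order, registry, k,
                            subject=series.subject, n_retained_frames=n_ret)
            for k in kinds}


# ---------------------------------------------------------------------------
# covariate partialling
# ---------------------------------------------------------------------------

def build_covariate_design(cohort: pd.DataFrame,
                           columns: tuple[str, ...] = ("age", "sex", "education"),
                           site_column: str | None = "site") -> pd.DataFrame:
    """Design matrix [intercept | age, sex, education | site dummies].

    The site factor is dummy-encoded with the reference level (first in
    sorted order) dropped, keeping the design full rank.
    """
    parts = {"intercept": np.ones(len(cohort))}
    for c in columns:
        parts[c] = pd.to_numeric(cohort[c]).to_numpy(dtype=float)
    X = pd.DataFrame(parts, index=cohort.index)
    if site_column is not None and site_column in cohort.columns:
        dummies = pd.get_dummies(cohort[site_column].astype(str),
                                 prefix="site", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _drop_to_full_rank(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, names
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
    logger.warning("covariate design rank-deficient; dropping: %s", dropped)
    warnings.warn(f"dropped collinear covariate columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[i] for i in keep]


def partial_out_covariates(stack: np.ndarray,
                           design: pd.DataFrame) -> np.ndarray:
    """Residualize each FCM element on the covariates, across subjects.

    For each element (i, j) an OLS fit of the across-subject value vector
    on the design is computed; the returned stack holds residual + grand
    mean, so group means stay interpretable on the correlation scale.
    Elements with missing (NaN) entries are fitted on the complete subjects
    only (pairwise-complete).  Values may leave [-1, 1]; they are not
    re-clipped.
    """
    stack = np.asarray(stack, dtype=float)
    n_subj = stack.shape[0]
    if len(design) != n_subj:
        raise ValueError("design rows must align with the subject stack")
    X = design.to_numpy(dtype=float)
    X, _ = _drop_to_full_rank(X, list(design.columns))

    Y = stack.reshape(n_subj, -1)
    out = np.full_like(Y, np.nan)
    nan_cols = np.isnan(Y).any(axis=0)

    if (~nan_cols).any():
        Yc = Y[:, ~nan_cols]
        beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
        resid = Yc - X @ beta
        out[:, ~nan_cols] = resid + Yc.mean(axis=0)

    for j in np.flatnonzero(nan_cols):  # pairwise-complete fallback
        y = Y[:, j]
        ok = ~np.isnan(y)
        if ok.sum() <= X.shape[1]:
            continue  # not enough complete subjects; stays NaN
        b, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        out[ok, j] = y[ok] - X[ok] @ b + y[ok].mean()

    return out.reshape(stack.shape)
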