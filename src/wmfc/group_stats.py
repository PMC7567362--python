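"""Group comparison of FCMs: permutation tests with FDR, effect sizes,
tract-wise FC t-tests and the normalized overall-FC trend.

For a CN-vs-patient contrast each FCM element is tested with a label
permutation test on the difference of group means (label shuffles shared
across elements, preserving their dependence), followed by
Benjamini-Hochberg FDR over the whole matrix.  Effect sizes are Cohen's d
with pooled SD.  WM-tract-wise FC averages each tract's row of the WG or
WW matrix (WW excluding the unit diagonal by default) and is compared
between groups with unpaired t-tests.  Overall-FC (per-subject mean over
all elements of one FCM kind) is normalized by the affine map sending the
CN group mean to 1 and the ADD group mean to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fcm import FCMatrix
from .registry import RoiRegistry

__all__ = [
    "GroupComparison",
    "OverallFCTrend",
    "mean_fcm",
    "permutation_test",
    "fdr_adjust",
    "effect_size",
    "compare_groups",
    "tractwise_fc",
    "tract_ttest",
    "significance_stars",
    "overall_fc",
    "overall_fc_trend",
]


def _two_group_arrays(stack: np.ndarray, labels: np.ndarray,
                      contrast: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    a, b = contrast
    ga = stack[labels == a]
    gb = stack[labels == b]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"empty group in contrast {contrast}")
    return ga, gb


def mean_fcm(stack: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Element-wise mean matrix per group (mFCM); NaN entries are skipped.

    ``stack`` is subjects x (matrix dims); groups with < 1 subject are a
    hard error, and an all-NaN element stays NaN in the mean.
    """
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        sel = stack[labels == g]
        if len(sel) == 0:
            raise ValueError(f"empty group {g!r}")
        with np.errstate(invalid="ignore"):
            out[g] = np.nanmean(sel, axis=0)
    return out


def nan_counts(stack: np.ndarray, labels: np.ndarray) -> dict[str, int]:
    """Number of missing (NaN) entries skipped per group when averaging."""
    labels = np.asarray(labels)
    return {g: int(np.isnan(stack[labels == g]).sum()) for g in pd.unique(labels)}


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(stack: np.ndarray, labels: np.ndarray,
                     contrast: tuple[str, str], n_perm: int = 10_000,
                     seed: int | np.random.Generator = 0,
                     chunk: int = 500) -> np.ndarray:
    """Element-wise two-sided permutation p-values for a two-group contrast.

    Statistic: difference of group means per element.  Each permutation
    reshuffles the group labels once and applies the same shuffle to every
    element.  p = (1 + #{|perm stat| >= |observed|}) / (n_perm + 1), so
    p > 0 always and the test is valid (slightly conservative).
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse",
                      stacklevel=2)
    ga, gb = _two_group_arrays(stack, labels, contrast)
    shape = ga.shape[1:]
    na, nb = len(ga), len(gb)
    data = np.concatenate([ga, gb]).reshape(na + nb, -1)
    has_nan = np.isnan(data).any()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if has_nan:
        obs = np.abs(np.nanmean(data[:na], axis=0) - np.nanmean(data[na:], axis=0))
    else:
        obs = np.abs(data[:na].mean(axis=0) - data[na:].mean(axis=0))

    n = na + nb
    count = np.zeros(data.shape[1])
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # one label shuffle per permutation, shared across elements
        picks = np.empty((m, n), dtype=bool)
        for i in range(m):
            perm = rng.permutation(n)
            row = np.zeros(n, dtype=bool)
            row[perm[:na]] = True
            picks[i] = row
        if has_nan:
            valid = ~np.isnan(data)
            dz = np.nan_to_num(data)
            sum_a = picks @ dz
            cnt_a = picks @ valid.astype(float)
            sum_all = dz.sum(axis=0)
            cnt_all = valid.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                stat = sum_a / cnt_a - (sum_all - sum_a) / (cnt_all - cnt_a)
        else:
            sum_a = picks @ data
            stat = sum_a / na - (data.sum(axis=0) - sum_a) / nb
        count += (np.abs(stat) >= obs).sum(axis=0)
        done += m

    p = (1.0 + count) / (n_perm + 1.0)
    p[np.isnan(obs)] = np.nan
    return p.reshape(shape)


def fdr_adjust(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over all finite entries.

    The family is the whole matrix; NaN entries are passed through.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    out = np.full_like(flat, np.nan)
    if ok.any():
        _, adj, _, _ = multipletests(flat[ok], alpha=alpha, method="fdr_bh")
        out[ok] = adj
    return out.reshape(p.shape)


def effect_size(stack: np.ndarray, labels: np.ndarray,
                contrast: tuple[str, str]) -> np.ndarray:
    """Cohen's d with pooled SD per element; sign is mean(first) - mean(second).

    Elements with zero pooled SD (or too few observations) are NaN.
    """
    ga, gb = _two_group_arrays(stack, labels, contrast)
    na, nb = len(ga), len(gb)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma, mb = np.nanmean(ga, axis=0), np.nanmean(gb, axis=0)
        va, vb = np.nanvar(ga, axis=0, ddof=1), np.nanvar(gb, axis=0, ddof=1)
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        d = (ma - mb) / sp
    d = np.where(sp == 0, np.nan, d)
    return d


@dataclass
class GroupComparison:
    """CN-vs-X contrast bundle: mean matrices, differences, permutation and
    FDR-adjusted p-values, effect sizes, and the difference matrix with
    non-significant (p_fdr > alpha) elements set to zero."""

    contrast: tuple[str, str]
    mean_fcm_per_group: dict[str, np.ndarray]
    difference: np.ndarray
    p_perm: np.ndarray
    p_fdr: np.ndarray
    effect_size: np.ndarray
    alpha: float = 0.05
    thresholded_difference: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        keep = self.p_fdr <= self.alpha
        self.thresholded_difference = np.where(keep, self.difference, 0.0)
        self.thresholded_difference[np.isnan(self.difference)] = np.nan

    @property
    def significant_mask(self) -> np.ndarray:
        return self.p_fdr <= self.alpha


def compare_groups(stack: np.ndarray, labels: np.ndarray,
                   contrast: tuple[str, str], n_perm: int = 10_000,
                   alpha: float = 0.05,
                   seed: int | np.random.Generator = 0) -> GroupComparison:
    """Full element-wise comparison for one contrast (first minus second)."""
    means = mean_fcm(np.asarray(stack, dtype=float), labels)
    a, b = contrast
    diff = means[a] - means[b]
    p = permutation_test(stack, labels, contrast, n_perm=n_perm, seed=seed)
    return GroupComparison(
        contrast=contrast,
        mean_fcm_per_group={a: means[a], b: means[b]},
        difference=diff,
        p_perm=p,
        p_fdr=fdr_adjust(p, alpha=alpha),
        effect_size=effect_size(stack, labels, contrast),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# tract-wise FC
# ---------------------------------------------------------------------------

def tractwise_fc(values: np.ndarray | FCMatrix, kind: str | None = None,
                 include_diagonal: bool = False) -> np.ndarray:
    """Per-WM-tract scalar FC: the mean of the tract's row of a WG or WW matrix.

    For WW the self-correlation diagonal is excluded by default (it is
    identically 1 and would bias the average); ``include_diagonal=True``
    reproduces the inclusive all-48-element reading.  NaN elements are
    skipped.
    """
    if isinstance(values, FCMatrix):
        kind = values.kind
        values = values.values
    if kind not in ("WG", "WW"):
        raise ValueError("tract-wise FC is defined for WG and WW matrices")
    values = np.asarray(values, dtype=float)
    if kind == "WW" and not include_diagonal:
        v = values.copy()
        np.fill_diagonal(v, np.nan)
        values = v
    with np.errstate(invalid="ignore"):
        return np.nanmean(values, axis=1)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tract_ttest(tract_values: np.ndarray, labels: np.ndarray,
                contrast: tuple[str, str],
                tract_names: list[str] | None = None,
                equal_var: bool = True) -> pd.DataFrame:
    """Unpaired two-sample t-test per WM tract (Student by default; set
    ``equal_var=False`` for Welch).  Returns tract, per-group mean/SD, t, p
    and significance stars at 0.05 / 0.01 / 0.001.
    """
    tract_values = np.asarray(tract_values, dtype=float)
    ga, gb = _two_group_arrays(tract_values, labels, contrast)
    n_tract = tract_values.shape[1]
    names = tract_names if tract_names is not None else [str(i) for i in range(n_tract)]
    rows = []
    for j in range(n_tract):
        x, y = ga[:, j], gb[:, j]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        rows.append({
            "tract": names[j],
            f"mean_{contrast[0]}": np.mean(x) if len(x) else np.nan,
            f"sd_{contrast[0]}": np.std(x, ddof=1) if len(x) > 1 else np.nan,
            f"mean_{contrast[1]}": np.mean(y) if len(y) else np.nan,
            f"sd_{contrast[1]}": np.std(y, ddof=1) if len(y) > 1 else np.nan,
            "t": t,
            "p": p,
            "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overall-FC trend
# ---------------------------------------------------------------------------

def overall_fc(stack: np.ndarray) -> np.ndarray:
    """Per-subject overall-FC: the mean over all elements of the subject's FCM."""
    stack = np.asarray(stack, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack.reshape(stack.shape[0], -1), axis=1)


@dataclass
class OverallFCTrend:
    """Raw and normalized per-group mean/SD of overall-FC.  Normalization is
    the single affine map x -> (x - m_ADD) / (m_CN - m_ADD) applied to all
    group means, with SDs scaled by 1 / (m_CN - m_ADD)."""

    group_order: list[str]
    raw_mean: dict[str, float]
    raw_sd: dict[str, float]
    normalized_mean: dict[str, float]
    normalized_sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group_order,
            "mean": [self.raw_mean[g] for g in self.group_order],
            "sd": [self.raw_sd[g] for g in self.group_order],
            "normalized_mean": [self.normalized_mean[g] for g in self.group_order],
            "normalized_sd": [self.normalized_sd[g] for g in self.group_order],
        })


def overall_fc_trend(per_subject: np.ndarray, labels: np.ndarray,
                     group_order: list[str] | None = None,
                     cn: str = "CN", add: str = "ADD") -> OverallFCTrend:
    """Group means/SDs of a per-subject quantity, normalized so that the CN
    mean is exactly 1 and the ADD mean exactly 0.

    Applies to overall-FC and equally to neuropsychological scores (the
    same linear-scaling is used for both trends).
    """
    per_subject = np.asarray(per_subject, dtype=float)
    labels = np.asarray(labels)
    groups = group_order or [g for g in pd.unique(labels)]
    for required in (cn, add):
        if required not in groups:
            raise ValueError(f"group {required!r} absent; cannot anchor normalization")
    raw_mean, raw_sd = {}, {}
    for g in groups:
        v = per_subject[labels == g]
        v = v[~np.isnan(v)]
        if len(v) == 0:
            raise ValueError(f"empty group {g!r}")
        raw_mean[g] = float(np.mean(v))
        raw_sd[g] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    denom = raw_mean[cn] - raw_mean[add]
    if denom == 0:
        raise ValueError("CN and ADD means are equal; normalization undefined")
    norm_mean = {g: (raw_mean[g] - raw_mean[add]) / denom for g in groups}
    norm_sd = {g: raw_sd[g] / abs(denom) for g in groups}
    return OverallFCTrend(list(groups), raw_mean, raw_sd, norm_mean, norm_sd)
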