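"""Synthetic multi-group resting-state cohort with planted WM connectivity deficits.

Generates everything the downstream pipeline consumes — per-subject ROI
time series, rigid-body motion tables with censorable spikes, a cohort
table with demographic covariates and neuropsychological scores — from a
known ground truth, so every stage can be validated without real data.

Signal model: each subject's ROI time series is a zero-mean stationary
Gaussian multivariate series whose population correlation matrix equals
the subject's group target.  The target starts from an equicorrelation
base and subtracts a group-specific delta on a configured set of
WM-involving edges (the planted deficit).  Neuropsychological scores are
affine functions of the group's true overall-FC plus Gaussian noise,
clipped to each instrument's plausible range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import RoiRegistry, load_registry
from .roi_extraction import MOTION_COLUMNS, RoiTimeSeries

__all__ = [
    "GROUP_ORDER",
    "SCORE_COLUMNS",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "default_deficit_edges",
    "simulate_cohort",
    "inject_motion",
    "make_synthetic_images",
]

#: clinical stages in order of disease severity
GROUP_ORDER = ("CN", "SMC", "eMCI", "MCI", "lMCI", "ADD")

SCORE_COLUMNS = ["MMSE", "CDR_global", "CDR_SOB", "GDS", "FAQ",
                 "WMS_LMII", "ADAS_Cog", "Hachinski"]

# score anchors: (value at CN-level overall-FC, value at ADD-level overall-FC,
# residual SD, (clip lo, clip hi)).  Anchors follow typical clinical ranges for
# an elderly cohort spanning normal cognition to dementia.  GDS and Hachinski
# are generated FC-independent (flat anchors): neither tracks AD-specific
# connectivity decline.
SCORE_MODELS: dict[str, tuple[float, float, float, tuple[float, float]]] = {
    "MMSE": (29.1, 22.4, 1.7, (0.0, 30.0)),
    "CDR_global": (0.0, 0.8, 0.2, (0.0, 3.0)),
    "CDR_SOB": (0.3, 4.7, 1.0, (0.0, 18.0)),
    "GDS": (1.2, 1.2, 1.5, (0.0, 15.0)),
    "FAQ": (1.0, 14.6, 3.7, (0.0, 30.0)),
    "WMS_LMII": (15.4, 4.5, 3.3, (0.0, 25.0)),
    "ADAS_Cog": (9.6, 22.7, 4.4, (0.0, 70.0)),
    "Hachinski": (0.7, 0.7, 0.8, (0.0, 12.0)),
}

#: default correlation reduction per group on deficit edges — graded with
#: disease severity, with clearly separated late stages
DEFAULT_DEFICIT_DELTAS = {
    "CN": 0.0, "SMC": 0.02, "eMCI": 0.05, "MCI": 0.08, "lMCI": 0.15, "ADD": 0.25,
}


def default_deficit_edges(n_wm: int, n_total: int, n_tracts: int = 5,
                          n_partners: int = 20) -> tuple[tuple[int, int], ...]:
    """Deficit edges concentrated on a few WM tracts.

    Returns (wm_index, partner_index) pairs in the combined ROI ordering
    (WM block first): the first ``n_tracts`` WM rows each paired with the
    first ``n_partners`` non-WM partners (for a WM-only registry subset,
    the remaining WM ROIs serve as partners instead).
    """
    n_tracts = min(n_tracts, n_wm)
    partners = [j for j in range(n_wm, n_total)][:n_partners]
    if not partners:
        partners = [j for j in range(n_tracts, n_wm)][:n_partners]
    return tuple((i, j) for i in range(n_tracts) for j in partners if j != i)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate an ADNI-like resting-state protocol (140 frames at
    TR = 3 s) with a modest equicorrelation baseline and a stage-graded
    planted deficit on a small set of WM edges.
    """

    groups: tuple[str, ...] = GROUP_ORDER
    n_per_group: int | dict[str, int] = 30
    n_frames: int = 140
    tr_seconds: float = 3.0
    n_wm: int = 48
    n_gm: int = 82
    base_correlation: float = 0.2
    deficit_edges: tuple[tuple[int, int], ...] | None = None
    deficit_delta_by_group: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEFICIT_DELTAS))
    motion_spike_rate: float = 0.03
    spike_translation_mm: float = 0.8
    spike_artifact_amplitude: float = 3.0
    ar_coefficient: float = 0.0
    score_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0 or self.n_wm <= 0 or self.n_gm < 0:
            raise ValueError("counts must be positive")
        counts = self.counts_by_group()
        if any(c <= 0 for c in counts.values()):
            raise ValueError("n_per_group must be positive for every group")
        if not 0 <= self.base_correlation < 1:
            raise ValueError("base_correlation must lie in [0, 1)")
        for g, d in self.deficit_delta_by_group.items():
            if d < 0 or d > self.base_correlation + 1:
                raise ValueError(f"deficit delta for {g} out of range")
        if not 0 <= self.motion_spike_rate < 1:
            raise ValueError("motion_spike_rate must lie in [0, 1)")
        if self.deficit_edges is None:
            self.deficit_edges = default_deficit_edges(self.n_wm, self.n_roi)
        for i, j in self.deficit_edges:
            if not (0 <= i < self.n_wm and 0 <= j < self.n_roi and i != j):
                raise ValueError(f"deficit edge ({i}, {j}) out of range")

    @property
    def n_roi(self) -> int:
        return self.n_wm + self.n_gm

    def counts_by_group(self) -> dict[str, int]:
        if isinstance(self.n_per_group, dict):
            return {g: int(self.n_per_group.get(g, 0)) for g in self.groups}
        return {g: int(self.n_per_group) for g in self.groups}

    def registry(self) -> RoiRegistry:
        full = load_registry()
        wm = full.wm_abbreviations[: self.n_wm]
        gm = full.gm_abbreviations[: self.n_gm]
        if len(wm) < self.n_wm or len(gm) < self.n_gm:
            raise ValueError("registry subset larger than packaged registry")
        return full.subset(wm + gm)


@dataclass
class GroundTruth:
    """What the generator planted: group target correlation matrices,
    deficit edges, and the affine score model (intercept, slope) mapping
    true overall-FC to each neuropsychological score."""

    true_fc_matrix_by_group: dict[str, np.ndarray]
    deficit_edges: tuple[tuple[int, int], ...]
    score_coefficients: dict[str, tuple[float, float]]
    true_overall_fc_by_group: dict[str, float]
    roi_order: list[str]

    def to_json(self) -> str:
        payload = {
            "roi_order": self.roi_order,
            "deficit_edges": [list(e) for e in self.deficit_edges],
            "score_coefficients": {k: list(v) for k, v in self.score_coefficients.items()},
            "true_overall_fc_by_group": self.true_overall_fc_by_group,
            "true_fc_matrix_by_group": {
                g: np.round(m, 10).tolist() for g, m in self.true_fc_matrix_by_group.items()
            },
        }
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticCohort:
    subjects: list[str]
    series: dict[str, RoiTimeSeries]
    motion: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    truth: GroundTruth
    registry: RoiRegistry

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
        (outdir / "motion").mkdir(parents=True, exist_ok=True)
        for sid in self.subjects:
            self.series[sid].write_tsv(outdir / "timeseries" / f"{sid}.tsv")
            self.motion[sid].to_csv(outdir / "motion" / f"{sid}.tsv",
                                    sep="\t", index=False, float_format="%.8g")
        self.cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        (outdir / "ground_truth.json").write_text(self.truth.to_json())


# ---------------------------------------------------------------------------
# target correlation matrices
# ---------------------------------------------------------------------------

def _repair_psd(R: np.ndarray, group: str, max_shift: float = 0.05,
                eig_floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal.

    Refuses (hard error naming the group) if the repair moves any entry by
    more than ``max_shift``.
    """
    w, V = np.linalg.eigh(R)
    if w.min() >= eig_floor:
        return R
    w_clipped = np.clip(w, eig_floor, None)
    R2 = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    shift = np.abs(R2 - R).max()
    if shift > max_shift:
        raise ValueError(
            f"target correlation matrix for group {group!r} is not positive "
            f"semi-definite and PSD repair moved an entry by {shift:.3f} > {max_shift}"
        )
    return R2


def _is_bipartite_block(edges) -> tuple[bool, list[int], list[int]]:
    rows = sorted({i for i, _ in edges})
    cols = sorted({j for _, j in edges})
    if set(rows) & set(cols):
        return False, rows, cols
    block = {(i, j) for i in rows for j in cols}
    return set(edges) == block, rows, cols


def _group_target(config: SimulationConfig, group: str) -> np.ndarray:
    """Target correlation matrix for one group.

    When the deficit edges form a complete bipartite tract x partner block,
    the deficit is planted through a rank-one contrast (+1 on deficit
    tracts, -1 on partners): cross edges drop by exactly delta, all other
    tract-partner entries stay at the base level, and positive
    semi-definiteness is guaranteed by construction (the side effects are
    confined to the within-tract and within-partner blocks).  Arbitrary
    edge sets fall back to direct entry subtraction with eigenvalue-clip
    repair, refused if the repair distorts any entry by more than 0.05.
    """
    n = config.n_roi
    R = np.full((n, n), config.base_correlation)
    np.fill_diagonal(R, 1.0)
    delta = config.deficit_delta_by_group.get(group, 0.0)
    if delta == 0.0 or not config.deficit_edges:
        return _repair_psd(R, group)
    is_block, rows, cols = _is_bipartite_block(config.deficit_edges)
    if is_block:
        if delta > 1.0 - config.base_correlation:
            raise ValueError(
                f"group {group!r}: deficit delta {delta} exceeds "
                f"1 - base_correlation; target would not be positive "
                f"semi-definite")
        w = np.zeros(n)
        w[rows] = 1.0
        w[cols] = -1.0
        A = delta * np.outer(w, w)
        np.fill_diagonal(A, 0.0)
        R = R + A
        return _repair_psd(R, group)
    for i, j in config.deficit_edges:
        R[i, j] = R[j, i] = config.base_correlation - delta
    return _repair_psd(R, group)


def _true_overall_fc(R: np.ndarray, n_wm: int) -> float:
    """Mean of the WM-involving FCM elements (WM x non-WM block plus the
    WM x WM off-diagonal) of a target matrix."""
    wg = R[:n_wm, n_wm:]
    ww = R[:n_wm, :n_wm]
    off = ww[~np.eye(n_wm, dtype=bool)]
    if wg.size:
        return float(np.concatenate([wg.ravel(), off]).mean())
    return float(off.mean())


# ---------------------------------------------------------------------------
# per-subject generation
# ---------------------------------------------------------------------------

def _simulate_series(L: np.ndarray, n_frames: int, ar: float,
                     rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n_frames, L.shape[0]))
    if ar:
        for t in range(1, n_frames):
            z[t] = ar * z[t - 1] + np.sqrt(1 - ar**2) * z[t]
    return z @ L.T


def _baseline_motion(n_frames: int, rng: np.random.Generator) -> np.ndarray:
    steps = np.hstack([
        rng.normal(0.0, 0.01, size=(n_frames, 3)),   # translations, mm
        rng.normal(0.0, 0.0002, size=(n_frames, 3)),  # rotations, radians
    ])
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def inject_motion(series: RoiTimeSeries, motion: pd.DataFrame,
                  spike_frames: list[int] | np.ndarray,
                  translation_mm: float = 0.8,
                  artifact_amplitude: float = 3.0) -> tuple[RoiTimeSeries, pd.DataFrame]:
    """Plant motion spikes: a persistent translation step in the motion
    table at each spike frame (so FD at that frame equals ``translation_mm``)
    and an additive signal artifact on every ROI at those frames.

    Returns new objects; the inputs are not modified.  With no spike frames
    the series is returned unchanged.
    """
    spike_frames = np.asarray(spike_frames, dtype=int)
    if spike_frames.size == 0:
        return series, motion
    n = series.n_frames
    if spike_frames.min() < 0 or spike_frames.max() >= n:
        raise IndexError("spike frame index out of range")
    values = series.values.copy()
    m = motion.to_numpy(dtype=float).copy()
    for t in spike_frames:
        values[t] += artifact_amplitude
        m[t:, 0] += translation_mm  # persistent x-translation step at frame t
    new_series = RoiTimeSeries(values, list(series.roi_order),
                               retained=series.retained.copy(),
                               tr_seconds=series.tr_seconds, subject=series.subject)
    return new_series, pd.DataFrame(m, columns=MOTION_COLUMNS)


def _simulate_scores(overall_fc: float, coeffs: dict[str, tuple[float, float]],
                     noise_scale: float, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name, (a, b) in coeffs.items():
        _, _, sd, (lo, hi) = SCORE_MODELS[name]
        raw = a + b * overall_fc + rng.normal(0.0, sd * noise_scale)
        out[name] = float(np.clip(raw, lo, hi))
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort from the configured conditions.

    Fully reproducible from ``config.seed``: the master seed is expanded
    into independent per-stage streams, so e.g. changing the motion spike
    rate does not perturb the BOLD signals.
    """
    registry = config.registry()
    counts = config.counts_by_group()

    targets = {g: _group_target(config, g) for g in config.groups}
    chol = {g: np.linalg.cholesky(targets[g]) for g in config.groups}
    true_fc = {g: _true_overall_fc(targets[g], config.n_wm) for g in config.groups}

    # affine score model anchored at the CN and ADD true overall-FC levels
    f_cn = true_fc.get("CN", max(true_fc.values()))
    f_add = true_fc.get("ADD", min(true_fc.values()))
    coeffs: dict[str, tuple[float, float]] = {}
    for name, (v_cn, v_add, _sd, _clip) in SCORE_MODELS.items():
        if abs(f_cn - f_add) < 1e-12 or v_cn == v_add:
            coeffs[name] = (float((v_cn + v_add) / 2), 0.0)
        else:
            b = (v_cn - v_add) / (f_cn - f_add)
            coeffs[name] = (float(v_cn - b * f_cn), float(b))

    truth = GroundTruth(
        true_fc_matrix_by_group=targets,
        deficit_edges=tuple(tuple(e) for e in config.deficit_edges),
        score_coefficients=coeffs,
        true_overall_fc_by_group=true_fc,
        roi_order=registry.abbreviations,
    )

    ss = np.random.SeedSequence(config.seed)
    rng_signal, rng_motion, rng_scores, rng_covar = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4))

    subjects: list[str] = []
    series: dict[str, RoiTimeSeries] = {}
    motion: dict[str, pd.DataFrame] = {}
    rows: list[dict] = []
    sites = np.array(["S", "G", "P"])
    k = 0
    for g in config.groups:
        for _ in range(counts[g]):
            sid = f"sub-{k:04d}"
            k += 1
            values = _simulate_series(chol[g], config.n_frames,
                                      config.ar_coefficient, rng_signal)
            ts = RoiTimeSeries(values, registry.abbreviations,
                               tr_seconds=config.tr_seconds, subject=sid)
            mtab = pd.DataFrame(_baseline_motion(config.n_frames, rng_motion),
                                columns=MOTION_COLUMNS)
            spikes = np.flatnonzero(
                rng_motion.random(config.n_frames) < config.motion_spike_rate)
            spikes = spikes[spikes > 0]
            ts, mtab = inject_motion(ts, mtab, spikes,
                                     translation_mm=config.spike_translation_mm,
                                     artifact_amplitude=config.spike_artifact_amplitude)
            subjects.append(sid)
            series[sid] = ts
            motion[sid] = mtab

            scores = _simulate_scores(true_fc[g], coeffs,
                                      config.score_noise_scale, rng_scores)
            age = float(np.clip(rng_covar.normal(74.5, 7.0), 60, 90))
            row = {
                "subject_id": sid, "group": g,
                "age": round(age, 1),
                "sex": int(rng_covar.random() < 0.53),
                "education": int(np.clip(round(rng_covar.normal(16.5, 2.6)), 8, 20)),
                "site": str(rng_covar.choice(sites, p=[0.45, 0.2, 0.35])),
            }
            row.update({s: round(scores[s], 2) for s in SCORE_COLUMNS})
            rows.append(row)

    cohort = pd.DataFrame(rows)
    return SyntheticCohort(subjects, series, motion, cohort, truth, registry)


# ---------------------------------------------------------------------------
# tiny NIfTI volumes for end-to-end image-path testing
# ---------------------------------------------------------------------------

def make_synthetic_images(series: RoiTimeSeries, registry: RoiRegistry,
                          voxels_per_roi: int = 2, noise_sd: float = 0.05,
                          seed: int = 0):
    """Pack an ROI time series into tiny NIfTI volumes.

    Each ROI occupies ``voxels_per_roi`` voxels in a minimal 3D grid; every
    voxel carries its ROI's signal plus independent Gaussian noise.  Returns
    ``(bold_img, label_img, prob_imgs)`` where ``prob_imgs`` maps "WM"/"GM"
    to probability volumes (0.9 inside the tissue's ROIs, 0.1 elsewhere).
    """
    import nibabel as nib

    rng = np.random.default_rng(seed)
    n_roi = len(registry)
    n_vox_needed = n_roi * voxels_per_roi
    nx = int(np.ceil(n_vox_needed ** (1 / 3)))
    shape = (nx, nx, int(np.ceil(n_vox_needed / nx**2)))
    n_vox = int(np.prod(shape))

    labels = np.zeros(n_vox, dtype=np.int16)
    prob = {"WM": np.full(n_vox, 0.1), "GM": np.full(n_vox, 0.1)}
    bold = np.zeros((n_vox, series.n_frames))
    v = 0
    for i, entry in enumerate(registry):
        sig = series.values[:, i]
        for _ in range(voxels_per_roi):
            labels[v] = entry.label
            prob[entry.tissue][v] = 0.9
            bold[v] = sig + rng.normal(0.0, noise_sd, size=series.n_frames)
            v += 1

    affine = np.eye(4) * 2.0
    affine[3, 3] = 1.0
    bold_img = nib.Nifti1Image(bold.reshape(*shape, series.n_frames), affine)
    bold_img.header.set_zooms((2.0, 2.0, 2.0, series.tr_seconds))
    label_img = nib.Nifti1Image(labels.reshape(shape), affine)
    prob_imgs = {t: nib.Nifti1Image(p.reshape(shape).astype(np.float32), affine)
                 for t, p in prob.items()}
    return bold_img, label_img, prob_imgs
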