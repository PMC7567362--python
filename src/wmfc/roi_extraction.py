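"""ROI time-course extraction from MNI-space images or voxel signal arrays.

Turns 4D BOLD data into per-ROI mean time courses: atlas labels are
constrained by tissue-probability masks, voxel signals optionally pass
through a temporal-cleaning stage (detrend, 24-parameter motion + CSF
nuisance regression, band-pass, z-normalization), and voxels are averaged
within each ROI.  Head motion is summarized as framewise displacement (FD)
for downstream frame censoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .registry import RoiRegistry

__all__ = [
    "CleaningConfig",
    "RoiTimeSeries",
    "framewise_displacement",
    "build_masks",
    "clean_timeseries",
    "extract_roi_means",
    "extract_from_images",
    "read_roi_timeseries_tsv",
    "read_motion_tsv",
]

logger = logging.getLogger("wmfc")

#: head-radius (mm) used to convert rotation angles to arc displacement
HEAD_RADIUS_MM = 50.0

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class CleaningConfig:
    """Temporal-cleaning settings.

    Defaults follow the standard resting-state protocol: 0.01-0.1 Hz
    band-pass, Friston 24-parameter motion regression plus mean CSF signal,
    tissue-probability threshold 0.8 and FD censoring threshold 0.5 mm.
    """

    bandpass_hz: tuple[float, float] = (0.01, 0.1)
    use_motion24: bool = True
    use_csf: bool = True
    probability_threshold: float = 0.8
    fd_threshold: float = 0.5
    butterworth_order: int = 4

    def __post_init__(self) -> None:
        low, high = self.bandpass_hz
        if not 0 < low < high:
            raise ValueError(f"invalid band-pass ({low}, {high}): need 0 < low < high")
        if not 0 < self.probability_threshold < 1:
            raise ValueError("probability_threshold must lie in (0, 1)")
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")


@dataclass
class RoiTimeSeries:
    """Frames x ROIs matrix of mean BOLD signals with a frame-retention mask.

    ``values`` holds z-scored signals (empty-ROI columns are NaN); ``retained``
    marks frames that survive censoring (all True until FD censoring is
    applied downstream).
    """

    values: np.ndarray
    roi_order: list[str]
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]
    tr_seconds: float = 3.0
    subject: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a frames x ROIs matrix")
        if self.values.shape[1] != len(self.roi_order):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.roi_order)} ROI labels"
            )
        if self.retained is None:
            self.retained = np.ones(self.values.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.values.shape[0],):
            raise ValueError("retained mask length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.roi_order)
        df["retained"] = self.retained.astype(int)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_roi_timeseries_tsv(path: str | Path, tr_seconds: float = 3.0,
                            subject: str | None = None) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    retained = None
    if "retained" in df.columns:
        retained = df.pop("retained").to_numpy(dtype=bool)
    return RoiTimeSeries(df.to_numpy(dtype=float), list(df.columns),
                         retained=retained, tr_seconds=tr_seconds, subject=subject)


def read_motion_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, found {df.shape[1]}")
    df.columns = MOTION_COLUMNS
    return df


# ---------------------------------------------------------------------------
# framewise displacement
# ---------------------------------------------------------------------------

def framewise_displacement(motion: np.ndarray | pd.DataFrame,
                           head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Per-frame framewise displacement in mm.

    FD(t) = sum |delta translation_i| + r * sum |delta rotation_i| for
    backward differences, with rotations (radians) converted to arc length
    on a sphere of radius ``head_radius_mm``; FD(0) = 0 by convention.
    Columns must be 3 translations (mm) then 3 rotations (radians).
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must be frames x 6, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(m, axis=0))
    fd = np.zeros(m.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def build_masks(labels: np.ndarray,
                probability: np.ndarray | dict[str, np.ndarray],
                registry: RoiRegistry,
                threshold: float = 0.8) -> dict[str, np.ndarray]:
    """Per-ROI flat voxel index sets from an atlas label volume.

    A voxel belongs to ROI ``r`` iff its label equals ``r``'s label value
    and its tissue probability exceeds ``threshold``.  ``probability`` may be
    a single volume or a ``{"WM": vol, "GM": vol}`` pair so each ROI is
    constrained by its own tissue class.  Empty ROIs are kept (flagged with
    a warning) so matrix shapes stay fixed.
    """
    labels = np.asarray(labels)
    if isinstance(probability, dict):
        prob_by_tissue = {k: np.asarray(v, dtype=float) for k, v in probability.items()}
    else:
        p = np.asarray(probability, dtype=float)
        prob_by_tissue = {"WM": p, "GM": p}
    for tissue, p in prob_by_tissue.items():
        if p.shape != labels.shape:
            raise ValueError(
                f"{tissue} probability volume shape {p.shape} does not match "
                f"label volume shape {labels.shape}"
            )
    flat_labels = labels.ravel()
    masks: dict[str, np.ndarray] = {}
    empty: list[str] = []
    for entry in registry:
        prob = prob_by_tissue[entry.tissue].ravel()
        idx = np.flatnonzero((flat_labels == entry.label) & (prob > threshold))
        masks[entry.abbreviation] = idx
        if idx.size == 0:
            empty.append(entry.abbreviation)
    if empty:
        msg = f"{len(empty)} empty ROI mask(s): {', '.join(empty[:10])}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return masks


# ---------------------------------------------------------------------------
# temporal cleaning
# ---------------------------------------------------------------------------

def _motion24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion: params, 1-frame-lagged params,
    and the squares of both (lagged rows zero-padded at frame 0)."""
    m = np.asarray(motion, dtype=float)
    lag = np.vstack([np.zeros((1, m.shape[1])), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns until the design is full rank (QR pivot order)."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, names
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
    logger.warning("rank-deficient nuisance design; dropping columns: %s", dropped)
    warnings.warn(f"dropped collinear nuisance columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[i] for i in keep]


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Column-wise zero mean, unit variance; constant columns become NaN."""
    x = np.asarray(x, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = np.nan
    return z


def bandpass_filter(x: np.ndarray, low_hz: float, high_hz: float,
                    tr_seconds: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along axis 0."""
    nyquist = 0.5 / tr_seconds
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=1.0 / tr_seconds, output="sos")
    return sp_signal.sosfiltfilt(sos, x, axis=0)


def clean_timeseries(voxel_signals: np.ndarray,
                     motion: np.ndarray | pd.DataFrame | None,
                     csf: np.ndarray | None,
                     config: CleaningConfig,
                     tr_seconds: float,
                     normalize: bool = True,
                     bandpass: bool = True) -> np.ndarray:
    """Detrend, regress out nuisance signals, band-pass and z-normalize.

    Order of operations: linear detrend and OLS removal of nuisance
    regressors (24-parameter motion expansion and/or mean CSF signal),
    performed as one projection so the step is exactly idempotent ->
    zero-phase band-pass -> column z-normalization.  Returns a new
    frames x voxels array.
    """
    x = np.asarray(voxel_signals, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]

    # linear detrend expressed as part of the nuisance design
    trend = np.linspace(-1.0, 1.0, n).reshape(-1, 1)
    regs: list[np.ndarray] = [trend]
    names: list[str] = ["trend"]
    if config.use_motion24 and motion is not None:
        m = np.asarray(motion, dtype=float)
        if m.shape != (n, 6):
            raise ValueError(f"motion table must be {n} x 6, got {m.shape}")
        regs.append(_motion24(m))
        names += [f"motion24_{i}" for i in range(24)]
    if config.use_csf and csf is not None:
        c = np.asarray(csf, dtype=float).reshape(-1, 1)
        if c.shape[0] != n:
            raise ValueError("CSF regressor length must equal frame count")
        regs.append(c)
        names.append("csf")
    X = np.hstack([np.ones((n, 1))] + regs)
    names = ["intercept"] + names
    X, names = _drop_collinear(X, names)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    x = x - X @ beta

    if bandpass:
        low, high = config.bandpass_hz
        x = bandpass_filter(x, low, high, tr_seconds, order=config.butterworth_order)

    if normalize:
        x = zscore_columns(x)
    return x


# ---------------------------------------------------------------------------
# ROI averaging
# ---------------------------------------------------------------------------

def extract_roi_means(voxel_signals: np.ndarray,
                      masks: dict[str, np.ndarray],
                      registry: RoiRegistry,
                      tr_seconds: float = 3.0,
                      subject: str | None = None,
                      renormalize: bool = True) -> RoiTimeSeries:
    """Average voxel signals within each ROI, in registry order.

    Empty-ROI columns are NaN and must be skipped downstream.  Columns are
    re-z-normalized after averaging by default so each ROI time course has
    zero mean and unit variance.
    """
    x = np.asarray(voxel_signals, dtype=float)
    n_frames = x.shape[0]
    cols = []
    for entry in registry:
        idx = masks.get(entry.abbreviation, np.empty(0, dtype=int))
        if len(idx) == 0:
            cols.append(np.full(n_frames, np.nan))
        else:
            cols.append(x[:, idx].mean(axis=1))
    values = np.column_stack(cols)
    if renormalize:
        values = zscore_columns(values)
    return RoiTimeSeries(values, registry.abbreviations,
                         tr_seconds=tr_seconds, subject=subject)


def extract_from_images(bold_img, label_img, probability_imgs,
                        registry: RoiRegistry,
                        config: CleaningConfig | None = None,
                        motion: np.ndarray | pd.DataFrame | None = None,
                        csf_label: int | None = None,
                        tr_seconds: float | None = None,
                        subject: str | None = None,
                        clean: bool = True) -> RoiTimeSeries:
    """End-to-end extraction from NIfTI images (nibabel image objects).

    ``probability_imgs`` is ``{"WM": img, "GM": img}`` (optionally with a
    ``"CSF"`` entry used, together with ``csf_label`` = None, to build the
    mean-CSF nuisance regressor from voxels with CSF probability > threshold).
    """
    import nibabel as nib  # local import: only needed on the image path

    config = config or CleaningConfig()
    bold = np.asanyarray(bold_img.dataobj, dtype=float)
    if bold.ndim != 4:
        raise ValueError("BOLD image must be 4D")
    labels = np.asanyarray(label_img.dataobj)
    if labels.shape != bold.shape[:3]:
        raise ValueError("label volume grid does not match BOLD grid")
    if not np.allclose(label_img.affine, bold_img.affine, atol=1e-4):
        raise ValueError("label volume affine does not match BOLD affine")
    prob_vols = {}
    for tissue, img in probability_imgs.items():
        vol = np.asanyarray(img.dataobj, dtype=float)
        if vol.shape != bold.shape[:3]:
            raise ValueError(f"{tissue} probability grid does not match BOLD grid")
        prob_vols[tissue] = vol
    if tr_seconds is None:
        tr_seconds = float(bold_img.header.get_zooms()[3]) or 3.0

    voxel_signals = bold.reshape(-1, bold.shape[3]).T  # frames x voxels
    masks = build_masks(labels, {k: v for k, v in prob_vols.items() if k != "CSF"},
                        registry, config.probability_threshold)
    csf = None
    if "CSF" in prob_vols:
        csf_idx = np.flatnonzero(prob_vols["CSF"].ravel() > config.probability_threshold)
        if csf_idx.size:
            csf = voxel_signals[:, csf_idx].mean(axis=1)
    if clean:
        voxel_signals = clean_timeseries(voxel_signals, motion, csf, config, tr_seconds)
    return extract_roi_means(voxel_signals, masks, registry,
                             tr_seconds=tr_seconds, subject=subject)
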