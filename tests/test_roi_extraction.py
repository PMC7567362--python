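"""Masking, framewise displacement, temporal cleaning and ROI averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmfc import (CleaningConfig, build_masks, clean_timeseries,
                  extract_from_images, extract_roi_means,
                  framewise_displacement, load_registry)
from wmfc.registry import RoiEntry, RoiRegistry
from wmfc.roi_extraction import RoiTimeSeries, bandpass_filter, zscore_columns


def small_registry():
    return RoiRegistry([
        RoiEntry("Wa", "tract a", "WM", "left", 1),
        RoiEntry("Wb", "tract b", "WM", "right", 2),
        RoiEntry("Ga", "area a", "GM", "left", 3),
    ])


# ---------------------------------------------------------------------------
# framewise displacement
# ---------------------------------------------------------------------------

def test_fd_constant_motion_is_zero():
    fd = framewise_displacement(np.ones((20, 6)) * 0.3)
    assert np.all(fd == 0.0)


def test_fd_translation_step():
    m = np.zeros((10, 6))
    m[5:, 0] = 0.6  # persistent 0.6 mm x step at frame 5
    fd = framewise_displacement(m)
    assert fd[5] == pytest.approx(0.6)
    assert np.sum(fd) == pytest.approx(0.6)


def test_fd_rotation_conversion():
    """0.01 rad on one axis -> 50 mm x 0.01 = 0.5 mm displacement."""
    m = np.zeros((5, 6))
    m[2:, 4] = 0.01
    fd = framewise_displacement(m)
    assert fd[2] == pytest.approx(0.5)


def test_fd_first_frame_zero_and_shape_checks():
    assert framewise_displacement(np.random.rand(4, 6))[0] == 0.0
    with pytest.raises(ValueError):
        framewise_displacement(np.zeros((5, 7)))
    with pytest.raises(ValueError):
        framewise_displacement(np.zeros((1, 6)))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_masks_threshold_zero_matches_labels():
    reg = small_registry()
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, 0, :3] = 1
    labels[1, 1, 0] = 2
    masks = build_masks(labels, np.ones_like(labels, dtype=float) * 0.99,
                        reg, threshold=0.0)
    assert len(masks["Wa"]) == 3
    assert len(masks["Wb"]) == 1


def test_masks_probability_constraint_hand_enumerated():
    """3 labelled voxels, one below the probability cutoff -> mask size 2."""
    reg = small_registry()
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, 0, 0] = labels[0, 0, 1] = labels[0, 0, 2] = 1
    prob = np.zeros((4, 4, 4))
    prob[0, 0, 0] = 0.9
    prob[0, 0, 1] = 0.85
    prob[0, 0, 2] = 0.5  # below 0.8
    masks = build_masks(labels, prob, reg, threshold=0.8)
    assert len(masks["Wa"]) == 2


def test_masks_tissue_specific_probability():
    reg = small_registry()
    labels = np.zeros((2, 2, 2), dtype=int)
    labels[0, 0, 0] = 1  # WM label
    labels[0, 0, 1] = 3  # GM label
    wm_p = np.zeros((2, 2, 2)); wm_p[0, 0, 0] = 0.9
    gm_p = np.zeros((2, 2, 2))  # GM probability never passes
    masks = build_masks(labels, {"WM": wm_p, "GM": gm_p}, reg, 0.8)
    assert len(masks["Wa"]) == 1
    assert len(masks["Ga"]) == 0


def test_masks_empty_roi_flagged():
    reg = small_registry()
    labels = np.zeros((2, 2, 2), dtype=int)
    with pytest.warns(UserWarning, match="empty ROI"):
        masks = build_masks(labels, np.ones((2, 2, 2)) * 0.9, reg, 0.8)
    assert all(len(v) == 0 for v in masks.values())


def test_masks_grid_mismatch_is_hard_error():
    reg = small_registry()
    with pytest.raises(ValueError, match="shape"):
        build_masks(np.zeros((2, 2, 2), dtype=int), np.ones((3, 3, 3)), reg, 0.5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=0.05, max_value=0.9),
       st.floats(min_value=0.0, max_value=0.85))
def test_mask_monotonicity(thr_hi, thr_lo):
    """Raising the probability threshold never adds voxels to any mask."""
    if thr_lo > thr_hi:
        thr_lo, thr_hi = thr_hi, thr_lo
    reg = small_registry()
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, size=(5, 5, 5))
    prob = rng.random((5, 5, 5))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = build_masks(labels, prob, reg, thr_lo)
        hi = build_masks(labels, prob, reg, thr_hi)
    for a in reg.abbreviations:
        assert set(hi[a]) <= set(lo[a])


# ---------------------------------------------------------------------------
# temporal cleaning
# ---------------------------------------------------------------------------

def test_nuisance_regressor_fully_removed():
    """A signal equal to a nuisance regressor leaves ~zero residual."""
    rng = np.random.default_rng(1)
    n = 200
    motion = np.cumsum(rng.normal(0, 0.01, (n, 6)), axis=0)
    sig = motion[:, [2]].copy()
    cfg = CleaningConfig(use_csf=False)
    out = clean_timeseries(sig, motion, None, cfg, tr_seconds=2.0, normalize=False)
    assert np.sqrt(np.mean(out**2)) < 1e-8 * max(1.0, np.abs(sig).max())


def test_slow_drift_attenuated():
    """A pure 0.005 Hz drift (below the 0.01 Hz band edge) is attenuated
    by at least 95% by the zero-phase band-pass."""
    tr = 2.0
    t = np.arange(600) * tr
    drift = np.sin(2 * np.pi * 0.005 * t)[:, None]
    out = bandpass_filter(drift, 0.01, 0.1, tr)
    # steady-state amplitude away from the filter edges
    core = slice(100, 500)
    assert np.abs(out[core]).max() < 0.05 * np.abs(drift[core]).max()


def test_passband_frequency_preserved():
    tr = 2.0
    t = np.arange(600) * tr
    wave = np.sin(2 * np.pi * 0.05 * t)[:, None]
    out = bandpass_filter(wave, 0.01, 0.1, tr)
    core = slice(100, 500)
    assert np.abs(out[core]).max() > 0.9


def test_white_noise_normalization_contract():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(300, 5))
    cfg = CleaningConfig(use_motion24=False, use_csf=False)
    out = clean_timeseries(x, None, None, cfg, tr_seconds=2.0)
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(out.var(axis=0), 1.0, atol=1e-6)


def test_nuisance_projection_idempotent():
    """Detrending + nuisance regression is a projection: applying it to an
    already-projected signal changes it by < 1e-8 RMS (band-pass disabled,
    which is a smoothing filter rather than a projection)."""
    rng = np.random.default_rng(3)
    n = 400
    x = rng.normal(size=(n, 3))
    motion = np.cumsum(rng.normal(0, 0.01, (n, 6)), axis=0)
    csf = rng.normal(size=n)
    cfg = CleaningConfig()
    once = clean_timeseries(x, motion, csf, cfg, tr_seconds=2.0,
                            normalize=False, bandpass=False)
    twice = clean_timeseries(once, motion, csf, cfg, tr_seconds=2.0,
                             normalize=False, bandpass=False)
    rms = np.sqrt(np.mean((twice - once) ** 2))
    assert rms < 1e-8 * max(1.0, np.sqrt(np.mean(once**2)))


def test_collinear_nuisance_columns_dropped():
    rng = np.random.default_rng(4)
    n = 100
    motion = np.zeros((n, 6))
    motion[:, 0] = rng.normal(size=n)
    # remaining columns constant -> squares/lags collinear with intercept
    cfg = CleaningConfig(use_csf=False)
    with pytest.warns(UserWarning, match="collinear"):
        out = clean_timeseries(rng.normal(size=(n, 2)), motion, None, cfg, 2.0)
    assert np.isfinite(out).all()


def test_bandpass_invalid_band():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros((50, 1)), 0.1, 0.01, 2.0)
    with pytest.raises(ValueError):
        # high edge above Nyquist for TR=3 s (0.167 Hz)
        bandpass_filter(np.zeros((50, 1)), 0.01, 0.2, 3.0)


# ---------------------------------------------------------------------------
# ROI averaging
# ---------------------------------------------------------------------------

def test_single_voxel_roi_identity():
    reg = small_registry()
    rng = np.random.default_rng(5)
    sig = rng.normal(size=(50, 4))
    masks = {"Wa": np.array([1]), "Wb": np.array([2, 3]), "Ga": np.array([0])}
    ts = extract_roi_means(sig, masks, reg, renormalize=False)
    np.testing.assert_allclose(ts.values[:, 0], sig[:, 1])
    np.testing.assert_allclose(ts.values[:, 2], sig[:, 0])


def test_identical_voxels_average_idempotent():
    reg = small_registry()
    sig = np.random.default_rng(6).normal(size=(30, 2))
    dup = np.column_stack([sig[:, 0], sig[:, 0], sig[:, 1]])
    masks = {"Wa": np.array([0, 1]), "Wb": np.array([2]), "Ga": np.array([2])}
    ts = extract_roi_means(dup, masks, reg, renormalize=False)
    np.testing.assert_allclose(ts.values[:, 0], sig[:, 0])


def test_hand_computed_roi_means():
    """3 voxels with hand-written 5-frame signals -> hand-computed means."""
    reg = small_registry()
    sig = np.array([[1.0, 2.0, 6.0],
                    [2.0, 4.0, 0.0],
                    [3.0, 6.0, 3.0],
                    [4.0, 8.0, 0.0],
                    [5.0, 10.0, 5.0]])
    masks = {"Wa": np.array([0, 1]), "Wb": np.array([2]), "Ga": np.array([0, 2])}
    ts = extract_roi_means(sig, masks, reg, renormalize=False)
    np.testing.assert_allclose(ts.values[:, 0], [1.5, 3.0, 4.5, 6.0, 7.5])
    np.testing.assert_allclose(ts.values[:, 2], [3.5, 1.0, 3.0, 2.0, 5.0])


def test_empty_mask_gives_nan_column():
    reg = small_registry()
    sig = np.random.default_rng(7).normal(size=(20, 3))
    masks = {"Wa": np.array([0]), "Wb": np.empty(0, dtype=int), "Ga": np.array([1])}
    ts = extract_roi_means(sig, masks, reg)
    assert np.isnan(ts.values[:, 1]).all()
    assert np.isfinite(ts.values[:, 0]).all()


def test_renormalized_columns_are_zscores():
    reg = small_registry()
    sig = np.random.default_rng(8).normal(2.0, 3.0, size=(100, 5))
    masks = {"Wa": np.array([0, 1]), "Wb": np.array([2]), "Ga": np.array([3, 4])}
    ts = extract_roi_means(sig, masks, reg)
    np.testing.assert_allclose(ts.values.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(ts.values.var(axis=0), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# image path end-to-end
# ---------------------------------------------------------------------------

def test_extract_from_synthetic_images():
    """Packing an ROI series into tiny NIfTI volumes and extracting it back
    recovers the planted signals (correlation ~1 per ROI)."""
    from wmfc import SimulationConfig, make_synthetic_images, simulate_cohort

    cfg = SimulationConfig(groups=("CN",), n_per_group=1, n_frames=80,
                           n_wm=3, n_gm=4, motion_spike_rate=0.0, seed=13)
    cohort = simulate_cohort(cfg)
    sid = cohort.subjects[0]
    series = cohort.series[sid]
    bold, labels, probs = make_synthetic_images(series, cohort.registry,
                                                voxels_per_roi=2, noise_sd=0.01)
    ts = extract_from_images(bold, labels, probs, cohort.registry,
                             clean=False, tr_seconds=cfg.tr_seconds)
    assert ts.values.shape == (80, 7)
    for i in range(7):
        r = np.corrcoef(ts.values[:, i], series.values[:, i])[0, 1]
        assert r > 0.99
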