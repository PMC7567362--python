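"""Permutation tests, FDR, effect sizes, tract-wise FC and the overall-FC trend."""

import itertools

import numpy as np
import pytest

from wmfc import (compare_groups, effect_size, fdr_adjust, mean_fcm,
                  overall_fc, overall_fc_trend, permutation_test,
                  significance_stars, tract_ttest, tractwise_fc)


# ---------------------------------------------------------------------------
# mean FCM
# ---------------------------------------------------------------------------

def test_mean_fcm_identical_subjects():
    m = np.random.default_rng(0).normal(size=(3, 3))
    stack = np.stack([m, m, m])
    means = mean_fcm(stack, np.array(["CN"] * 3))
    np.testing.assert_allclose(means["CN"], m)


def test_mean_fcm_arithmetic_and_nan_skip():
    stack = np.array([[[0.2]], [[0.4]], [[np.nan]]])
    means = mean_fcm(stack, np.array(["CN", "CN", "CN"]))
    assert means["CN"][0, 0] == pytest.approx(0.3)
    from wmfc.group_stats import nan_counts

    assert nan_counts(stack, np.array(["CN"] * 3))["CN"] == 1


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_identical_groups_give_p_one():
    m = np.random.default_rng(1).normal(size=(4, 2, 2))
    stack = np.concatenate([m, m])
    labels = np.array(["CN"] * 4 + ["ADD"] * 4)
    p = permutation_test(stack, labels, ("CN", "ADD"), n_perm=200, seed=0)
    np.testing.assert_array_equal(p, 1.0)


def test_monte_carlo_matches_exhaustive_enumeration():
    """4-vs-4 toy: Monte-Carlo p within +/-0.02 of the exactly enumerated
    permutation p over all 70 label splits."""
    rng = np.random.default_rng(2)
    x = np.array([0.1, 0.5, 0.3, 0.9, -0.2, -0.5, 0.0, -0.4])
    stack = x[:, None, None]
    labels = np.array(["CN"] * 4 + ["ADD"] * 4)
    obs = abs(x[:4].mean() - x[4:].mean())
    count = 0
    total = 0
    for comb in itertools.combinations(range(8), 4):
        sel = np.zeros(8, dtype=bool)
        sel[list(comb)] = True
        stat = abs(x[sel].mean() - x[~sel].mean())
        count += stat >= obs
        total += 1
    exact = count / total  # 70 splits
    p = permutation_test(stack, labels, ("CN", "ADD"), n_perm=10_000, seed=3)
    assert abs(p[0, 0] - exact) < 0.02


def test_null_calibration_on_synthetic_cohort():
    """Complete-null cohort: the element-wise rejection rate at alpha is
    within alpha + 2 binomial SE, and no element survives FDR."""
    from tests.conftest import stack_fcms
    from wmfc import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(groups=("CN", "ADD"), n_per_group=20, n_frames=120,
                           n_wm=48, n_gm=82, motion_spike_rate=0.0,
                           deficit_delta_by_group={"CN": 0.0, "ADD": 0.0},
                           seed=42)
    cohort = simulate_cohort(cfg)
    stack, labels = stack_fcms(cohort, kind="WG")
    assert stack.shape[1:] == (48, 82)
    p = permutation_test(stack, labels, ("CN", "ADD"), n_perm=2000, seed=1)
    n_el = p.size
    for alpha in (0.01, 0.05):
        rate = np.mean(p <= alpha)
        se = np.sqrt(alpha * (1 - alpha) / n_el)
        assert rate <= alpha + 2 * se + 0.01  # small slack for element dependence
    p_fdr = fdr_adjust(p)
    assert np.mean(p_fdr <= 0.05) < 0.001


def test_low_n_perm_warns():
    stack = np.random.default_rng(3).normal(size=(8, 1, 1))
    labels = np.array(["CN"] * 4 + ["ADD"] * 4)
    with pytest.warns(UserWarning, match="n_perm"):
        permutation_test(stack, labels, ("CN", "ADD"), n_perm=50, seed=0)


def test_permutation_p_positive_and_at_most_one():
    rng = np.random.default_rng(4)
    stack = rng.normal(size=(20, 3, 3)) * 0.1
    stack[:10] += 2.0  # enormous effect
    labels = np.array(["CN"] * 10 + ["ADD"] * 10)
    p = permutation_test(stack, labels, ("CN", "ADD"), n_perm=500, seed=0)
    assert np.all(p > 0) and np.all(p <= 1)
    # the +1 tie correction bounds p below by 1/(n_perm+1); a shared shuffle
    # may reproduce the observed split, so allow a count of a few
    assert np.all(p <= 4 / 501)
    assert p.min() == pytest.approx(1 / 501)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_bh_manual_step_up():
    """[0.01, 0.02, 0.03, 0.04]: step-up gives min over j>=i of p_j*m/j =
    0.04 for every entry."""
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(fdr_adjust(p), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_degenerate():
    assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
    np.testing.assert_array_equal(fdr_adjust(np.ones(5)), 1.0)


def test_bh_monotone_and_never_below_raw():
    rng = np.random.default_rng(5)
    p = rng.random((6, 7))
    adj = fdr_adjust(p)
    assert np.all(adj >= p - 1e-15)
    flat = p.ravel()
    order = np.argsort(flat)
    assert np.all(np.diff(adj.ravel()[order]) >= -1e-15)


def test_bh_passes_nan_through():
    p = np.array([0.01, np.nan, 0.5])
    adj = fdr_adjust(p)
    assert np.isnan(adj[1]) and np.isfinite(adj[0])


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def test_effect_size_zero_for_equal_means():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(30, 2, 2))
    stack = np.concatenate([a, a])
    labels = np.array(["CN"] * 30 + ["ADD"] * 30)
    d = effect_size(stack, labels, ("CN", "ADD"))
    np.testing.assert_allclose(d, 0.0, atol=1e-12)


def test_effect_size_hand_computed():
    """{1,2,3} vs {3,4,5}: pooled SD = 1, d = -2."""
    stack = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])[:, None, None]
    labels = np.array(["CN"] * 3 + ["ADD"] * 3)
    d = effect_size(stack, labels, ("CN", "ADD"))
    assert d[0, 0] == pytest.approx(-2.0)


def test_effect_size_zero_variance_is_nan():
    stack = np.ones((6, 1, 1))
    labels = np.array(["CN"] * 3 + ["ADD"] * 3)
    assert np.isnan(effect_size(stack, labels, ("CN", "ADD"))[0, 0])


def test_deficit_edges_carry_largest_effects():
    """On a simulated cohort with planted deficits, deficit edges show
    systematically larger |d| than null edges."""
    from tests.conftest import stack_fcms
    from wmfc import SimulationConfig, simulate_cohort

    edges = tuple((i, j) for i in range(2) for j in range(6, 14))
    cfg = SimulationConfig(groups=("CN", "ADD"), n_per_group=40, n_frames=200,
                           n_wm=6, n_gm=10, motion_spike_rate=0.0,
                           deficit_edges=edges,
                           deficit_delta_by_group={"CN": 0.0, "ADD": 0.25},
                           seed=8)
    cohort = simulate_cohort(cfg)
    stack, labels = stack_fcms(cohort, kind="WG")
    d = effect_size(stack, labels, ("CN", "ADD"))
    mask = np.zeros((6, 10), dtype=bool)
    for i, j in edges:
        mask[i, j - 6] = True
    null_q95 = np.quantile(np.abs(d[~mask]), 0.95)
    frac = np.mean(np.abs(d[mask]) > null_q95)
    assert frac >= 0.95


# ---------------------------------------------------------------------------
# comparison bundle
# ---------------------------------------------------------------------------

def test_thresholded_difference_matches_fdr_mask():
    rng = np.random.default_rng(9)
    stack = rng.normal(size=(30, 4, 4)) * 0.1
    stack[15:, 0, 0] -= 1.0  # one strong element
    labels = np.array(["CN"] * 15 + ["ADD"] * 15)
    comp = compare_groups(stack, labels, ("CN", "ADD"), n_perm=2000, seed=0)
    nz = comp.thresholded_difference != 0
    np.testing.assert_array_equal(nz, comp.p_fdr <= 0.05)
    assert np.all(comp.p_fdr >= comp.p_perm - 1e-15)
    assert nz[0, 0]


# ---------------------------------------------------------------------------
# tract-wise FC
# ---------------------------------------------------------------------------

def test_tractwise_constant_matrix():
    wg = np.full((4, 7), 0.3)
    np.testing.assert_allclose(tractwise_fc(wg, kind="WG"), 0.3)
    ww = np.full((4, 4), 0.3)
    np.fill_diagonal(ww, 1.0)
    np.testing.assert_allclose(tractwise_fc(ww, kind="WW"), 0.3)
    np.testing.assert_allclose(
        tractwise_fc(ww, kind="WW", include_diagonal=True),
        (0.3 * 3 + 1.0) / 4)


def test_tractwise_single_row():
    wg = np.zeros((3, 5))
    wg[1] = 0.5
    out = tractwise_fc(wg, kind="WG")
    np.testing.assert_allclose(out, [0.0, 0.5, 0.0])


def test_tractwise_hand_means():
    wg = np.array([[0.1, 0.2, 0.3, 0.4],
                   [0.0, -0.4, 0.4, 0.0],
                   [1.0, 1.0, -1.0, -1.0]])
    np.testing.assert_allclose(tractwise_fc(wg, kind="WG"), [0.25, 0.0, 0.0])


def test_tractwise_requires_wm_rows():
    with pytest.raises(ValueError):
        tractwise_fc(np.zeros((3, 3)), kind="GG")


# ---------------------------------------------------------------------------
# tract t-tests
# ---------------------------------------------------------------------------

def test_ttest_identical_groups():
    vals = np.tile(np.array([0.3, 0.4, 0.5, 0.6])[:, None], (2, 3))
    labels = np.array(["CN"] * 4 + ["ADD"] * 4)
    out = tract_ttest(vals, labels, ("CN", "ADD"))
    np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
    np.testing.assert_allclose(out["p"], 1.0)
    assert (out["stars"] == "").all()


def test_ttest_closed_form():
    """Textbook equal-variance two-sample t reproduced to 1e-6."""
    x = np.array([2.1, 2.5, 2.3, 2.7])
    y = np.array([1.1, 1.4, 1.2, 1.5])
    nx, ny = 4, 4
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    vals = np.concatenate([x, y])[:, None]
    labels = np.array(["CN"] * 4 + ["ADD"] * 4)
    out = tract_ttest(vals, labels, ("CN", "ADD"))
    assert out.loc[0, "t"] == pytest.approx(t_hand, abs=1e-6)
    assert out.loc[0, "stars"] == "***"


def test_stars_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == ""
    assert significance_stars(float("nan")) == ""


def test_tract_recovery_on_planted_deficits():
    """Tracts carrying planted deficits are flagged (p < 0.05) with
    sensitivity >= 0.8 at the configured effect size."""
    from tests.conftest import stack_fcms
    from wmfc import SimulationConfig, simulate_cohort

    deficit_tracts = range(3)
    edges = tuple((i, j) for i in deficit_tracts for j in range(6, 16))
    cfg = SimulationConfig(groups=("CN", "lMCI"), n_per_group=50, n_frames=200,
                           n_wm=6, n_gm=10, motion_spike_rate=0.0,
                           deficit_edges=edges,
                           deficit_delta_by_group={"CN": 0.0, "lMCI": 0.25},
                           seed=12)
    cohort = simulate_cohort(cfg)
    stack, labels = stack_fcms(cohort, kind="WG")
    tract_vals = np.stack([tractwise_fc(s, kind="WG") for s in stack])
    out = tract_ttest(tract_vals, labels, ("CN", "lMCI"))
    flagged = out["p"] < 0.05
    assert flagged[list(deficit_tracts)].mean() >= 0.8


# ---------------------------------------------------------------------------
# overall-FC trend
# ---------------------------------------------------------------------------

def test_trend_anchor_points():
    vals = np.array([0.5, 0.5, 0.3, 0.3, 0.1, 0.1])
    labels = np.array(["CN", "CN", "MCI", "MCI", "ADD", "ADD"])
    trend = overall_fc_trend(vals, labels, group_order=["CN", "MCI", "ADD"])
    assert trend.normalized_mean["CN"] == pytest.approx(1.0)
    assert trend.normalized_mean["ADD"] == pytest.approx(0.0)
    assert trend.normalized_mean["MCI"] == pytest.approx(0.5)


def test_trend_affine_preserves_order_and_scales_sd():
    rng = np.random.default_rng(10)
    labels = np.repeat(["CN", "SMC", "MCI", "ADD"], 20)
    means = {"CN": 0.5, "SMC": 0.45, "MCI": 0.35, "ADD": 0.2}
    vals = np.concatenate([rng.normal(means[g], 0.02, 20)
                           for g in ["CN", "SMC", "MCI", "ADD"]])
    trend = overall_fc_trend(vals, labels,
                             group_order=["CN", "SMC", "MCI", "ADD"])
    seq = [trend.normalized_mean[g] for g in ["CN", "SMC", "MCI", "ADD"]]
    assert np.all(np.diff(seq) < 0)
    denom = trend.raw_mean["CN"] - trend.raw_mean["ADD"]
    for g in means:
        assert trend.normalized_sd[g] == pytest.approx(trend.raw_sd[g] / denom)


def test_trend_requires_distinct_anchors():
    vals = np.array([0.3, 0.3, 0.3, 0.3])
    labels = np.array(["CN", "CN", "ADD", "ADD"])
    with pytest.raises(ValueError, match="normalization"):
        overall_fc_trend(vals, labels)


def test_overall_fc_is_elementwise_mean():
    stack = np.arange(24, dtype=float).reshape(2, 3, 4)
    np.testing.assert_allclose(overall_fc(stack),
                               [stack[0].mean(), stack[1].mean()])
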