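"""Validation metrics: calibration, discrimination, summaries."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

import cpmshrink as cs
from cpmshrink.performance import (
    auc,
    brier,
    calibration_in_the_large,
    calibration_slope,
    cox_snell_r2_validation,
    evaluate_model,
    rmsd,
    summarise,
)


def test_calibration_slope_matches_grid_search_oracle():
    """Tiny fixed dataset: slope equals the 2-parameter likelihood maximiser."""
    lp = np.array([-2.0, -1.0, -0.5, 0.0, 0.3, 0.8, 1.5, 2.0])
    y = np.array([0, 0, 1, 0, 1, 0, 1, 1], dtype=float)

    def ll(a, b):
        p = expit(a + b * lp)
        return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    grid_a = np.linspace(-2, 2, 401)
    grid_b = np.linspace(-2, 4, 601)
    vals = [(ll(a, b), a, b) for a in grid_a for b in grid_b]
    _, a_best, b_best = max(vals)
    # refine around the coarse grid optimum
    grid_a = np.linspace(a_best - 0.02, a_best + 0.02, 81)
    grid_b = np.linspace(b_best - 0.02, b_best + 0.02, 81)
    _, _, b_best = max((ll(a, b), a, b) for a in grid_a for b in grid_b)
    assert calibration_slope(lp, y) == pytest.approx(b_best, abs=1e-3)


def test_calibration_slope_scale_equivariance(toy_cohort):
    m = cs.fit_mle(toy_cohort)
    lp = m.linear_predictor(toy_cohort.X)
    s = calibration_slope(lp, toy_cohort.y)
    assert calibration_slope(lp / 2, toy_cohort.y) == pytest.approx(2 * s, rel=1e-8)


def test_calibration_self_consistency_on_generated_outcomes():
    """y ~ Bernoulli(expit(lp)) gives slope ~ 1 and citl ~ 0."""
    rng = np.random.default_rng(17)
    lp = rng.normal(-1.4, 1.2, size=100_000)
    y = (rng.random(lp.size) < expit(lp)).astype(float)
    assert calibration_slope(lp, y) == pytest.approx(1.0, abs=0.03)
    assert calibration_in_the_large(lp, y) == pytest.approx(0.0, abs=0.02)
    # shifting predictions up by c moves citl to -c
    assert calibration_in_the_large(lp + 0.5, y) == pytest.approx(-0.5, abs=0.02)


def test_degenerate_linear_predictor_flags_nan():
    y = np.r_[np.ones(5), np.zeros(5)]
    assert np.isnan(calibration_slope(np.full(10, 0.3), y))


def test_citl_zero_for_constant_logit_of_mean():
    y = np.r_[np.ones(30), np.zeros(70)]
    lp = np.full(100, logit(0.3))
    assert calibration_in_the_large(lp, y) == pytest.approx(0.0, abs=1e-10)


def test_in_sample_mle_is_perfectly_calibrated(dev898):
    """Score equations: in-sample citl = 0 and slope = 1 for an MLE fit."""
    m = cs.fit_mle(dev898)
    lp = m.linear_predictor(dev898.X)
    assert calibration_slope(lp, dev898.y) == pytest.approx(1.0, abs=1e-6)
    assert calibration_in_the_large(lp, dev898.y) == pytest.approx(0.0, abs=1e-6)


def test_permutation_invariance(toy_cohort):
    m = cs.fit_mle(toy_cohort)
    lp = m.linear_predictor(toy_cohort.X)
    perm = np.random.default_rng(1).permutation(toy_cohort.n)
    assert calibration_slope(lp[perm], toy_cohort.y[perm]) == pytest.approx(
        calibration_slope(lp, toy_cohort.y), rel=1e-9
    )
    assert calibration_in_the_large(lp[perm], toy_cohort.y[perm]) == pytest.approx(
        calibration_in_the_large(lp, toy_cohort.y), rel=1e-9
    )


def test_auc_brute_force_and_properties():
    p = np.array([0.1, 0.4, 0.35, 0.8])
    y = np.array([0, 0, 1, 1], dtype=float)
    # exhaustive pairwise concordance over event/non-event pairs
    pairs = list(itertools.product(np.flatnonzero(y == 1), np.flatnonzero(y == 0)))
    conc = np.mean([1.0 if p[i] > p[j] else 0.5 if p[i] == p[j] else 0.0 for i, j in pairs])
    assert auc(p, y) == pytest.approx(conc)
    assert auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
    assert auc(np.full(4, 0.5), y) == 0.5
    # invariance under strictly monotone transforms of the scores
    assert auc(np.log(p / (1 - p)), y) == pytest.approx(auc(p, y))
    with pytest.raises(ValueError):
        auc(p, np.ones(4))


def test_brier_arithmetic():
    assert brier(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == 0.0
    assert brier(np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)]) == 0.25
    assert brier(np.array([0.2, 0.7]), np.array([0.0, 1.0])) == pytest.approx(0.065)


def test_validation_r2_identity_with_lr(toy_cohort):
    """In-sample on an MLE fit the metric equals 1 - exp(-LR/n)."""
    m = cs.fit_mle(toy_cohort)
    LR = cs.lr_statistic(m, toy_cohort)
    got = cox_snell_r2_validation(m.predict(toy_cohort.X), toy_cohort.y)
    assert got == pytest.approx(1 - np.exp(-LR / toy_cohort.n), rel=1e-10)
    assert got < cs.max_cox_snell_r2(toy_cohort.prevalence)
    # predictions at the outcome mean explain nothing
    flat = np.full(toy_cohort.n, toy_cohort.prevalence)
    assert cox_snell_r2_validation(flat, toy_cohort.y) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_values_and_jensen_bound():
    assert rmsd(np.array([1.0, 1.0, 1.0]), 1.0) == 0.0
    assert rmsd(np.array([0.9, 1.1]), 1.0) == pytest.approx(0.1)
    rng = np.random.default_rng(2)
    vals = rng.normal(0.95, 0.1, 200)
    assert rmsd(vals, 1.0) >= abs(vals.mean() - 1.0)


def test_summarise_against_sort_based_quantile_oracle():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=500)
    s = summarise(vals)

    def quantile_oracle(v, q):
        x = np.sort(v)
        h = (v.size - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, v.size - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    assert s.q025 == pytest.approx(quantile_oracle(vals, 0.025), abs=1e-12)
    assert s.median == pytest.approx(quantile_oracle(vals, 0.5), abs=1e-12)
    assert s.q975 == pytest.approx(quantile_oracle(vals, 0.975), abs=1e-12)
    assert s.iqr == pytest.approx(
        quantile_oracle(vals, 0.75) - quantile_oracle(vals, 0.25), abs=1e-12
    )
    assert s.q025 <= s.median <= s.q975


def test_summarise_simple_cases():
    s = summarise(np.full(10, 3.5))
    assert s.median == s.q025 == s.q975 == 3.5 and s.iqr == 0.0
    assert summarise(np.arange(1.0, 101.0)).median == 50.5
    with_nan = summarise(np.r_[np.arange(1.0, 101.0), np.nan])
    assert with_nan.n_iterations == 100 and with_nan.median == 50.5
    with pytest.raises(ValueError):
        summarise(np.array([np.nan]))


def test_evaluate_model_flags_degenerate_lasso(dev898):
    null = cs.FittedModel(intercept=logit(0.2), coefficients=np.zeros(10), method="lasso")
    metrics = evaluate_model(null, dev898)
    assert np.isnan(metrics.slope) and np.isnan(metrics.auc)
    assert np.isfinite(metrics.brier) and np.isfinite(metrics.citl)
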