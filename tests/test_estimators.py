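"""Estimation strategies: MLE, uniform shrinkage, Firth, lasso/ridge, CV."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

import cpmshrink as cs
from cpmshrink import _glm
from cpmshrink.estimators import (
    METHODS,
    SeparationError,
    bootstrap_shrinkage_factor,
    closed_form_shrinkage_factor,
    cv_select_lambda,
    develop_model,
    fit_firth,
    fit_mle,
    fit_penalised,
    lambda_grid,
    lambda_max,
    lr_statistic,
)


# ----------------------------------------------------------------- MLE
def test_mle_intercept_only():
    y = np.r_[np.ones(20), np.zeros(80)]
    m = fit_mle(cs.Cohort(X=np.zeros((100, 0)), y=y))
    assert m.intercept == pytest.approx(logit(0.2), abs=1e-8)
    assert m.coefficients.size == 0


def test_mle_matches_grouped_log_odds_ratio():
    """Binary predictor: the slope is the 2x2 table's log odds ratio."""
    # cells: x=0 -> 30/100 events; x=1 -> 60/100 events
    x = np.r_[np.zeros(100), np.ones(100)]
    y = np.r_[np.ones(30), np.zeros(70), np.ones(60), np.zeros(40)]
    m = fit_mle(cs.Cohort(X=x[:, None], y=y))
    log_or = np.log((60 * 70) / (40 * 30))
    assert m.coefficients[0] == pytest.approx(log_or, abs=1e-8)
    assert m.intercept == pytest.approx(logit(0.3), abs=1e-8)


def test_mle_agrees_with_statsmodels(dev898):
    ref = sm.GLM(dev898.y, sm.add_constant(dev898.X), family=sm.families.Binomial()).fit()
    m = fit_mle(dev898)
    assert m.intercept == pytest.approx(ref.params[0], abs=1e-7)
    assert np.allclose(m.coefficients, ref.params[1:], atol=1e-7)
    assert m.loglik_at_fit == pytest.approx(ref.llf, abs=1e-6)


def test_mle_is_a_maximum(toy_cohort):
    m = fit_mle(toy_cohort)
    rng = np.random.default_rng(0)
    beta = np.r_[m.intercept, m.coefficients]
    Z = np.column_stack([np.ones(toy_cohort.n), toy_cohort.X])
    best = _glm.bernoulli_loglik(Z @ beta, toy_cohort.y)
    for _ in range(100):
        pert = beta + rng.normal(scale=0.05, size=beta.shape)
        assert _glm.bernoulli_loglik(Z @ pert, toy_cohort.y) <= best + 1e-12


def test_mle_errors_on_separation_and_single_class():
    x = np.linspace(-1, 1, 20)
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_mle(cs.Cohort(X=x[:, None], y=y))
    with pytest.raises(ValueError):
        fit_mle(cs.Cohort(X=x[:, None], y=np.ones(20)))


def test_lr_statistic_direct_evaluation(toy_cohort):
    """LR equals 2*(LL_full - LL_null) computed from raw likelihoods."""
    m = fit_mle(toy_cohort)
    lp = m.intercept + toy_cohort.X[:, 0] * m.coefficients[0]
    p = expit(lp)
    y = toy_cohort.y
    ll_full = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    pbar = y.mean()
    ll_null = np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar))
    assert lr_statistic(m, toy_cohort) == pytest.approx(2 * (ll_full - ll_null), rel=1e-10)
    assert lr_statistic(m, toy_cohort) >= 0


# ------------------------------------------------------ uniform shrinkage
def test_closed_form_shrinkage_identity():
    """Printed formula == 1 - P/LR to 12 significant digits."""
    for LR in np.geomspace(10.1, 1e4, 25):
        for n in (100, 10**6):
            assert closed_form_shrinkage_factor(LR, n, 10) == pytest.approx(
                1 - 10 / LR, rel=1e-12
            )
    assert closed_form_shrinkage_factor(1e9, 1000, 10) == pytest.approx(1.0, abs=1e-6)
    with pytest.warns(RuntimeWarning):
        assert closed_form_shrinkage_factor(10.0, 500, 10) == pytest.approx(0.0, abs=1e-10)


def test_apply_uniform_shrinkage_properties(dev898):
    m = fit_mle(dev898)
    same = cs.apply_uniform_shrinkage(m, 1.0, dev898)
    assert np.allclose(same.coefficients, m.coefficients)
    assert same.intercept == pytest.approx(m.intercept, abs=1e-6)

    null = cs.apply_uniform_shrinkage(m, 0.0, dev898)
    assert np.all(null.coefficients == 0)
    assert null.intercept == pytest.approx(logit(dev898.prevalence), abs=1e-8)

    shrunk = cs.apply_uniform_shrinkage(m, 0.9, dev898)
    assert np.allclose(shrunk.coefficients, 0.9 * m.coefficients)
    # offset-refit score equation: mean prediction == outcome proportion
    assert shrunk.predict(dev898.X).mean() == pytest.approx(dev898.prevalence, abs=1e-8)


def test_bootstrap_shrinkage_fixed_model_has_no_optimism():
    """A fit that ignores the data estimates S ~ 1 (nothing to overfit)."""
    pop = cs.generate_population(cs.scenario(5, n_population=5000, seed=21))
    truth = cs.FittedModel(
        intercept=cs.solve_intercept(cs.BETA_ALL10, 0.2),
        coefficients=cs.BETA_ALL10,
        method="mle",
    )
    S = bootstrap_shrinkage_factor(pop, fit_fn=lambda c: truth, B=100, seed=5)
    assert abs(S - 1.0) < 0.05


def test_bootstrap_shrinkage_single_draw_oracle(dev898):
    """B=1: the factor equals a hand-computed calibration slope."""
    S = bootstrap_shrinkage_factor(dev898, fit_fn=fit_mle, B=1, seed=99)
    rng = np.random.default_rng(99)
    idx = rng.integers(0, dev898.n, dev898.n)
    refit = fit_mle(dev898.subset(idx))
    lp = refit.linear_predictor(dev898.X)
    slope = cs.calibration_slope(lp, dev898.y)
    assert S == pytest.approx(slope, abs=1e-6)


def test_bootstrap_shrinkage_batched_equals_loop(dev898):
    """The batched MLE fast path reproduces the per-resample loop."""
    loop = bootstrap_shrinkage_factor(dev898, fit_fn=fit_mle, B=25, seed=3)
    fast = bootstrap_shrinkage_factor(dev898, B=25, seed=3)
    assert fast == pytest.approx(loop, abs=1e-5)


def test_bootstrap_shrinkage_near_target_at_minimum_n(dev898):
    """At the criterion-1 size the estimated shrinkage sits near 0.9."""
    S = bootstrap_shrinkage_factor(dev898, B=200, seed=1)
    assert 0.85 < S < 0.95


# ----------------------------------------------------------------- Firth
def test_firth_finite_under_separation():
    x = np.linspace(-1, 1, 20)
    y = (x > 0).astype(float)
    m = fit_firth(cs.Cohort(X=x[:, None], y=y))
    assert np.isfinite(m.coefficients).all() and np.isfinite(m.intercept)


def test_firth_intercept_only_closed_form():
    """Jeffreys-penalised binomial: p_hat = (k + 1/2) / (n + 1)."""
    y = np.r_[np.ones(3), np.zeros(17)]
    m = fit_firth(cs.Cohort(X=np.zeros((20, 0)), y=y), reestimate_intercept=False)
    assert expit(m.intercept) == pytest.approx(3.5 / 21, abs=1e-8)


def test_firth_shrinks_toward_zero(dev898):
    mle = fit_mle(dev898)
    fir = fit_firth(dev898)
    # overall shrinkage of the slope vector, and calibrated intercept
    assert np.linalg.norm(fir.coefficients) < np.linalg.norm(mle.coefficients)
    assert fir.predict(dev898.X).mean() == pytest.approx(dev898.prevalence, abs=1e-8)


# ------------------------------------------------------------- penalised
def test_penalised_lambda_zero_equals_mle(dev898):
    mle = fit_mle(dev898)
    for pen in ("l1", "l2"):
        m = fit_penalised(dev898, pen, 0.0)
        assert np.allclose(m.coefficients, mle.coefficients, atol=1e-4)
        assert m.intercept == pytest.approx(mle.intercept, abs=1e-4)


def test_lasso_lambda_max_boundary(dev898):
    lm = lambda_max(dev898, "l1")
    at_max = fit_penalised(dev898, "l1", lm)
    assert np.all(at_max.coefficients == 0.0)
    assert at_max.intercept == pytest.approx(logit(dev898.prevalence), abs=1e-6)
    just_below = fit_penalised(dev898, "l1", 0.99 * lm)
    assert np.count_nonzero(just_below.coefficients) >= 1


def test_lambda_max_zero_when_outcome_constant():
    Xs, _, _ = _glm.standardise(np.random.default_rng(0).standard_normal((50, 3)))
    assert _glm.lasso_lambda_max(Xs, np.ones(50)) == 0.0


def test_penalised_matches_sklearn(dev898):
    """Independent solver cross-check on the average-NLL lambda scale."""
    from sklearn.linear_model import LogisticRegression

    Xs, _, _ = _glm.standardise(dev898.X)
    n = dev898.n
    for pen, lam, l1_ratio in [("l2", 0.02, 0.0), ("l1", 0.01, 1.0)]:
        b0, bs = _glm.fit_penalised_std(Xs, dev898.y, pen, lam)
        C = 1.0 / (2 * n * lam) if pen == "l2" else 1.0 / (n * lam)
        sk = LogisticRegression(
            C=C, l1_ratio=l1_ratio, solver="saga", tol=1e-10, max_iter=50_000
        ).fit(Xs, dev898.y)
        assert np.allclose(bs, sk.coef_[0], atol=1e-6)
        assert b0 == pytest.approx(sk.intercept_[0], abs=1e-6)


def test_ridge_norm_monotone_in_lambda(dev898):
    norms = [
        np.linalg.norm(fit_penalised(dev898, "l2", lam).coefficients)
        for lam in np.geomspace(1e-4, 1.0, 20)
    ]
    assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


def test_lasso_support_monotone_along_grid(dev898):
    nz = [
        np.count_nonzero(fit_penalised(dev898, "l1", lam).coefficients)
        for lam in np.geomspace(1e-3, lambda_max(dev898, "l1"), 20)
    ]
    assert all(a >= b for a, b in zip(nz, nz[1:]))


def test_penalised_preserves_outcome_proportion(dev898):
    for pen in ("l1", "l2"):
        m = fit_penalised(dev898, pen, 0.01)
        assert m.predict(dev898.X).mean() == pytest.approx(dev898.prevalence, abs=1e-6)


# ---------------------------------------------------------------- CV
def test_cv_grid_shape_and_anchor(dev898):
    g1 = lambda_grid(dev898, "l1")
    g2 = lambda_grid(dev898, "l2")
    assert g1.size == g2.size == 100
    assert g1[0] == pytest.approx(1e-4) and g1[-1] == pytest.approx(lambda_max(dev898, "l1"))
    assert g2[-1] == pytest.approx(1000 * lambda_max(dev898, "l1"))


def test_cv_deterministic_and_one_se_larger(dev898):
    a = cv_select_lambda(dev898, "l2", seed=5)
    b = cv_select_lambda(dev898, "l2", seed=5)
    assert a.lam == b.lam
    assert np.array_equal(a.cv_deviance_curve, b.cv_deviance_curve)
    one_se = cv_select_lambda(dev898, "l2", rule="one_se", seed=5)
    assert one_se.lam >= a.lam


def test_cv_selection_matches_converged_fold_fits(toy_cohort):
    """Path-tracked deviance curve agrees with exactly-converged fold fits."""
    rng = np.random.default_rng(8)
    X = np.column_stack([toy_cohort.X, rng.standard_normal((toy_cohort.n, 2))])
    dev = cs.Cohort(X=X, y=toy_cohort.y)
    Xs, _, _ = _glm.standardise(dev.X)
    from cpmshrink.estimators import _stratified_fold_ids

    ids = _stratified_fold_ids(dev.y, 5, np.random.default_rng(1))
    masks = np.column_stack([(ids != f).astype(float) for f in range(5)])
    grid = lambda_grid(dev, "l1")
    fast = _glm.penalised_path_deviance(Xs, dev.y, masks, grid, "l1").mean(axis=1)
    exact = np.zeros_like(fast)
    for f in range(5):
        tr = masks[:, f] > 0
        for li, lam in enumerate(grid):
            b0, bs = _glm.fit_penalised_std(Xs[tr], dev.y[tr], "l1", lam)
            lp = b0 + Xs[~tr] @ bs
            exact[li] += -2 * np.mean(dev.y[~tr] * lp - np.logaddexp(0, lp)) / 5
    assert np.abs(fast - exact).max() < 5e-3
    assert np.argmin(fast) == np.argmin(exact)


def test_cv_on_pure_noise_prefers_sparsity():
    """Min-deviance lasso zeroes coefficients on signal-free data."""
    zeroed = 0
    n_seeds = 50
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        X = rng.standard_normal((500, 10))
        y = (rng.random(500) < 0.3).astype(float)
        dev = cs.Cohort(X=X, y=y)
        rec = cv_select_lambda(dev, "l1", seed=seed)
        m = fit_penalised(dev, "l1", rec.lam)
        if np.count_nonzero(m.coefficients) < 10:
            zeroed += 1
    assert zeroed >= 0.9 * n_seeds


# ------------------------------------------------------------ dispatcher
def test_develop_model_composition_contract(dev898):
    direct = develop_model(dev898, "closed_form_shrinkage")
    mle = fit_mle(dev898)
    S = closed_form_shrinkage_factor(lr_statistic(mle, dev898), dev898.n, dev898.P)
    manual = cs.apply_uniform_shrinkage(mle, S, dev898)
    assert np.allclose(direct.coefficients, manual.coefficients)
    assert direct.intercept == pytest.approx(manual.intercept, abs=1e-12)
    assert direct.tuning.shrinkage_S == pytest.approx(S)


def test_develop_model_deterministic_and_default_boot():
    pop = cs.generate_population(cs.scenario(5, n_population=3000, seed=2))
    dev, _ = cs.split_development(pop, 898, 0)
    a = develop_model(dev, "bootstrap_shrinkage", seed=4, B_shrink=50)
    b = develop_model(dev, "bootstrap_shrinkage", seed=4, B_shrink=50)
    assert a.intercept == b.intercept
    assert np.array_equal(a.coefficients, b.coefficients)
    assert a.tuning.n_boot == 50
    import inspect

    assert inspect.signature(develop_model).parameters["B_shrink"].default == 500
    with pytest.raises(ValueError):
        develop_model(dev, "stepwise")


def test_all_methods_preserve_outcome_proportion(dev898):
    """Every strategy's intercept handling keeps mean(p) == mean(y)."""
    for method in METHODS:
        m = develop_model(dev898, method, seed=0, B_shrink=25)
        assert m.predict(dev898.X).mean() == pytest.approx(dev898.prevalence, abs=1e-6), method


def test_parameter_recovery_at_large_n():
    """On abundant scenario-5 data every method lands near the true betas."""
    pop = cs.generate_population(cs.scenario(5, n_population=100_000, seed=31))
    for method in ("mle", "closed_form_shrinkage", "firth", "lasso", "ridge"):
        m = develop_model(pop, method, seed=1)
        assert np.abs(m.coefficients - cs.BETA_ALL10).max() < 0.05, method
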