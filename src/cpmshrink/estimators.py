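"""Model-development strategies for logistic clinical prediction models.

Seven ways of estimating the coefficients of one logistic regression are
provided, all returning a common :class:`FittedModel` contract:

* unpenalised maximum likelihood (MLE);
* closed-form uniform shrinkage — MLE slopes multiplied by
  ``S = 1 + P / (n * log(1 - (1 - exp(-LR/n))))`` (equivalently
  ``1 - P/LR``), intercept re-estimated;
* uniform bootstrap shrinkage — S estimated as the average calibration
  slope of resample-fitted models evaluated on the original data;
* Firth's bias-reduced fit (Jeffreys-prior penalty), intercept
  re-estimated so the overall outcome proportion is preserved;
* lasso (l1) and ridge (l2) penalised likelihood with the penalty chosen
  by single or repeated 10-fold cross-validation on the binomial
  deviance, using a 100-point log-spaced lambda grid.

Lambda lives on the per-observation average negative log-likelihood
scale: the fitted objective is ``(1/n) * sum nll_i + lam * pen(beta)``
(multiply by n for the summed-likelihood form).  Predictors are
standardised internally for the penalised fits and coefficients returned
on the original scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy.special import expit, logit

from . import _glm
from ._glm import SeparationError, bernoulli_loglik, fit_logistic
from .cohort import Cohort

__all__ = [
    "FittedModel",
    "TuningRecord",
    "SeparationError",
    "METHODS",
    "fit_mle",
    "lr_statistic",
    "closed_form_shrinkage_factor",
    "apply_uniform_shrinkage",
    "bootstrap_shrinkage_factor",
    "fit_firth",
    "fit_penalised",
    "lambda_max",
    "lambda_grid",
    "cv_select_lambda",
    "develop_model",
]

logger = logging.getLogger(__name__)

METHODS = (
    "mle",
    "closed_form_shrinkage",
    "bootstrap_shrinkage",
    "firth",
    "lasso",
    "ridge",
)

RIDGE_GRID_MULTIPLIER = 1000.0  # anchor of the l2 grid relative to the l1 lambda-max
GRID_SIZE = 100
GRID_MIN = 1e-4


@dataclass
class TuningRecord:
    """Record of how a model's shrinkage/penalty was chosen."""

    shrinkage_S: Optional[float] = None
    lam: Optional[float] = None
    lambda_grid: Optional[np.ndarray] = None
    cv_deviance_curve: Optional[np.ndarray] = None
    selection_rule: Optional[Literal["min_deviance", "one_se"]] = None
    cv_folds: int = 0
    cv_repeats: int = 0
    n_boot: Optional[int] = None

    def __post_init__(self) -> None:
        if self.shrinkage_S is not None and self.lam is not None:
            raise ValueError(
                "exactly one of shrinkage_S / lam may be populated"
            )


@dataclass
class FittedModel:
    """A fitted logistic prediction model: intercept, P slopes, provenance."""

    intercept: float
    coefficients: np.ndarray
    method: str
    tuning: TuningRecord = field(default_factory=TuningRecord)
    loglik_at_fit: float = np.nan

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def P(self) -> int:
        return self.coefficients.shape[0]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted probabilities expit(b0 + x'b)."""
        return expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        t = self.tuning
        return {
            "method": self.method,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "loglik_at_fit": self.loglik_at_fit,
            "tuning": {
                "shrinkage_S": t.shrinkage_S,
                "lambda": t.lam,
                "selection_rule": t.selection_rule,
                "cv_folds": t.cv_folds,
                "cv_repeats": t.cv_repeats,
                "n_boot": t.n_boot,
            },
        }


# ------------------------------------------------------------------- MLE
def fit_mle(dev: Cohort) -> FittedModel:
    """Unpenalised maximum-likelihood logistic regression (Newton/IRLS).

    Raises :class:`SeparationError` when the MLE does not exist (complete
    or quasi-complete separation) and ``ValueError`` for a single-class
    outcome.
    """
    beta, ll = fit_logistic(dev.X if dev.P else None, dev.y)
    return FittedModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        method="mle",
        loglik_at_fit=ll,
    )


def lr_statistic(model: FittedModel, dev: Cohort) -> float:
    """Likelihood-ratio statistic of a fitted model vs the null model.

    ``LR = 2 * (LL_full - LL_null)`` with the null being intercept-only.
    """
    ll_full = float(bernoulli_loglik(model.linear_predictor(dev.X), dev.y))
    ll_null = float(
        bernoulli_loglik(np.full(dev.n, logit(dev.prevalence)), dev.y)
    )
    return max(0.0, 2.0 * (ll_full - ll_null))


# ------------------------------------------------------- uniform shrinkage
def closed_form_shrinkage_factor(LR: float, n: int, P: int) -> float:
    """Closed-form (likelihood-ratio based) uniform shrinkage factor.

    ``S = 1 + P / (n * log(1 - (1 - exp(-LR/n))))``; the inner logarithm
    collapses to ``-LR/n`` so this equals ``1 - P/LR``.  When ``LR <= P``
    the factor is non-positive: the model carries no shrinkable signal,
    and a warning is emitted.
    """
    if LR <= 0:
        raise ValueError("LR must be positive")
    # inner log(1 - (1 - exp(-LR/n))) collapses exactly to -LR/n; evaluating
    # it collapsed avoids the 1-(1-x) cancellation at small LR/n
    S = 1.0 + P / (n * (-LR / n))
    if S <= 0:
        warnings.warn(
            f"shrinkage factor S={S:.4f} <= 0 (LR={LR:.3f} <= P={P}): the "
            "model carries no shrinkable signal",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(S)


def apply_uniform_shrinkage(model: FittedModel, S: float, dev: Cohort) -> FittedModel:
    """Multiply slopes by S and re-estimate the intercept on ``dev``.

    The intercept is refit by maximum likelihood with the shrunken linear
    predictor as a fixed offset, whose score equation forces the mean
    predicted probability to equal the observed outcome proportion.
    """
    shrunk = S * model.coefficients
    offset = dev.X @ shrunk
    b0 = _glm.fit_intercept_offset(dev.y, offset)
    lp = b0 + offset
    return FittedModel(
        intercept=b0,
        coefficients=shrunk,
        method=model.method,
        tuning=TuningRecord(shrinkage_S=float(S)),
        loglik_at_fit=float(bernoulli_loglik(lp, dev.y)),
    )


def bootstrap_shrinkage_factor(
    dev: Cohort,
    fit_fn: Optional[Callable[[Cohort], FittedModel]] = None,
    B: int = 500,
    seed: int | np.random.Generator = 0,
    max_redraw: int = 50,
) -> float:
    """Uniform shrinkage factor from B bootstrap calibration slopes.

    For each resample (with replacement): refit with ``fit_fn``
    (replicating all modelling steps; default plain MLE), compute the
    linear predictor on the ORIGINAL development data, regress the
    original outcomes on it, and collect the slope.  The factor is the
    mean of the B slopes — an estimate of the in-sample optimism of the
    calibration slope.

    Resamples with a single outcome class are redrawn (logged); resamples
    whose fit fails are skipped, and the whole procedure fails if more
    than 10% are skipped.

    With the default ``fit_fn`` (plain MLE) the B refits are solved as one
    batched weighted Newton system — same resamples, same estimates as
    the per-resample loop, at a fraction of the cost.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if fit_fn is None:
        return _bootstrap_shrinkage_batched(dev, B, rng, max_redraw)
    slopes: list[float] = []
    skipped = 0
    for _ in range(B):
        for attempt in range(max_redraw):
            idx = rng.integers(0, dev.n, dev.n)
            boot = dev.subset(idx)
            if 0.0 < boot.y.mean() < 1.0:
                break
            logger.info("bootstrap resample had a single outcome class; redrawn")
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        try:
            m = fit_fn(boot)
        except (SeparationError, ValueError) as exc:
            skipped += 1
            logger.warning("bootstrap resample fit failed (%s); skipped", exc)
            continue
        lp = m.linear_predictor(dev.X)
        beta, _ = fit_logistic(lp.reshape(-1, 1), dev.y)
        slopes.append(float(beta[1]))
    if skipped > 0.1 * B:
        raise RuntimeError(
            f"{skipped}/{B} bootstrap resamples failed to fit; shrinkage "
            "factor unreliable"
        )
    return float(np.mean(slopes))


def _bootstrap_shrinkage_batched(
    dev: Cohort, B: int, rng: np.random.Generator, max_redraw: int = 50
) -> float:
    """Batched-MLE variant of the bootstrap shrinkage factor.

    Each resample with replacement is a multinomial weight vector on the
    original rows, so all B unpenalised refits share one design matrix and
    are solved simultaneously; the B calibration slopes on the original
    data are then fit as one batched two-parameter system.  Draws consume
    the generator exactly like the per-resample loop (one ``integers``
    row per resample).
    """
    n = dev.n
    y = dev.y
    counts = np.empty((n, B))
    for b in range(B):
        for _attempt in range(max_redraw):
            idx = rng.integers(0, n, n)
            w = np.bincount(idx, minlength=n).astype(float)
            if 0.0 < (w @ y) < n:
                break
            logger.info("bootstrap resample had a single outcome class; redrawn")
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        counts[:, b] = w
    Z = np.column_stack([np.ones(n), dev.X])
    Bcoef = np.zeros((Z.shape[1], B))
    ybar = (counts * y[:, None]).sum(axis=0) / n
    Bcoef[0] = logit(ybar)
    Bcoef = _glm._batched_ridge_newton(
        Z, y, counts, np.zeros(B), Bcoef, tol=1e-8 * n, max_iter=40
    )
    LP = Z @ Bcoef  # linear predictors of every resample model on dev
    _, slopes = _glm.batched_calibration_fits(LP, y)
    if np.isnan(slopes).any():
        raise RuntimeError("degenerate calibration fit in bootstrap resample")
    return float(np.mean(slopes))


# ----------------------------------------------------------------- Firth
def fit_firth(
    dev: Cohort, *, tol: float = 1e-8, max_iter: int = 50, reestimate_intercept: bool = True
) -> FittedModel:
    """Firth's bias-reduced logistic regression.

    Maximises the Jeffreys-penalised likelihood
    ``LL + 0.5 * log |I(beta)|`` by modified-score Newton iterations (the
    score augmented with the hat-value correction ``h_i (1/2 - p_i)``),
    with step-halving.  Finite estimates exist even under separation.
    Afterwards the intercept is re-estimated with the penalised slopes'
    linear predictor as an offset (FLIC-style) so the overall outcome
    proportion is preserved; pass ``reestimate_intercept=False`` for the
    raw penalised fit.
    """
    n = dev.n
    Z = np.column_stack([np.ones(n), dev.X]) if dev.P else np.ones((n, 1))
    d = Z.shape[1]
    y = dev.y
    beta = np.zeros(d)

    def pen_ll(b: np.ndarray) -> float:
        lp = Z @ b
        p = expit(lp)
        w = p * (1.0 - p)
        H = (Z * w[:, None]).T @ Z
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        return float(bernoulli_loglik(lp, y)) + 0.5 * logdet

    ll_old = pen_ll(beta)
    converged = False
    for _ in range(max_iter):
        lp = Z @ beta
        p = expit(lp)
        w = p * (1.0 - p)
        Hinf = (Z * w[:, None]).T @ Z
        Hinv = np.linalg.inv(Hinf)
        h = w * np.einsum("ij,jk,ik->i", Z, Hinv, Z)
        score = Z.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = Hinv @ score
        t = 1.0
        for _ in range(30):
            cand_ll = pen_ll(beta + t * step)
            if cand_ll >= ll_old - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll_old = pen_ll(beta)
    if not converged and np.max(np.abs(score)) > 1e-4:
        raise RuntimeError(
            f"Firth fit failed to converge in {max_iter} iterations "
            f"(max |modified score| = {np.max(np.abs(score)):.3g})"
        )
    slopes = beta[1:]
    b0 = float(beta[0])
    if reestimate_intercept and dev.P:
        offset = dev.X @ slopes
        b0 = _glm.fit_intercept_offset(y, offset)
    lp = b0 + (dev.X @ slopes if dev.P else 0.0)
    return FittedModel(
        intercept=b0,
        coefficients=slopes,
        method="firth",
        loglik_at_fit=float(bernoulli_loglik(lp, y)),
    )


# ------------------------------------------------------------- penalised
def lambda_max(dev: Cohort, penalty: Literal["l1", "l2"] = "l1") -> float:
    """Entry point of the penalised path, on the average-NLL lambda scale.

    For l1 this is the smallest lambda at which every slope is exactly
    zero: ``max_p |x~_p . (y - ybar)| / n`` on standardised predictors.
    The l2 grid reuses the same anchor times
    :data:`RIDGE_GRID_MULTIPLIER`, since no finite l2 penalty zeroes the
    coefficients.
    """
    Xs, _, _ = _glm.standardise(dev.X)
    lm = _glm.lasso_lambda_max(Xs, dev.y)
    if penalty == "l2":
        lm *= RIDGE_GRID_MULTIPLIER
    return lm


def lambda_grid(dev: Cohort, penalty: Literal["l1", "l2"]) -> np.ndarray:
    """100-point log-spaced grid from 1e-4 up to the penalty's lambda-max."""
    lm = lambda_max(dev, penalty)
    lo = GRID_MIN
    if lm <= lo:
        lo = lm * 1e-3 if lm > 0 else 1e-8
        lm = max(lm, 1e-7)
    return np.geomspace(lo, lm, GRID_SIZE)


def fit_penalised(
    dev: Cohort, penalty: Literal["l1", "l2"], lam: float
) -> FittedModel:
    """Penalised logistic fit at a fixed lambda (intercept unpenalised).

    Predictors are standardised internally; returned coefficients are on
    the original predictor scale.  The objective is the average negative
    log-likelihood plus ``lam * sum |beta_p|`` (l1) or
    ``lam * sum beta_p^2`` (l2) in standardised coordinates.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Xs, mu, sd = _glm.standardise(dev.X)
    b0s, bs = _glm.fit_penalised_std(Xs, dev.y, penalty, lam)
    coef = bs / sd
    b0 = b0s - float(mu @ coef)
    lp = b0 + dev.X @ coef
    return FittedModel(
        intercept=b0,
        coefficients=coef,
        method="lasso" if penalty == "l1" else "ridge",
        tuning=TuningRecord(lam=float(lam)),
        loglik_at_fit=float(bernoulli_loglik(lp, dev.y)),
    )


def _stratified_fold_ids(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels 0..k-1, stratified by outcome class."""
    n = y.shape[0]
    ids = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        ids[perm] = np.arange(perm.size) % k
    return ids


def cv_select_lambda(
    dev: Cohort,
    penalty: Literal["l1", "l2"],
    k: int = 10,
    repeats: int = 1,
    rule: Literal["min_deviance", "one_se"] = "min_deviance",
    seed: int | np.random.Generator = 0,
) -> TuningRecord:
    """Choose lambda by (repeated) k-fold cross-validated binomial deviance.

    Each repeat draws a fresh outcome-stratified fold partition; the
    held-out deviance curve over the 100-point grid is averaged across
    folds and repeats.  ``min_deviance`` returns the minimiser of the
    averaged curve; ``one_se`` the largest lambda whose averaged deviance
    is within one standard error (over the fold-level deviances) of the
    minimum.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Xs, _, _ = _glm.standardise(dev.X)
    grid = lambda_grid(dev, penalty)
    n = dev.n
    # training-membership mask over all fold x repeat systems
    masks = np.empty((n, k * repeats), dtype=float)
    for r in range(repeats):
        ids = _stratified_fold_ids(dev.y, k, rng)
        for f in range(k):
            masks[:, r * k + f] = (ids != f).astype(float)
    dev_curves = _glm.penalised_path_deviance(Xs, dev.y, masks, grid, penalty)
    curve = dev_curves.mean(axis=1)
    i_min = int(np.argmin(curve))
    if rule == "min_deviance":
        i_sel = i_min
    elif rule == "one_se":
        se = float(np.std(dev_curves[i_min], ddof=1) / np.sqrt(dev_curves.shape[1]))
        within = np.flatnonzero(curve <= curve[i_min] + se)
        i_sel = int(within[np.argmax(grid[within])])
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return TuningRecord(
        lam=float(grid[i_sel]),
        lambda_grid=grid,
        cv_deviance_curve=curve,
        selection_rule=rule,
        cv_folds=k,
        cv_repeats=repeats,
    )


# ------------------------------------------------------------- dispatcher
def develop_model(
    dev: Cohort,
    method: str,
    *,
    seed: int | np.random.Generator = 0,
    B_shrink: int = 500,
    cv_folds: int = 10,
    cv_repeats: int = 1,
    selection_rule: Literal["min_deviance", "one_se"] = "min_deviance",
) -> FittedModel:
    """Single entry point used by the simulation and internal validation.

    Routes to the strategy named by ``method`` (one of :data:`METHODS`),
    recording the full tuning trace so variability in S or lambda can be
    reported.  Two calls with identical inputs, options and seed are
    bit-identical.
    """
    if method == "mle":
        return fit_mle(dev)
    if method == "closed_form_shrinkage":
        mle = fit_mle(dev)
        S = closed_form_shrinkage_factor(lr_statistic(mle, dev), dev.n, dev.P)
        out = apply_uniform_shrinkage(mle, S, dev)
        out.method = "closed_form_shrinkage"
        return out
    if method == "bootstrap_shrinkage":
        mle = fit_mle(dev)
        S = bootstrap_shrinkage_factor(dev, B=B_shrink, seed=seed)
        out = apply_uniform_shrinkage(mle, S, dev)
        out.method = "bootstrap_shrinkage"
        out.tuning.n_boot = B_shrink
        return out
    if method == "firth":
        return fit_firth(dev)
    if method in ("lasso", "ridge"):
        penalty = "l1" if method == "lasso" else "l2"
        rec = cv_select_lambda(
            dev,
            penalty,
            k=cv_folds,
            repeats=cv_repeats,
            rule=selection_rule,
            seed=seed,
        )
        out = fit_penalised(dev, penalty, rec.lam)
        out.tuning = rec
        return out
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
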