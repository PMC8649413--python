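"""Low-level logistic-regression machinery.

Everything here operates on plain arrays.  The public estimation API in
:mod:`cpmshrink.estimators` wraps these routines; the simulation engine
calls the batched variants, which solve many small logistic systems
simultaneously (bootstrap resamples, cross-validation folds x repeats,
calibration fits for several models at once) so that a full scenario
iteration stays cheap on a single CPU.

Conventions
-----------
* Designs are passed without an intercept column; an intercept is always
  added internally and never penalised.
* Ridge penalties follow the summed-objective form
  ``-LL + n * lam * sum(beta_p^2)`` and lasso ``-LL + n * lam *
  sum(|beta_p|)``, i.e. ``lam`` lives on the per-observation average
  negative log-likelihood scale.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "SeparationError",
    "bernoulli_loglik",
    "fit_logistic",
    "fit_intercept_offset",
    "batched_calibration_fits",
    "batched_citl_fits",
    "standardise",
    "lasso_lambda_max",
    "penalised_path_deviance",
    "fit_penalised_std",
]

_COEF_BLOWUP = 1e3  # coefficient sup-norm beyond which we call separation


class SeparationError(RuntimeError):
    """Raised when maximum-likelihood coefficients diverge.

    Complete or quasi-complete separation of the outcome classes makes the
    unpenalised likelihood monotone in some direction, so the MLE does not
    exist; we report this rather than returning huge coefficients.
    """


def bernoulli_loglik(lp: np.ndarray, y: np.ndarray, weights=None):
    """Bernoulli log-likelihood at linear predictor ``lp`` (stable form).

    Uses ``LL_i = y_i * lp_i - log(1 + exp(lp_i))`` computed via
    ``logaddexp`` so extreme linear predictors do not overflow.  Sums over
    axis 0, broadcasting across trailing axes.
    """
    lp = np.asarray(lp, dtype=float)
    yb = np.asarray(y, dtype=float)
    if lp.ndim > 1:
        yb = yb[:, None]  # broadcast outcomes across systems
    ll = yb * lp - np.logaddexp(0.0, lp)
    if weights is not None:
        ll = ll * weights
    return ll.sum(axis=0)


def _full_design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None or X.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), X])


def fit_logistic(
    X: np.ndarray | None,
    y: np.ndarray,
    *,
    offset: np.ndarray | None = None,
    sample_weight: np.ndarray | None = None,
    l2: np.ndarray | float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Newton/IRLS maximiser of the (optionally ridge-penalised) Bernoulli LL.

    Parameters
    ----------
    X
        Predictor matrix (n x P) WITHOUT an intercept column, or None for
        an intercept-only model.
    offset
        Fixed additive term in the linear predictor (not estimated).
    l2
        Ridge strength(s) applied to the slope coefficients only, on the
        summed-objective scale (``-LL + sum_j l2_j beta_j^2``).

    Returns
    -------
    beta : ndarray
        ``[intercept, slopes...]``.
    loglik : float
        Unpenalised log-likelihood at the optimum (excluding any penalty).

    Raises
    ------
    SeparationError
        If coefficients diverge (no finite MLE).
    ValueError
        If the outcome has a single class and no penalty stabilises the fit.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Z = _full_design(X, n)
    d = Z.shape[1]
    l2_vec = np.zeros(d)
    l2_vec[1:] = l2
    if offset is None:
        offset = 0.0
    w_obs = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)

    if d > 1 or np.all(l2_vec == 0.0):
        ybar = float(np.average(y, weights=w_obs))
        if ybar in (0.0, 1.0):
            raise ValueError("outcome has a single class; logistic MLE undefined")

    beta = np.zeros(d) if init is None else np.asarray(init, dtype=float).copy()

    def penalised_ll(b: np.ndarray) -> float:
        lp = Z @ b + offset
        return float(bernoulli_loglik(lp, y, w_obs)) - float(l2_vec @ b**2)

    ll_old = penalised_ll(beta)
    for _ in range(max_iter):
        lp = Z @ beta + offset
        p = expit(lp)
        w = w_obs * p * (1.0 - p)
        score = Z.T @ (w_obs * (y - p)) - 2.0 * l2_vec * beta
        if np.max(np.abs(score)) < tol:
            break
        H = (Z * w[:, None]).T @ Z + 2.0 * np.diag(l2_vec)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError(
                "singular information matrix (collinear or separated data)"
            ) from exc
        # step-halving keeps the penalised LL monotone
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = penalised_ll(cand)
            if ll_new >= ll_old - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll_old = penalised_ll(beta)
        if np.max(np.abs(beta)) > _COEF_BLOWUP and np.all(l2_vec == 0.0):
            raise SeparationError(
                "coefficients diverged beyond sup-norm 1e3: complete or "
                "quasi-complete separation of the outcome"
            )
    else:
        if np.max(np.abs(score)) > 1e-4:
            raise SeparationError(
                f"logistic fit failed to converge in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(score)):.3g})"
            )
    lp = Z @ beta + offset
    if d > 1 and np.all(l2_vec == 0.0):
        # a 'converged' score with saturated, perfectly classifying
        # probabilities means the likelihood is monotone along some
        # direction: the finite numbers returned are not an MLE
        margins = np.where(y > 0.5, lp, -lp)
        if np.max(np.abs(lp)) > 25.0 and np.all(margins > 0.0):
            raise SeparationError(
                "complete separation: fitted probabilities saturate at 0/1 "
                "and classify the outcome perfectly; no finite MLE exists"
            )
    return beta, float(bernoulli_loglik(lp, y, w_obs))


def fit_intercept_offset(y: np.ndarray, offset: np.ndarray) -> float:
    """Re-estimate the intercept with a fixed linear predictor as offset.

    The score equation of this one-parameter fit forces the mean predicted
    probability to equal the observed outcome proportion.
    """
    beta, _ = fit_logistic(None, y, offset=offset)
    return float(beta[0])


# --------------------------------------------------------------- batched 2x2
def batched_calibration_fits(
    LP: np.ndarray, y: np.ndarray, *, tol: float = 1e-10, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fit ``logit P(y=1) = a_m + b_m * lp_m`` for each column of ``LP``.

    Newton iterations on m independent two-parameter systems, vectorised
    across systems.  Returns ``(intercepts, slopes)`` of shape (m,).
    Columns with (numerically) constant lp yield NaN.
    """
    LP = np.asarray(LP, dtype=float)
    if LP.ndim == 1:
        LP = LP[:, None]
    n, m = LP.shape
    y = np.asarray(y, dtype=float)
    # row-contiguous (m, n) layout keeps the per-iteration reductions cheap
    LPt = np.ascontiguousarray(LP.T)
    LP2t = LPt * LPt
    sd = LPt.std(axis=1)
    ok = sd > 1e-12
    a = np.zeros(m)
    b = np.ones(m)  # unit slope: the natural start for calibration fits
    for _ in range(max_iter):
        lp = LPt * b[:, None]
        lp += a[:, None]
        p = expit(lp)
        r = y[None, :] - p
        s0 = r.sum(axis=1)
        s1 = np.einsum("mn,mn->m", LPt, r)
        if max(
            np.max(np.abs(s0[ok]), initial=0.0),
            np.max(np.abs(s1[ok]), initial=0.0),
        ) < tol * n:
            break
        w = p * (1.0 - p)
        h00 = w.sum(axis=1)
        h01 = np.einsum("mn,mn->m", w, LPt)
        h11 = np.einsum("mn,mn->m", w, LP2t)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (h11 * s0 - h01 * s1) / det
        db = (h00 * s1 - h01 * s0) / det
        a = a + np.where(ok, da, 0.0)
        b = b + np.where(ok, db, 0.0)
    a[~ok] = np.nan
    b[~ok] = np.nan
    return a, b


def batched_citl_fits(
    LP: np.ndarray, y: np.ndarray, *, tol: float = 1e-10, max_iter: int = 50
) -> np.ndarray:
    """Intercept of a logistic fit with each lp column as a fixed offset."""
    LP = np.asarray(LP, dtype=float)
    if LP.ndim == 1:
        LP = LP[:, None]
    n, m = LP.shape
    y = np.asarray(y, dtype=float)
    LPt = np.ascontiguousarray(LP.T)
    a = np.zeros(m)
    for _ in range(max_iter):
        p = expit(LPt + a[:, None])
        s = (y[None, :] - p).sum(axis=1)
        if np.max(np.abs(s)) < tol * n:
            break
        h = (p * (1.0 - p)).sum(axis=1)
        a = a + s / h
    return a


# ----------------------------------------------------------- penalised paths
def standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and scale columns to mean 0, sd 1 (population sd).

    Returns ``(Xs, means, sds)``; constant columns keep sd 1 so they simply
    stay zero after centring.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lasso_lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest average-scale l1 penalty that zeroes every slope.

    At beta = 0 (intercept at logit of the mean) the slope score is
    ``x_p . (y - ybar) / n``; the sup over p is the entry point of the
    first predictor on the path.
    """
    n = y.shape[0]
    r = y - y.mean()
    if np.allclose(r, 0.0):
        return 0.0
    return float(np.max(np.abs(Xs.T @ r)) / n)


def _pair_index(d: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(d)
    return iu


def _batched_ridge_newton(
    Z: np.ndarray,
    y: np.ndarray,
    M: np.ndarray,
    lam_times_n: np.ndarray,
    B: np.ndarray,
    *,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """One ridge logistic solve for S systems sharing design Z (n x d).

    ``M`` (n x S) are nonnegative observation weights (0/1 fold masks or
    bootstrap counts), ``lam_times_n`` (S,) the ridge strength on the
    summed scale, ``B`` (d x S) the warm start (modified in place).
    """
    n, d = Z.shape
    S = M.shape[1]
    iu = _pair_index(d)
    T = Z[:, iu[0]] * Z[:, iu[1]]  # (n, npairs)
    pen = np.zeros((d, S))
    pen[1:, :] = lam_times_n[None, :]
    for _ in range(max_iter):
        lp = Z @ B
        p = expit(lp)
        w = p * (1.0 - p) * M
        G = Z.T @ (M * (y[:, None] - p)) - 2.0 * pen * B  # (d, S)
        if np.max(np.abs(G)) < tol:
            break
        Hflat = T.T @ w  # (npairs, S)
        H = np.zeros((S, d, d))
        H[:, iu[0], iu[1]] = Hflat.T
        H[:, iu[1], iu[0]] = Hflat.T
        H[:, np.arange(d), np.arange(d)] += 2.0 * pen.T
        step = np.linalg.solve(H, G.T[:, :, None])[:, :, 0].T  # (d, S)
        np.clip(step, -5.0, 5.0, out=step)
        B += step
    return B


def _batched_lasso_cd(
    Xs: np.ndarray,
    y: np.ndarray,
    M: np.ndarray,
    lam_times_n: np.ndarray,
    b0: np.ndarray,
    B: np.ndarray,
    *,
    tol: float,
    max_outer: int,
    max_sweeps: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Lasso logistic via IRLS + coordinate descent, batched over systems.

    Standard quadratic-approximation coordinate descent: at each outer
    step form the weighted least-squares surrogate at the current
    coefficients, then cycle soft-thresholded coordinate updates.  Warm
    starts along a descending lambda path keep the iteration counts small.
    """
    n, P = Xs.shape
    S = M.shape[1]
    for _ in range(max_outer):
        lp = b0[None, :] + Xs @ B
        p = expit(lp)
        w = p * (1.0 - p) * M
        w = np.maximum(w, 1e-10 * M)
        rw = M * (y[:, None] - p)  # weighted working residual w*(z - lp)
        sw = w.sum(axis=0)
        wxx = (Xs**2).T @ w  # (P, S)
        B_before = B.copy()
        for _ in range(max_sweeps):
            delta_max = 0.0
            for j in range(P):
                xj = Xs[:, j]
                num = xj @ rw + wxx[j] * B[j]
                Bj_new = np.sign(num) * np.maximum(np.abs(num) - lam_times_n, 0.0)
                Bj_new = np.where(wxx[j] > 0, Bj_new / np.where(wxx[j] > 0, wxx[j], 1.0), 0.0)
                dj = Bj_new - B[j]
                if np.any(dj != 0.0):
                    rw -= (w * xj[:, None]) * dj[None, :]
                    B[j] = Bj_new
                    delta_max = max(delta_max, float(np.max(np.abs(dj))))
            d0 = rw.sum(axis=0) / np.maximum(sw, 1e-300)
            b0 += d0
            rw -= w * d0[None, :]
            delta_max = max(delta_max, float(np.max(np.abs(d0))))
            if delta_max < tol:
                break
        if float(np.max(np.abs(B - B_before))) < tol and float(np.max(np.abs(d0))) < tol:
            break
    return b0, B


def _quadratic_lasso_cd(
    H: np.ndarray,
    g: np.ndarray,
    B: np.ndarray,
    lam_n: np.ndarray,
    *,
    sweeps: int = 3,
    tol: float = 1e-5,
) -> np.ndarray:
    """Coordinate descent on the local quadratic model of the lasso objective.

    Minimises ``g'D + D'HD/2 + lam_n * ||(B+D)_slopes||_1`` over the step
    ``D`` for S systems at once (``H``: (S,d,d), ``g``/``B``: (d,S)); the
    intercept (coordinate 0) is unpenalised.  Cost per sweep is O(S d^2),
    independent of the number of observations.
    """
    d, S = g.shape
    D = np.zeros((d, S))
    q = np.zeros((d, S))  # H @ D, maintained incrementally
    Hdiag = H[:, np.arange(d), np.arange(d)].T  # (d, S)
    for _ in range(sweeps):
        biggest = 0.0
        for j in range(d):
            a = Hdiag[j]
            cj = g[j] + q[j] - a * D[j]
            raw = a * B[j] - cj
            if j == 0:
                u = raw / a
            else:
                u = np.sign(raw) * np.maximum(np.abs(raw) - lam_n, 0.0) / a
            dnew = u - B[j]
            delta = dnew - D[j]
            if np.any(delta != 0.0):
                q += H[:, :, j].T * delta[None, :]
                D[j] = dnew
                biggest = max(biggest, float(np.max(np.abs(delta))))
        if biggest < tol:
            break
    return D


def penalised_path_deviance(
    Xs: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    grid: np.ndarray,
    penalty: str,
    *,
    refresh_every: int = 8,
    step_tol: float = 0.04,
    max_steps: int = 4,
) -> np.ndarray:
    """Held-out binomial deviance along a lambda grid, batched over systems.

    The grid is swept in descending order with warm starts.  Each lambda
    takes one or more proximal-Newton steps with an *exact* gradient but a
    weighted-curvature matrix that is only refreshed every
    ``refresh_every`` grid points or after a large move — coefficients
    drift slowly along a geometric grid, so the stale-curvature step
    tracks the exact path to well below cross-validation noise (the model
    finally refit at the selected lambda is converged exactly).

    Parameters
    ----------
    Xs
        Standardised predictors (n x P), shared by all systems.
    train_mask
        (n x S) 0/1 training membership per system (fold x repeat).
    grid
        Lambda grid on the average-NLL scale, any order.

    Returns
    -------
    ndarray of shape (len(grid), S): mean held-out deviance
    ``-2/n_test * sum LL`` per lambda per system, in the order of ``grid``.
    """
    if penalty not in ("l1", "l2"):
        raise ValueError(f"unknown penalty {penalty!r}")
    n, P = Xs.shape
    S = train_mask.shape[1]
    d = P + 1
    M = np.ascontiguousarray(train_mask, dtype=float)
    n_train = M.sum(axis=0)
    Mtest = 1.0 - M
    n_test = Mtest.sum(axis=0)
    order = np.argsort(grid, kind="stable")[::-1]
    dev = np.empty((grid.shape[0], S))

    Z = np.column_stack([np.ones(n), Xs])
    iu = _pair_index(d)
    T = Z[:, iu[0]] * Z[:, iu[1]]
    slope_diag = np.arange(1, d)

    B = np.zeros((d, S))
    ybar = (M * y[:, None]).sum(axis=0) / n_train
    B[0] = np.log(ybar / (1.0 - ybar))
    lp = Z @ B
    p = expit(lp)

    H = None
    since_refresh = refresh_every  # force a build on the first lambda

    for idx in order:
        lam_n = grid[idx] * n_train
        for _step in range(max_steps):
            if since_refresh >= refresh_every or H is None:
                w = p * (1.0 - p) * M
                Hflat = T.T @ w
                H = np.zeros((S, d, d))
                H[:, iu[0], iu[1]] = Hflat.T
                H[:, iu[1], iu[0]] = Hflat.T
                H[:, np.arange(d), np.arange(d)] += 1e-10
                since_refresh = 0
            g = Z.T @ (M * (p - y[:, None]))  # exact NLL gradient, (d, S)
            if penalty == "l2":
                g[1:] += 2.0 * lam_n[None, :] * B[1:]
                Heff = H.copy()
                Heff[:, slope_diag, slope_diag] += 2.0 * lam_n[:, None]
                step = -np.linalg.solve(Heff, g.T[:, :, None])[:, :, 0].T
            else:
                step = _quadratic_lasso_cd(H, g, B, lam_n)
            np.clip(step, -4.0, 4.0, out=step)
            B += step
            lp = Z @ B
            p = expit(lp)
            move = float(np.max(np.abs(step)))
            if move >= 0.5:
                since_refresh = refresh_every  # curvature badly stale
            if move < step_tol:
                break
        since_refresh += 1
        # held-out deviance: -2 * (y*lp + log(1-p)) on test rows
        log1mp = np.log1p(-np.minimum(p, 1.0 - 1e-12))
        log1mp += y[:, None] * lp
        dev[idx] = (-2.0 / n_test) * np.einsum("ns,ns->s", Mtest, log1mp)
    return dev


def fit_penalised_std(
    Xs: np.ndarray,
    y: np.ndarray,
    penalty: str,
    lam: float,
    *,
    path_start: float | None = None,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Fit one penalised logistic model on standardised predictors.

    Solves down a short geometric warm-start path from ``path_start``
    (default: the l1 lambda-max or ``lam`` itself, whichever is larger)
    to the requested ``lam`` for stability, then polishes at ``lam``.
    Returns ``(intercept, slopes)`` on the standardised scale.
    """
    n, P = Xs.shape
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0.0:
        beta, _ = fit_logistic(Xs, y, tol=tol)
        return float(beta[0]), beta[1:]
    start = path_start if path_start is not None else max(lasso_lambda_max(Xs, y), lam)
    start = max(start, lam)
    n_steps = 1 if start <= lam * (1 + 1e-12) else 12
    path = np.geomspace(start, lam, n_steps)
    M = np.ones((n, 1))
    if penalty == "l2":
        Z = np.column_stack([np.ones(n), Xs])
        B = np.zeros((P + 1, 1))
        ybar = y.mean()
        B[0] = np.log(ybar / (1.0 - ybar))
        for lam_k in path:
            B = _batched_ridge_newton(
                Z, y, M, np.array([lam_k * n]), B, tol=tol * n, max_iter=60
            )
        return float(B[0, 0]), B[1:, 0].copy()
    elif penalty == "l1":
        ybar = y.mean()
        b0 = np.array([np.log(ybar / (1.0 - ybar))])
        B = np.zeros((P, 1))
        for lam_k in path:
            b0, B = _batched_lasso_cd(
                Xs, y, M, np.array([lam_k * n]), b0, B, tol=1e-9, max_outer=40
            )
        return float(b0[0]), B[:, 0].copy()
    raise ValueError(f"unknown penalty {penalty!r}")
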