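"""Data-generating mechanism for the simulation scenarios.

Populations contain P = 10 predictors drawn i.i.d. per row from a
multivariate normal with unit variances and a common pairwise correlation
(0 by default, 0.5 for the correlated sensitivity re-run).  The binary
outcome follows a logistic model whose slope coefficients take one of two
patterns:

* ``all10``  — all ten predictors truly associated:
  six at log(1.1), two at log(1.5), two at log(2);
* ``noise5`` — five true predictors and five noise terms:
  three at log(1.1), one at log(1.5), one at log(2), five at 0.

The intercept beta0 is solved numerically so that the marginal outcome
proportion equals the scenario's target prevalence (20% or 50%).  Eight
scenarios cross the two beta patterns, the two prevalences and the two
routes for anticipating the Cox–Snell R^2 in the sample-size calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort

__all__ = [
    "ScenarioSpec",
    "BETA_ALL10",
    "BETA_NOISE5",
    "scenario",
    "solve_intercept",
    "generate_population",
    "split_development",
    "iteration_rngs",
]

#: slope pattern with all 10 predictors truly associated with the outcome
BETA_ALL10 = np.array([np.log(1.1)] * 6 + [np.log(1.5)] * 2 + [np.log(2.0)] * 2)

#: slope pattern with 5 true predictors and 5 noise terms
BETA_NOISE5 = np.array([np.log(1.1)] * 3 + [np.log(1.5), np.log(2.0)] + [0.0] * 5)

# scenario table: (prevalence, r2 rule, beta pattern)
_SCENARIOS: dict[int, tuple[float, str, str]] = {
    1: (0.2, "population_r2", "all10"),
    2: (0.2, "population_r2", "noise5"),
    3: (0.5, "population_r2", "all10"),
    4: (0.5, "population_r2", "noise5"),
    5: (0.2, "max_r2_15pct", "all10"),
    6: (0.2, "max_r2_15pct", "noise5"),
    7: (0.5, "max_r2_15pct", "all10"),
    8: (0.5, "max_r2_15pct", "noise5"),
}


@dataclass
class ScenarioSpec:
    """Full description of one simulation scenario."""

    scenario_id: int
    prevalence_target: float
    beta: np.ndarray
    r2_rule: Literal["population_r2", "max_r2_15pct"]
    predictor_correlation: float = 0.0
    n_population: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must lie in (0, 1)")
        if not (0.0 <= self.predictor_correlation < 1.0):
            raise ValueError("predictor_correlation must lie in [0, 1)")
        if self.r2_rule not in ("population_r2", "max_r2_15pct"):
            raise ValueError(f"unknown r2_rule {self.r2_rule!r}")
        if self.scenario_id in _SCENARIOS:
            prev, rule, pattern = _SCENARIOS[self.scenario_id]
            ref = BETA_ALL10 if pattern == "all10" else BETA_NOISE5
            if self.prevalence_target != prev or self.r2_rule != rule:
                raise ValueError(
                    f"scenario {self.scenario_id} requires prevalence {prev} "
                    f"and r2_rule {rule!r}"
                )
            if self.beta.shape != ref.shape or not np.allclose(self.beta, ref):
                raise ValueError(
                    f"scenario {self.scenario_id} beta must match the "
                    f"{pattern!r} pattern"
                )

    @property
    def P(self) -> int:
        return self.beta.shape[0]


def scenario(
    scenario_id: int,
    *,
    predictor_correlation: float = 0.0,
    n_population: int = 1_000_000,
    seed: int = 0,
) -> ScenarioSpec:
    """Construct the :class:`ScenarioSpec` for one of the eight scenarios."""
    if scenario_id not in _SCENARIOS:
        raise ValueError(f"scenario_id must be 1-8, got {scenario_id}")
    prev, rule, pattern = _SCENARIOS[scenario_id]
    beta = BETA_ALL10 if pattern == "all10" else BETA_NOISE5
    return ScenarioSpec(
        scenario_id=scenario_id,
        prevalence_target=prev,
        beta=beta.copy(),
        r2_rule=rule,
        predictor_correlation=predictor_correlation,
        n_population=n_population,
        seed=seed,
    )


def _lp_sd(beta: np.ndarray, correlation: float) -> float:
    """Standard deviation of X @ beta under the compound-symmetric normal.

    With unit variances and common correlation rho,
    var(X beta) = (1 - rho) * sum(beta^2) + rho * (sum beta)^2.
    """
    beta = np.asarray(beta, dtype=float)
    return float(
        np.sqrt(
            (1.0 - correlation) * np.sum(beta**2)
            + correlation * np.sum(beta) ** 2
        )
    )


def solve_intercept(
    beta: np.ndarray,
    prevalence_target: float,
    correlation: float = 0.0,
    *,
    n_quad: int = 120,
    tol: float = 1e-12,
) -> float:
    """Solve for beta0 so the marginal outcome proportion hits the target.

    The linear predictor L = X @ beta is univariate normal with mean 0 and
    known variance, so the marginal prevalence E[expit(beta0 + L)] is a 1-D
    Gaussian integral, evaluated here by Gauss–Hermite quadrature
    (probabilists' weights) and inverted by Brent root-finding.  This is
    deterministic — no Monte-Carlo noise enters the generating model.
    """
    if not (0.0 < prevalence_target < 1.0):
        raise ValueError("prevalence_target must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all():
        raise ValueError("beta must be finite")
    sd = _lp_sd(beta, correlation)
    if sd == 0.0:
        return float(logit(prevalence_target))

    nodes, weights = hermegauss(n_quad)
    weights = weights / weights.sum()
    L = sd * nodes

    def marginal_minus_target(b0: float) -> float:
        return float(weights @ expit(b0 + L)) - prevalence_target

    # expit is monotone in b0, so a wide bracket around logit(target) works
    lo = logit(prevalence_target) - 6.0 * sd - 2.0
    hi = logit(prevalence_target) + 6.0 * sd + 2.0
    if marginal_minus_target(lo) > 0 or marginal_minus_target(hi) < 0:
        raise RuntimeError(
            f"intercept root-finder bracket [{lo:.3f}, {hi:.3f}] does not "
            "enclose the solution"
        )
    return float(brentq(marginal_minus_target, lo, hi, xtol=tol))


def generate_population(
    spec: ScenarioSpec, rng: Optional[np.random.Generator] = None
) -> Cohort:
    """Draw the population-level cohort for a scenario.

    Rows of X are i.i.d. N(0, Sigma) with unit variances and all
    off-diagonal entries equal to ``spec.predictor_correlation``; the
    outcome is Bernoulli(expit(beta0 + X beta)).
    """
    if spec.n_population <= spec.P:
        raise ValueError(
            f"degenerate population: n_population={spec.n_population} "
            f"must exceed P={spec.P}"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, P, rho = spec.n_population, spec.P, spec.predictor_correlation
    Z = rng.standard_normal((n, P))
    if rho > 0.0:
        # compound symmetry: X = sqrt(rho)*g + sqrt(1-rho)*Z, g shared per row
        g = rng.standard_normal((n, 1))
        X = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * Z
    else:
        X = Z
    beta0 = solve_intercept(spec.beta, spec.prevalence_target, rho)
    lp = beta0 + X @ spec.beta
    y = (rng.random(n) < expit(lp)).astype(float)
    return Cohort(X=X, y=y, true_lp=lp)


def split_development(
    population: Cohort, n_dev: int, seed: int | np.random.Generator
) -> Tuple[Cohort, Cohort]:
    """Sample a development cohort without replacement; complement validates.

    Returns ``(development, validation)`` where the development cohort has
    exactly ``n_dev`` rows drawn uniformly without replacement and the
    validation cohort is the exact complement.
    """
    if not (0 < n_dev < population.n):
        raise ValueError(
            f"n_dev must lie strictly between 0 and the population size "
            f"{population.n}, got {n_dev}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm = rng.permutation(population.n)
    return population.subset(perm[:n_dev]), population.subset(perm[n_dev:])


def iteration_rngs(
    root_seed: int, scenario_id: int, iteration: int, n_streams: int = 6
) -> list[np.random.Generator]:
    """Independent, reproducible random streams for one simulation iteration.

    A single root seed and the (scenario, iteration) coordinates determine
    every stream via :class:`numpy.random.SeedSequence` spawn keys — a
    counter scheme, so results are identical regardless of execution order
    or parallelism.  Stream slots (by convention): 0 population,
    1 development split, 2 bootstrap shrinkage, 3 CV folds, 4 validation
    sub-sampling, 5 spare.
    """
    return [
        np.random.default_rng(
            np.random.SeedSequence(
                entropy=root_seed, spawn_key=(scenario_id, iteration, s)
            )
        )
        for s in range(n_streams)
    ]
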