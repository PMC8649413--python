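"""Minimum development sample sizes for logistic prediction models.

Implements the published minimum-sample-size criteria for binary-outcome
prediction models (the framework behind the pmsampsize calculators) as
used throughout the package:

* **Criterion 1** — limit overfitting by targeting a uniform shrinkage
  factor S (default 0.9):
  ``n = P / ((S - 1) * ln(1 - R2/S))``, rounded up.
* **Criterion 2** — small absolute difference between apparent and
  adjusted Cox–Snell R^2 (delta = 0.05 by default), re-expressed as a
  shrinkage requirement ``S = R2 / (R2 + delta * max R2)``.
* **Criterion 3** — precise estimation of the overall risk (intercept):
  ``n = (z_{0.975} / delta)^2 * phi * (1 - phi)`` with delta = 0.05.

Criteria 2 and 3 follow the cited sample-size methodology and are
optional extension points; with the defaults used here criterion 1
drives the overall minimum.  The anticipated R^2 may be pre-specified
directly, taken as 15% of the prevalence-dependent maximum
``max(R2) = 1 - (phi^phi * (1-phi)^(1-phi))^2``, or estimated from a
population-level cohort via the likelihood ratio of a full model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .cohort import Cohort

__all__ = [
    "SampleSizeSpec",
    "SampleSizeResult",
    "max_cox_snell_r2",
    "anticipated_r2_15pct",
    "adjusted_cox_snell_r2",
    "n_criterion1",
    "n_criterion2",
    "n_criterion3",
    "min_sample_size",
    "population_r2",
]


@dataclass
class SampleSizeSpec:
    """Inputs of a minimum-sample-size calculation."""

    P: int
    r2_anticipated: float
    prevalence: float
    S_target: float = 0.9

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 < self.S_target <= 1.0):
            raise ValueError("S_target must lie in (0, 1]")
        if not (0.0 < self.r2_anticipated < max_cox_snell_r2(self.prevalence)):
            raise ValueError(
                "r2_anticipated must lie in (0, max_cox_snell_r2(prevalence))"
            )


@dataclass
class SampleSizeResult:
    """Per-criterion minima and the overall minimum sample size."""

    n_criterion1: int
    n_min: int
    driving_criterion: int
    spec: SampleSizeSpec
    n_criterion2: Optional[int] = None
    n_criterion3: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "n_criterion1": self.n_criterion1,
            "n_criterion2": self.n_criterion2,
            "n_criterion3": self.n_criterion3,
            "n_min": self.n_min,
            "driving_criterion": self.driving_criterion,
            "P": self.spec.P,
            "S_target": self.spec.S_target,
            "r2_anticipated": self.spec.r2_anticipated,
            "prevalence": self.spec.prevalence,
        }


def max_cox_snell_r2(prevalence: float) -> float:
    """Maximum achievable Cox–Snell R^2 for a binary outcome.

    ``1 - (phi^phi * (1-phi)^(1-phi))^2``; symmetric about 0.5 where it
    peaks at 0.75.
    """
    phi = prevalence
    if not (0.0 < phi < 1.0):
        raise ValueError("prevalence must lie strictly in (0, 1)")
    ll_null = phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi)
    return 1.0 - math.exp(2.0 * ll_null)


def anticipated_r2_15pct(prevalence: float) -> float:
    """Conservative anticipated R^2: 15% of the achievable maximum."""
    return 0.15 * max_cox_snell_r2(prevalence)


def adjusted_cox_snell_r2(LR: float, n: int, P: int) -> float:
    """Adjusted (optimism-corrected) Cox–Snell R^2 from a likelihood ratio.

    ``R2 = (1 + P/(n*log(1-(1-exp(-LR/n))))) * (1 - exp(-LR/n))``, which
    collapses algebraically to ``(1 - P/LR) * (1 - exp(-LR/n))`` since the
    inner log equals ``-LR/n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if P < 0:
        raise ValueError("P must be nonnegative")
    if LR < 0:
        raise ValueError("LR must be nonnegative")
    if LR == 0.0:
        if P > 0:
            warnings.warn(
                "LR = 0 with P > 0: adjustment undefined, returning 0",
                RuntimeWarning,
                stacklevel=2,
            )
        return 0.0
    apparent = 1.0 - math.exp(-LR / n)
    # the inner log(1 - (1 - exp(-LR/n))) collapses exactly to -LR/n;
    # evaluating it that way avoids log(0) when LR/n is large
    inner_log = -LR / n
    return (1.0 + P / (n * inner_log)) * apparent


def n_criterion1(P: int, S_target: float, r2: float) -> int:
    """Minimum n so expected uniform shrinkage meets the target S.

    ``ceil( P / ((S - 1) * ln(1 - R2/S)) )``.  Both denominator factors
    are negative for S in (0,1) and 0 < R2 < S, so the result is
    positive; ``r2 >= S_target`` makes the log argument non-positive and
    is an error.
    """
    if not (0.0 < S_target < 1.0):
        raise ValueError("S_target must lie in (0, 1)")
    if not (0.0 < r2 < S_target):
        raise ValueError(
            f"anticipated R2 must lie in (0, S_target={S_target}); got {r2}"
        )
    return math.ceil(P / ((S_target - 1.0) * math.log(1.0 - r2 / S_target)))


def n_criterion2(P: int, r2: float, prevalence: float, delta: float = 0.05) -> int:
    """Minimum n for a small apparent-vs-adjusted R^2 difference.

    Follows the cited sample-size methodology: the allowable optimism
    ``delta * max(R2)`` is re-expressed as a shrinkage requirement
    ``S = R2 / (R2 + delta * max R2)`` and plugged into the criterion-1
    formula.  Extension point; not a driver of the headline results.
    """
    S = r2 / (r2 + delta * max_cox_snell_r2(prevalence))
    return math.ceil(P / ((S - 1.0) * math.log(1.0 - r2 / S)))


def n_criterion3(prevalence: float, delta: float = 0.05) -> int:
    """Minimum n for a precise overall risk estimate (+/- delta).

    Normal-approximation precision of a proportion:
    ``(z_{0.975}/delta)^2 * phi * (1-phi)``.  Extension point.
    """
    z = 1.96
    return math.ceil((z / delta) ** 2 * prevalence * (1.0 - prevalence))


def min_sample_size(
    spec: SampleSizeSpec, include_criteria_2_3: bool = True
) -> SampleSizeResult:
    """Overall minimum sample size: the maximum over the enabled criteria."""
    n1 = n_criterion1(spec.P, spec.S_target, spec.r2_anticipated)
    n2 = n3 = None
    if include_criteria_2_3:
        n2 = n_criterion2(spec.P, spec.r2_anticipated, spec.prevalence)
        n3 = n_criterion3(spec.prevalence)
    candidates = {1: n1}
    if n2 is not None:
        candidates[2] = n2
    if n3 is not None:
        candidates[3] = n3
    driving = max(candidates, key=lambda c: (candidates[c], -c))
    return SampleSizeResult(
        n_criterion1=n1,
        n_criterion2=n2,
        n_criterion3=n3,
        n_min=candidates[driving],
        driving_criterion=driving,
        spec=spec,
    )


def population_r2(population: Cohort) -> float:
    """Adjusted Cox–Snell R^2 of the full model fit on population data.

    Fits the all-predictor logistic model by MLE, forms the likelihood
    ratio against the intercept-only model, and applies
    :func:`adjusted_cox_snell_r2`.
    """
    from .estimators import fit_mle, lr_statistic  # local import: avoid cycle

    model = fit_mle(population)
    LR = lr_statistic(model, population)
    return adjusted_cox_snell_r2(LR, population.n, population.P)
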