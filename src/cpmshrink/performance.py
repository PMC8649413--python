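"""Validation performance metrics and cross-iteration summaries.

Calibration is quantified by the calibration slope (slope of a logistic
regression of observed outcomes on the model's linear predictor; < 1
indicates overfitting) and calibration-in-the-large (intercept of the
same regression with the slope fixed at 1; < 0 means the model
overestimates overall risk).  Discrimination is the AUC.  Overall fit is
summarised by the Cox–Snell R^2 and the Brier score.  Distributions of
metrics across simulation iterations or bootstrap draws are summarised
by median, 2.5–97.5% quantiles, IQR and root-mean-square deviation from
the ideal reference value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logit
from sklearn.metrics import roc_auc_score

from ._glm import batched_calibration_fits, batched_citl_fits, bernoulli_loglik
from .cohort import Cohort
from .estimators import FittedModel

__all__ = [
    "PerformanceMetrics",
    "SummaryRow",
    "calibration_slope",
    "calibration_in_the_large",
    "auc",
    "brier",
    "cox_snell_r2_validation",
    "rmsd",
    "summarise",
    "evaluate_model",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("citl", "slope", "auc", "cox_snell_r2", "brier")


@dataclass
class PerformanceMetrics:
    """Metrics of one model on one dataset.  NaN flags a degenerate metric."""

    citl: float
    slope: float
    auc: float
    cox_snell_r2: float
    brier: float

    def to_dict(self) -> dict:
        return {
            "citl": self.citl,
            "slope": self.slope,
            "auc": self.auc,
            "cox_snell_r2": self.cox_snell_r2,
            "brier": self.brier,
        }


@dataclass
class SummaryRow:
    """Distributional summary of one metric across iterations/draws."""

    median: float
    q025: float
    q975: float
    iqr: float
    n_iterations: int
    rmsd: Optional[float] = None


def _check_two_class(y: np.ndarray) -> None:
    if not (0.0 < np.mean(y) < 1.0):
        raise ValueError("outcome must contain both classes")


def calibration_slope(lp: np.ndarray, y: np.ndarray) -> float:
    """Slope of ``logit P(y=1) = a + b*lp`` fitted by MLE.

    Returns NaN (with a log record) when the linear predictor is
    degenerate (zero variance — e.g. an l1 fit that shrank every slope to
    zero), so a single pathological model cannot abort a simulation loop.
    """
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_class(y)
    if lp.std() < 1e-12:
        logger.warning("degenerate (constant) linear predictor; slope flagged NaN")
        return float("nan")
    _, b = batched_calibration_fits(lp[:, None], y)
    return float(b[0])


def calibration_in_the_large(lp: np.ndarray, y: np.ndarray) -> float:
    """Intercept of a logistic fit with ``lp`` as fixed offset (slope = 1)."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_class(y)
    return float(batched_citl_fits(lp[:, None], y)[0])


def auc(p: np.ndarray, y: np.ndarray) -> float:
    """Probability a random event outscores a random non-event (ties 1/2)."""
    y = np.asarray(y, dtype=float)
    _check_two_class(y)
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def brier(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((p - y) ** 2))


def cox_snell_r2_validation(p: np.ndarray, y: np.ndarray) -> float:
    """Likelihood-based Cox–Snell R^2 of predictions against outcomes.

    ``1 - exp((2/n) * (LL_null - LL_model))`` with the null likelihood at
    the observed mean; in-sample on an MLE fit this reduces to
    ``1 - exp(-LR/n)``.  Probabilities exactly 0 or 1 are clipped at
    1e-15 with a warning when discordant.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    discordant = ((p <= 0.0) & (y == 1.0)) | ((p >= 1.0) & (y == 0.0))
    if discordant.any():
        logger.warning(
            "%d predictions at exact 0/1 discordant with outcomes; clipped",
            int(discordant.sum()),
        )
    p = np.clip(p, 1e-15, 1.0 - 1e-15)
    ll_model = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    ll_null = float(bernoulli_loglik(np.full(n, logit(y.mean())), y))
    return 1.0 - float(np.exp((2.0 / n) * (ll_null - ll_model)))


def rmsd(values: np.ndarray, reference: float) -> float:
    """Root-mean-square deviation from a reference (0 for CITL, 1 for slope)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("values must be non-empty")
    return float(np.sqrt(np.mean((values - reference) ** 2)))


def summarise(values: np.ndarray, reference: Optional[float] = None) -> SummaryRow:
    """Median, 2.5/97.5% quantiles (linear interpolation), IQR and count.

    NaN entries (flagged-degenerate metrics) are excluded, with the count
    logged.  ``reference`` additionally populates the RMSD field.
    """
    values = np.asarray(values, dtype=float)
    keep = values[~np.isnan(values)]
    n_dropped = values.size - keep.size
    if n_dropped:
        logger.info("summarise: excluded %d flagged-missing values", n_dropped)
    if keep.size == 0:
        raise ValueError("values must contain at least one non-missing entry")
    q025, q25, med, q75, q975 = np.quantile(keep, [0.025, 0.25, 0.5, 0.75, 0.975])
    return SummaryRow(
        median=float(med),
        q025=float(q025),
        q975=float(q975),
        iqr=float(q75 - q25),
        n_iterations=int(keep.size),
        rmsd=None if reference is None else rmsd(keep, reference),
    )


def evaluate_model(
    model: FittedModel, data: Cohort, metrics: tuple[str, ...] = METRIC_NAMES
) -> PerformanceMetrics:
    """All requested performance metrics for one model on one cohort."""
    lp = model.linear_predictor(data.X)
    p = model.predict(data.X)
    vals = dict.fromkeys(METRIC_NAMES, float("nan"))
    degenerate = lp.std() < 1e-12
    if "citl" in metrics:
        vals["citl"] = calibration_in_the_large(lp, data.y)
    if "slope" in metrics and not degenerate:
        vals["slope"] = calibration_slope(lp, data.y)
    if "auc" in metrics and not degenerate:
        vals["auc"] = auc(p, data.y)
    if "cox_snell_r2" in metrics:
        vals["cox_snell_r2"] = cox_snell_r2_validation(p, data.y)
    if "brier" in metrics:
        vals["brier"] = brier(p, data.y)
    return PerformanceMetrics(**vals)
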