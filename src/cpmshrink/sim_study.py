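"""Orchestration of the eight-scenario simulation study.

Each iteration of a scenario: (1) generate a population-level cohort;
(2) compute the minimum development sample size by the scenario's rule
for anticipating the Cox–Snell R^2 (15%-of-maximum closed form, or the
adjusted R^2 of a full-model fit on the population); (3) sample the
development cohort without replacement, the complement forming an
extremely large independent validation set; (4) develop a model with
every configured strategy; (5) evaluate each on the validation
complement (optionally sub-sampled to a cap, since validation-set noise
is negligible next to development-sample variability).

Results are returned as one tidy table (scenario x iteration x method)
from which Table-style summaries — median (2.5%, 97.5%) calibration
slope per cell, RMSD versus the ideal value, IQR of slope and of tuning
parameters — are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._glm import batched_calibration_fits, batched_citl_fits
from .cohort import Cohort
from .estimators import develop_model
from .performance import METRIC_NAMES, auc, brier, cox_snell_r2_validation, summarise
from .sample_size import SampleSizeSpec, anticipated_r2_15pct, min_sample_size, population_r2
from .synthetic_data import ScenarioSpec, generate_population, iteration_rngs, scenario, split_development

__all__ = [
    "DEFAULT_METHODS",
    "StudyConfig",
    "run_iteration",
    "run_study",
    "summarise_study",
    "format_cell",
    "median_slope_iqr",
]

logger = logging.getLogger(__name__)

#: the eight analytic strategies compared in the study, in reporting order
DEFAULT_METHODS = (
    "mle",
    "closed_form_shrinkage",
    "bootstrap_shrinkage",
    "firth",
    "lasso",
    "lasso_repeat",
    "ridge",
    "ridge_repeat",
)


@dataclass
class StudyConfig:
    """Settings of a simulation run.

    The defaults are the full-scale study conditions (500 iterations,
    10^6 population, 500 inner bootstraps, 100 CV repeats).
    ``scale_factor`` < 1 produces an honest desk-scale run: it uniformly
    reduces iteration, population, bootstrap and CV-repeat counts via
    :meth:`scaled` and is stamped into every output row.
    """

    scenarios: Sequence[int] = tuple(range(1, 9))
    n_iterations: int = 500
    methods: Sequence[str] = DEFAULT_METHODS
    B_shrink: int = 500
    cv_repeats: int = 100
    cv_folds: int = 10
    n_population: int = 1_000_000
    root_seed: int = 0
    validation_cap: Optional[int] = 100_000
    predictor_correlation: float = 0.0
    S_target: float = 0.9
    metrics: Sequence[str] = METRIC_NAMES
    scale_factor: float = 1.0

    def scaled(self, factor: float) -> "StudyConfig":
        """Uniformly scaled-down copy (counts reduced, factor recorded)."""
        if not (0.0 < factor <= 1.0):
            raise ValueError("scale factor must lie in (0, 1]")
        shrink = lambda x: max(1, math.ceil(x * factor))  # noqa: E731
        return replace(
            self,
            n_iterations=shrink(self.n_iterations),
            n_population=shrink(self.n_population),
            B_shrink=shrink(self.B_shrink),
            cv_repeats=shrink(self.cv_repeats),
            scale_factor=self.scale_factor * factor,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _method_options(method: str, config: StudyConfig) -> tuple[str, dict]:
    """Map a study method label to develop_model's method + options."""
    if method in ("mle", "closed_form_shrinkage", "firth"):
        return method, {}
    if method == "bootstrap_shrinkage":
        return method, {"B_shrink": config.B_shrink}
    if method == "lasso":
        return "lasso", {"cv_folds": config.cv_folds, "cv_repeats": 1}
    if method == "lasso_repeat":
        return "lasso", {"cv_folds": config.cv_folds, "cv_repeats": config.cv_repeats}
    if method == "lasso_1se":
        return "lasso", {"cv_folds": config.cv_folds, "cv_repeats": 1, "selection_rule": "one_se"}
    if method == "ridge":
        return "ridge", {"cv_folds": config.cv_folds, "cv_repeats": 1}
    if method == "ridge_repeat":
        return "ridge", {"cv_folds": config.cv_folds, "cv_repeats": config.cv_repeats}
    if method == "ridge_1se":
        return "ridge", {"cv_folds": config.cv_folds, "cv_repeats": 1, "selection_rule": "one_se"}
    raise ValueError(f"unknown study method {method!r}")


def _n_dev_for(spec: ScenarioSpec, population: Cohort, config: StudyConfig) -> int:
    if spec.r2_rule == "max_r2_15pct":
        r2 = anticipated_r2_15pct(spec.prevalence_target)
    else:
        r2 = population_r2(population)
    result = min_sample_size(
        SampleSizeSpec(
            P=spec.P,
            r2_anticipated=r2,
            prevalence=spec.prevalence_target,
            S_target=config.S_target,
        )
    )
    return result.n_min


def run_iteration(
    spec: ScenarioSpec, config: StudyConfig, iteration: int
) -> list[dict]:
    """One simulation iteration; returns one tidy row dict per method.

    Per-method failures are recorded in the row (metrics NaN, ``error``
    filled) and do not abort the iteration.  All randomness derives from
    ``config.root_seed`` and the (scenario, iteration) coordinates, so
    iterations are reproducible independently of execution order.
    """
    rngs = iteration_rngs(config.root_seed, spec.scenario_id, iteration)
    spec = replace(spec, n_population=config.n_population)
    population = generate_population(spec, rng=rngs[0])
    n_dev = _n_dev_for(spec, population, config)
    dev, val = split_development(population, n_dev, rngs[1])
    if config.validation_cap is not None and val.n > config.validation_cap:
        keep = rngs[4].choice(val.n, size=config.validation_cap, replace=False)
        val = val.subset(keep)

    models = {}
    errors = {}
    for mi, method in enumerate(config.methods):
        name, opts = _method_options(method, config)
        method_rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=config.root_seed,
                spawn_key=(spec.scenario_id, iteration, 10 + mi),
            )
        )
        try:
            models[method] = develop_model(dev, name, seed=method_rng, **opts)
        except Exception as exc:  # record, do not abort the iteration
            errors[method] = str(exc)
            logger.warning(
                "scenario %d iter %d method %s failed: %s",
                spec.scenario_id, iteration, method, exc,
            )

    # batched validation metrics across the fitted methods
    fitted = list(models)
    rows_metrics: dict[str, dict[str, float]] = {
        m: dict.fromkeys(METRIC_NAMES, float("nan")) for m in config.methods
    }
    if fitted:
        LP = np.column_stack([models[m].linear_predictor(val.X) for m in fitted])
        live = np.array([models[m].coefficients.any() for m in fitted])
        if "slope" in config.metrics and live.any():
            _, slopes = batched_calibration_fits(LP[:, live], val.y)
            for m, s in zip(np.array(fitted)[live], slopes):
                rows_metrics[m]["slope"] = float(s)
        if "citl" in config.metrics:
            citls = batched_citl_fits(LP, val.y)
            for m, c in zip(fitted, citls):
                rows_metrics[m]["citl"] = float(c)
        prob_metrics = {"auc", "cox_snell_r2", "brier"} & set(config.metrics)
        if prob_metrics:
            from scipy.special import expit

            for mi, m in enumerate(fitted):
                p = expit(LP[:, mi])
                if "auc" in prob_metrics and live[mi]:
                    rows_metrics[m]["auc"] = auc(p, val.y)
                if "cox_snell_r2" in prob_metrics:
                    rows_metrics[m]["cox_snell_r2"] = cox_snell_r2_validation(p, val.y)
                if "brier" in prob_metrics:
                    rows_metrics[m]["brier"] = brier(p, val.y)

    rows = []
    for method in config.methods:
        row = {
            "scenario": spec.scenario_id,
            "iteration": iteration,
            "n_dev": n_dev,
            "n_val": val.n,
            "method": method,
            "scale_factor": config.scale_factor,
            "error": errors.get(method, ""),
            "tuning_S": float("nan"),
            "tuning_lambda": float("nan"),
        }
        if method in models:
            t = models[method].tuning
            if t.shrinkage_S is not None:
                row["tuning_S"] = t.shrinkage_S
            if t.lam is not None:
                row["tuning_lambda"] = t.lam
        row.update(rows_metrics[method])
        rows.append(row)
    return rows


def run_study(
    config: StudyConfig,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario x iteration; returns the tidy results table.

    With ``checkpoint_dir`` set, per-scenario CSVs are written as each
    scenario completes and already-present scenarios are loaded instead
    of recomputed, making long runs resumable.
    """
    frames = []
    for sid in config.scenarios:
        ckpt = None
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir) / f"scenario_{sid:02d}.csv"
            if ckpt.exists():
                logger.info("scenario %d loaded from checkpoint", sid)
                loaded = pd.read_csv(ckpt)
                loaded["error"] = loaded["error"].fillna("")
                frames.append(loaded)
                continue
        spec = scenario(
            sid,
            predictor_correlation=config.predictor_correlation,
            n_population=config.n_population,
        )
        rows: list[dict] = []
        for it in range(config.n_iterations):
            rows.extend(run_iteration(spec, config, it))
            if progress and (it + 1) % 25 == 0:
                logger.info("scenario %d: %d/%d iterations", sid, it + 1, config.n_iterations)
        frame = pd.DataFrame(rows)
        if ckpt is not None:
            ckpt.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(ckpt, index=False)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def format_cell(s) -> str:
    """Render a summary as the conventional 'median (q2.5, q97.5)' cell."""
    return f"{s.median:.2f} ({s.q025:.2f}, {s.q975:.2f})"


_REFERENCES = {"slope": 1.0, "citl": 0.0}


def summarise_study(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per scenario x method summaries of every metric.

    Returns ``{"summary": tidy long table, "slope_table": wide
    median-(2.5,97.5) calibration-slope table}``.  The long table carries
    median/quantiles/IQR for each metric plus RMSD for the calibration
    slope (reference 1) and calibration-in-the-large (reference 0), and
    the IQR of the tuning draws.
    """
    if results.empty:
        raise ValueError("results table is empty")
    long_rows = []
    methods_order = list(dict.fromkeys(results["method"]))
    for (sid, method), grp in results.groupby(["scenario", "method"], sort=True):
        for metric in METRIC_NAMES:
            if metric not in grp or grp[metric].isna().all():
                continue
            s = summarise(grp[metric].to_numpy(), reference=_REFERENCES.get(metric))
            long_rows.append(
                {
                    "scenario": sid,
                    "method": method,
                    "metric": metric,
                    "median": s.median,
                    "q025": s.q025,
                    "q975": s.q975,
                    "iqr": s.iqr,
                    "rmsd": s.rmsd,
                    "n_iterations": s.n_iterations,
                    "cell": format_cell(s),
                    "iqr_tuning_S": float(
                        np.subtract(*grp["tuning_S"].quantile([0.75, 0.25]))
                    )
                    if grp["tuning_S"].notna().any()
                    else float("nan"),
                    "iqr_tuning_lambda": float(
                        np.subtract(*grp["tuning_lambda"].quantile([0.75, 0.25]))
                    )
                    if grp["tuning_lambda"].notna().any()
                    else float("nan"),
                }
            )
    summary = pd.DataFrame(long_rows)
    slope = summary[summary["metric"] == "slope"]
    slope_table = (
        slope.pivot(index="scenario", columns="method", values="cell")
        .reindex(columns=[m for m in methods_order if m in set(slope["method"])])
    )
    return {"summary": summary, "slope_table": slope_table}


def median_slope_iqr(summary: pd.DataFrame) -> float:
    """Median, over scenario x method cells, of the calibration-slope IQR."""
    slope = summary[summary["metric"] == "slope"]
    if slope.empty:
        raise ValueError("no calibration-slope summaries present")
    return float(slope["iqr"].median())
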