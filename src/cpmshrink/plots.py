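"""Boxplot/violin figures of performance and tuning-parameter variability."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["slope_distribution_plot", "tuning_distribution_plot", "adjusted_draws_plot"]


def _box_violin(ax, groups: list[np.ndarray], labels: list[str], rng) -> None:
    groups = [g[~np.isnan(g)] for g in groups]
    pos = np.arange(1, len(groups) + 1)
    ax.violinplot(groups, positions=pos, showextrema=False)
    ax.boxplot(groups, positions=pos, widths=0.15, showfliers=False)
    for x, g in zip(pos, groups):  # jittered points aid visual clarity
        ax.plot(x + rng.uniform(-0.08, 0.08, g.size), g, ".", ms=2, alpha=0.25)
    ax.set_xticks(pos)
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)


def slope_distribution_plot(
    results: pd.DataFrame, out: Optional[str | Path] = None, seed: int = 0
):
    """Per-scenario panels of the validation calibration-slope distribution."""
    rng = np.random.default_rng(seed)
    scenarios = sorted(results["scenario"].unique())
    methods = list(dict.fromkeys(results["method"]))
    ncol = min(4, len(scenarios))
    nrow = -(-len(scenarios) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False)
    for ax, sid in zip(axes.flat, scenarios):
        grp = results[results["scenario"] == sid]
        groups = [grp.loc[grp["method"] == m, "slope"].to_numpy() for m in methods]
        _box_violin(ax, groups, methods, rng)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_title(f"scenario {sid}")
        ax.set_ylabel("calibration slope")
    for ax in axes.flat[len(scenarios):]:
        ax.set_visible(False)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def tuning_distribution_plot(
    results: pd.DataFrame, out: Optional[str | Path] = None, seed: int = 0
):
    """Shrinkage-factor and penalty distributions across iterations.

    Panel A: uniform shrinkage factors S; Panel B/C: lasso and ridge
    lambda draws (log scale), single vs repeated cross-validation.
    """
    rng = np.random.default_rng(seed)
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    panels = [
        ("S", ["closed_form_shrinkage", "bootstrap_shrinkage"], "tuning_S", False),
        ("lasso lambda", ["lasso", "lasso_repeat"], "tuning_lambda", True),
        ("ridge lambda", ["ridge", "ridge_repeat"], "tuning_lambda", True),
    ]
    for ax, (title, methods, col, logscale) in zip(axes, panels):
        present = [m for m in methods if (results["method"] == m).any()]
        groups = [
            results.loc[results["method"] == m, col].to_numpy() for m in present
        ]
        if not groups:
            ax.set_visible(False)
            continue
        _box_violin(ax, groups, present, rng)
        if logscale:
            ax.set_yscale("log")
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def adjusted_draws_plot(
    report_draws: dict[str, np.ndarray],
    metric: str = "slope",
    out: Optional[str | Path] = None,
    seed: int = 0,
):
    """Optimism-adjusted bootstrap draws per method (internal validation)."""
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(1.2 * len(report_draws) + 2, 3.6))
    methods = list(report_draws)
    _box_violin(ax, [np.asarray(report_draws[m]) for m in methods], methods, rng)
    if metric == "slope":
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel(f"optimism-adjusted {metric}")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
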