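"""Matplotlib views of the fitted models (imported lazily, Agg-safe).

Each function returns the Axes it drew on, so figures compose normally.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .models import CongruenceResults, WithinStudyReport

__all__ = ["plot_congruence", "plot_within_study_slopes"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_congruence(
    rows: pd.DataFrame,
    fit: CongruenceResults,
    predictor: str = "logit_fst_nonneutral",
    ax=None,
):
    """Scatter of logit(P_ST) against one logit F_ST predictor with the
    fitted line (covariates other than the predictor held at their means)."""
    ax = _get_ax(ax)
    data = fit.model.data
    ax.scatter(data[predictor], data[fit.model.response], s=18, alpha=0.6,
               edgecolor="none")
    grid = np.linspace(data[predictor].min(), data[predictor].max(), 50)
    intercept = fit.params.get("Intercept", 0.0)
    offset = sum(
        fit.params[name] * data[name].mean()
        for name in fit.params.index
        if name not in ("Intercept", predictor) and name in data.columns
    )
    ax.plot(grid, intercept + offset + fit.params[predictor] * grid, lw=2)
    ax.set_xlabel(predictor)
    ax.set_ylabel(fit.model.response)
    ax.set_title(f"slope = {fit.params[predictor]:.2f}, R$^2$ = {fit.r_squared:.2f}")
    return ax


def plot_within_study_slopes(report: WithinStudyReport, ax=None):
    """Per-combination slope estimates with +/- 2 SE bars and the mean slope."""
    ax = _get_ax(ax)
    slopes = sorted(report.slopes, key=lambda s: s.beta)
    y = np.arange(len(slopes))
    betas = [s.beta for s in slopes]
    errs = [2 * s.se for s in slopes]
    ax.errorbar(betas, y, xerr=errs, fmt="o", ms=4, lw=1, capsize=2)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.axvline(report.summary.mean_slope, color="C1", lw=1.5, ls="--",
               label=f"mean = {report.summary.mean_slope:.2f}")
    ax.set_yticks(y)
    ax.set_yticklabels([s.combo_id for s in slopes], fontsize=6)
    ax.set_xlabel("within-study logit(P_ST) ~ logit(nnF_ST) slope")
    ax.legend(frameon=False)
    return ax
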