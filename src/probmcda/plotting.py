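"""Optional plotting helpers (value densities and scenario forest plot)."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .engine import ValueSummary

__all__ = ["plot_value_densities", "plot_scenario_comparison"]


def plot_value_densities(summary: ValueSummary, ax=None):
    """Kernel-density curves of the value distribution per alternative."""
    if ax is None:
        _, ax = plt.subplots()
    for rec in summary.records:
        if rec.density_grid is None:
            ax.axvline(rec.mean, linestyle="--", label=f"{rec.name} (point)")
        else:
            ax.plot(rec.density_grid, rec.density_pdf, label=rec.name)
    ax.set_xlabel("overall value")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_scenario_comparison(table: pd.DataFrame, ax=None):
    """Forest-style plot of posterior means with 95% CI bars.

    ``table`` is the output of :func:`probmcda.scenarios.compare_scenarios`.
    """
    if ax is None:
        _, ax = plt.subplots()
    scenarios = list(dict.fromkeys(table["scenario"]))
    alternatives = list(dict.fromkeys(table["alternative"]))
    width = 0.8 / max(len(alternatives), 1)
    for j, alt in enumerate(alternatives):
        sub = table[table["alternative"] == alt].set_index("scenario").loc[scenarios]
        x = np.arange(len(scenarios)) + (j - (len(alternatives) - 1) / 2) * width
        yerr = np.vstack([sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]])
        ax.errorbar(x, sub["mean"], yerr=yerr, fmt="o", capsize=3, label=alt)
    ax.set_xticks(np.arange(len(scenarios)))
    ax.set_xticklabels(scenarios, rotation=30, ha="right")
    ax.set_ylabel("overall value (95% CI)")
    ax.legend()
    return ax
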