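"""Plain plots for sweep curves and importance rankings."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_sweep(
    sweeps: Mapping[str, pd.DataFrame], ax: Optional[plt.Axes] = None
) -> plt.Figure:
    """Max-F1-per-lag curves, one line per scenario."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, table in sweeps.items():
        ax.plot(table["lag"], table["max_f1"], marker="o", label=name)
    ax.set_xlabel("lag (days of anticipation)")
    ax.set_ylabel("max F1 over leads")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax.figure


def plot_importances(
    table: pd.DataFrame, top: int = 15, ax: Optional[plt.Axes] = None
) -> plt.Figure:
    """Horizontal bar chart of the top mean-|SHAP| features."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * min(top, len(table)) + 1.5))
    sub = table.nsmallest(top, "rank").sort_values("mean_abs_shap")
    ax.barh(sub["feature"], sub["mean_abs_shap"])
    ax.set_xlabel("mean |SHAP| (margin units)")
    return ax.figure
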