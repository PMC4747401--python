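"""Simple diagnostic plots for trajectories and the FC/AD expression bias."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ranking import ExpressionBiasReport


def plot_trajectories(trajectory: pd.DataFrame, stat: str = "log2_fc", ax=None):
    """Line plot of per-gene FC or AD trajectories over treatment time.

    ``trajectory`` is the table from :func:`crgpipe.pipeline.trajectory_table`
    (columns gene_id, time_h, log2_fc, ad); ``stat`` selects the column.
    """
    import matplotlib.pyplot as plt

    if stat not in ("log2_fc", "ad"):
        raise ValueError("stat must be 'log2_fc' or 'ad'")
    if ax is None:
        _, ax = plt.subplots()
    for _, group in trajectory.groupby("gene_id"):
        ax.plot(group["time_h"], group[stat], color="steelblue", alpha=0.3, lw=0.8)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("treatment time (h)")
    ax.set_ylabel(stat)
    return ax


def plot_expression_bias(report: ExpressionBiasReport, ax=None):
    """Bar chart of mean expression of method-exclusive genes per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = report.to_frame()
    mean_cols = [c for c in frame.columns if c.startswith("mean_")]
    x = np.arange(len(mean_cols))
    width = 0.35
    for i, (_, row) in enumerate(frame.iterrows()):
        ax.bar(
            x + (i - 0.5) * width,
            [row[c] for c in mean_cols],
            width,
            label=f"{row['set']} exclusive (n={row['n_exclusive']})",
        )
    ax.set_xticks(x)
    ax.set_xticklabels([c.removeprefix("mean_") for c in mean_cols])
    ax.set_ylabel("mean expression (linear)")
    ax.legend()
    return ax
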