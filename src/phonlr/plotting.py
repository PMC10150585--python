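"""Basic diagnostic plots for replication summaries (not publication graphics)."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .resampling import ReplicationSummary

__all__ = ["plot_replication_curves", "plot_metric_boxes"]


def plot_replication_curves(
    results: Mapping[str, ReplicationSummary], metric: str = "cllr", ax=None
):
    """Metric value per replication, one line per system."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for system, summary in results.items():
        df = summary.per_replication
        ax.plot(df["replication"], df[metric], label=system, lw=1)
    ax.set_xlabel("replication (independent downsampling)")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7, ncol=2)
    return ax.figure


def plot_metric_boxes(
    results: Mapping[str, ReplicationSummary], metric: str = "cllr", ax=None
):
    """Box plot of the metric's replication distribution per system."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    names = list(results)
    data = [results[n].per_replication[metric].to_numpy() for n in names]
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=45)
    return ax.figure
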