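"""Comparison plots of prediction performance over the observation window."""

from __future__ import annotations

import pandas as pd

from .labeling import TIMESTEP_KEYS

__all__ = ["plot_comparison"]


def plot_comparison(comparison: pd.DataFrame, split: str = "validation", ax=None):
    """Accuracy / sensitivity / specificity per method over the seven
    prediction time steps (one panel per metric)."""
    import matplotlib.pyplot as plt

    data = comparison[comparison["split"] == split]
    if ax is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    else:
        axes = ax
    order = [k for k in TIMESTEP_KEYS if k in set(data["timestep"])]
    for metric, a in zip(("accuracy", "sensitivity", "specificity"), axes):
        for method, grp in data.groupby("method"):
            grp = grp.set_index("timestep").reindex(order)
            a.plot(order, grp[metric], marker="o", label=method)
        a.set_title(metric)
        a.set_xlabel("prediction time step")
        a.set_ylim(0, 1.05)
    axes[0].set_ylabel(f"{split} value")
    axes[-1].legend(fontsize=8)
    return axes
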