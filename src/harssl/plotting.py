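"""Plotting helpers for metric histories (accuracy and complexity curves)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_accuracy(history: pd.DataFrame, ax=None):
    """Overall accuracy and classification rate versus episodes seen."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = history["n_total"]
    ax.plot(x, history["overall_accuracy_pct"], marker="o", label="Acc (%)")
    ax.plot(
        x,
        history["classification_rate_pct"],
        marker="s",
        label=r"$\lambda$ (%)",
    )
    for col in history.columns:
        if col.startswith("tp_pct_"):
            ax.plot(
                x,
                history[col],
                alpha=0.5,
                lw=1,
                label=f"TP {col.removeprefix('tp_pct_')}",
            )
    ax.set_xlabel("episodes seen")
    ax.set_ylabel("percent")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    ax.set_title("Accuracy vs incoming episodes")
    return ax


def plot_complexity(history: pd.DataFrame, ax=None):
    """Cumulative compute time and pool+model memory versus episodes seen."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = history["n_total"]
    ax.plot(
        x,
        history["cumulative_compute_seconds"],
        marker="o",
        color="tab:blue",
        label="compute time (s)",
    )
    ax.set_xlabel("episodes seen")
    ax.set_ylabel("cumulative compute time (s)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(
        x,
        history["pool_memory_bytes"],
        marker="s",
        color="tab:red",
        label="memory (B)",
    )
    ax2.set_ylabel("pool+model memory (bytes)", color="tab:red")
    ax.set_title("Complexity vs incoming episodes")
    return ax
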