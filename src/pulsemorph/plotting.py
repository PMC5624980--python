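"""Plotting helpers for run summaries (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .types import BIOLOGICAL_CLASSES  # noqa: E402

_CLASS_NAMES = [str(c) for c in BIOLOGICAL_CLASSES]


def plot_size_distribution(edges, freqs, ax=None, label=None):
    """Step histogram of a relative size distribution (lengths in μm)."""
    ax = ax or plt.gca()
    if len(edges) > 1:
        ax.stairs(freqs, edges, label=label)
    ax.set_xlabel("sample length (μm)")
    ax.set_ylabel("relative frequency")
    return ax


def plot_class_fractions(tc: pd.DataFrame, value="sws_fraction_pct", ax=None):
    """Stacked-area time course of per-class fractions or concentrations."""
    ax = ax or plt.gca()
    wide = tc.pivot_table(index="timepoint", columns="class", values=value, aggfunc="mean")
    wide = wide.reindex(columns=[c for c in _CLASS_NAMES if c in wide.columns])
    ax.stackplot(wide.index, [wide[c].to_numpy() for c in wide.columns], labels=list(wide.columns))
    ax.set_xlabel("process time (h)")
    ax.set_ylabel(value)
    ax.legend(loc="upper left", fontsize="small")
    return ax


def save_summary_figure(tc: pd.DataFrame, path) -> None:
    """Two-panel figure: concentration and SWS-fraction time courses."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    plot_class_fractions(tc, "concentration_per_ml", ax=axes[0])
    plot_class_fractions(tc, "sws_fraction_pct", ax=axes[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
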