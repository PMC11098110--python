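"""Basic diagnostic plots: landscape masks, abundance series, correlograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import AbundanceSeries, SynchronyResult
from .landscape import Landscape

__all__ = ["plot_landscape", "plot_abundance", "plot_correlogram"]


def plot_landscape(landscape: Landscape, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(landscape.mask, cmap="Greys", interpolation="nearest")
    ax.set_title(f"cover = {landscape.cover:.3f}")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_abundance(series: AbundanceSeries, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(series.sim.shape[1])
    for k in range(series.n_reps):
        ax.plot(t, series.sim[k], color="C0", alpha=0.5, lw=0.8)
    ax.plot(t, series.mean_field.mean(axis=0), color="C3", lw=1.5, label="mean field")
    ax.set_xlabel("generation")
    ax.set_ylabel("population size")
    ax.legend()
    return ax


def plot_correlogram(result: SynchronyResult, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    s = result.summary
    width = 0.35
    x = np.arange(len(s))
    ax.bar(x - width / 2, s["mean_occupancy_corr"], width, label="occupancy")
    ax.bar(x + width / 2, s["mean_abundance_corr"], width, label="abundance")
    ax.set_xticks(x, [f"d≈{b:g}" for b in s["bin"]])
    ax.set_ylabel("mean pairwise correlation")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    return ax
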