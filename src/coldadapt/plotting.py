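"""Optional matplotlib views of the pipeline's main outputs."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def plot_growth_curves(curves: Sequence, ax=None):
    """A600 versus time, one line per (temperature, replicate)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    temps = sorted({c.temperature for c in curves})
    cmap = plt.get_cmap("coolwarm")
    for c in curves:
        frac = (
            (c.temperature - temps[0]) / (temps[-1] - temps[0])
            if len(temps) > 1
            else 0.5
        )
        ax.plot(c.times, c.a600, color=cmap(frac), alpha=0.7, lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel("A600")
    ax.set_title(curves[0].strain if curves else "")
    return ax


def plot_significance_heatmap(matrix, ax=None):
    """Pairwise counts of significantly different (pathway x metric) cells."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(matrix.counts, cmap="viridis")
    n = len(matrix.entities)
    ax.set_xticks(range(n), matrix.entities, rotation=45, ha="right")
    ax.set_yticks(range(n), matrix.entities)
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(matrix.counts[i, j]), ha="center", va="center",
                    color="white")
    plt.colorbar(im, ax=ax, label=f"cells with Tukey p < {matrix.alpha}")
    return ax


def plot_delta_regression(results, pathway: str, metric: str, param: str,
                          points: Mapping | None = None, ax=None):
    """One difference-vs-difference regression line (and its points if given)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    res = next(
        r for r in results
        if r.pathway == pathway and r.flex_metric == metric
        and r.growth_param == param
    )
    if points:
        xs, ys = zip(*points.items()) if isinstance(points, dict) else points
        ax.scatter(xs, ys, color="k")
        grid = np.linspace(min(xs), max(xs), 20)
    else:
        grid = np.linspace(-1, 1, 20)
    ax.plot(grid, res.intercept + res.slope * grid, "r-",
            label=f"R$^2$={res.r2:.2f}")
    ax.set_xlabel(f"delta {param}")
    ax.set_ylabel(f"delta {metric} ({pathway})")
    ax.legend()
    return ax
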