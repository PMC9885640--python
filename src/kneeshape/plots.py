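"""Basic method-comparison plots: Bland-Altman and regression scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import PairedMeasures, bland_altman

__all__ = ["bland_altman_plot", "regression_plot"]


def bland_altman_plot(p: PairedMeasures, ax=None):
    """Mean-vs-difference plot with bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    s = bland_altman(p)
    mean = (p.x_mr + p.x_ct) / 2.0
    ax.scatter(mean, p.differences, s=12, alpha=0.6)
    for y, style in ((s.bias, "-"), (s.loa_lower, "--"), (s.loa_upper, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    unit = f" ({p.units})" if p.units else ""
    ax.set_xlabel(f"mean of MR and CT{unit}")
    ax.set_ylabel(f"MR - CT{unit}")
    ax.set_title(p.measure)
    return ax


def regression_plot(p: PairedMeasures, ax=None):
    """CT-vs-MR scatter with the least-squares line and the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(p.x_ct, p.x_mr, s=12, alpha=0.6)
    slope, intercept = np.polyfit(p.x_ct, p.x_mr, 1)
    xs = np.linspace(p.x_ct.min(), p.x_ct.max(), 2)
    ax.plot(xs, slope * xs + intercept, "k-", linewidth=0.8, label="fit")
    ax.plot(xs, xs, "k:", linewidth=0.8, label="identity")
    unit = f" ({p.units})" if p.units else ""
    ax.set_xlabel(f"CT{unit}")
    ax.set_ylabel(f"MR{unit}")
    ax.set_title(p.measure)
    ax.legend(frameon=False, fontsize=8)
    return ax
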