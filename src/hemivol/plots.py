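"""Cosmetic plots: side-vs-reference scatter with fit, Bland-Altman."""

from __future__ import annotations

import numpy as np


def scatter_fit_plot(reference, side, fit, path=None, ax=None):
    """Half-body volume against reference volume with the fitted line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    reference = np.asarray(reference, float)
    ax.plot(reference, side, "o", ms=4, alpha=0.7)
    xs = np.linspace(reference.min(), reference.max(), 2)
    ax.plot(xs, fit.slope * xs + fit.intercept, "-", color="k",
            label=f"f={fit.slope:.4f}, b={fit.intercept:.1f} cm$^3$, "
                  f"$R^2$={fit.r_squared:.3f}")
    ax.set_xlabel(f"{fit.compartment.upper()} reference volume [cm$^3$]")
    ax.set_ylabel(f"{fit.compartment.upper()} {fit.side} half [cm$^3$]")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def bland_altman_plot(measured, estimated, stats, path=None, ax=None):
    """Differences against means with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    m = np.asarray(measured, float)
    e = np.asarray(estimated, float)
    ax.plot((m + e) / 2.0, m - e, "o", ms=4, alpha=0.7)
    for y, style in ((stats.mean_diff, "-"), (stats.loa_low, "--"),
                     (stats.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of measured and estimated [cm$^3$]")
    ax.set_ylabel("measured - estimated [cm$^3$]")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
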