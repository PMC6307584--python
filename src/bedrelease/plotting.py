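"""Plots for the bootstrap distribution and the acceptability curve."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .inference import BootstrapResult, histogram_bed_days


def plot_bed_days_histogram(result: BootstrapResult, bin_width: float = 5.0, ax=None):
    """Histogram of bed days released per patient over bootstrap replicates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hist = histogram_bed_days(result, bin_width)
    ax.bar(
        hist["bin_left"],
        hist["count"],
        width=hist["bin_right"] - hist["bin_left"],
        align="edge",
        edgecolor="white",
    )
    ax.set_xlabel("Bed days released per patient managed")
    ax.set_ylabel("Bootstrap replicates")
    return ax


def plot_ceac(curve, wtp: Optional[float] = None, ax=None):
    """Cost-effectiveness acceptability curve; optionally mark one threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["wtp"], curve["probability"], drawstyle="steps-post")
    if wtp is not None:
        ax.axvline(wtp, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("Willingness to pay per bed day released ($)")
    ax.set_ylabel("Probability cost per bed day is below WTP")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_phi_curve(results, ax=None):
    """Per-time decomposition phi(s) with point sizes by weight."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w = np.asarray(results.weights)
    size = 10 + 200 * w / w.max() if len(w) else 10
    ax.scatter(results.s_times, results.phi_curve, s=size, alpha=0.6)
    ax.axhline(0, color="grey", linewidth=1)
    ax.axhline(results.delta, color="C1", linestyle="--", linewidth=1,
               label=f"weighted delta = {results.delta:.1f} d")
    ax.set_xlabel("Time of intervention s (days from admission)")
    ax.set_ylabel("phi(s) = e1(s) - e0(s) (days)")
    ax.legend()
    return ax
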