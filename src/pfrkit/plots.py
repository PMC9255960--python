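"""Optional figures: projected-velocity time courses and gain-vs-NDR scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .pfr import ProjectedVelocityTrace
from .stats_report import NdrPfrFit

__all__ = ["plot_projected_velocity", "plot_gain_vs_ndr"]


def plot_projected_velocity(
    traces: list[ProjectedVelocityTrace], ax=None, colors=("tab:red", "tab:blue")
):
    """Mean projected eye velocity with a +-2 SEM band per condition.

    Positive values are eye motion along the pre-saccadic target motion
    direction; the open-loop epoch is shaded.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for tr, color in zip(traces, colors):
        ax.plot(tr.t_ms, tr.mean, color=color, label=f"stimulus {tr.condition}")
        ax.fill_between(
            tr.t_ms, tr.mean - tr.dispersion, tr.mean + tr.dispersion,
            color=color, alpha=0.25, linewidth=0,
        )
    if traces and traces[0].alignment == "offset":
        ax.axvspan(20, 100, color="0.9", zorder=0)
    ax.axhline(0.0, color="0.3", linewidth=0.6)
    ax.set_xlabel("time from saccade %s (ms)" % (traces[0].alignment if traces else "offset"))
    ax.set_ylabel("projected eye velocity (deg/s)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_gain_vs_ndr(
    pairs_intact: np.ndarray,
    pairs_blind: np.ndarray,
    fit: NdrPfrFit | None = None,
    ax=None,
):
    """Per-location open-loop gain against NDR threshold, with the intact-field
    exponential fit and its bootstrap confidence band when supplied."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    pairs_intact = np.asarray(pairs_intact, float)
    pairs_blind = np.asarray(pairs_blind, float)
    ax.scatter(pairs_intact[:, 0], pairs_intact[:, 1], facecolor="none",
               edgecolor="k", label="intact locations")
    if pairs_blind.size:
        ax.scatter(pairs_blind[:, 0], pairs_blind[:, 1], color="0.5",
                   label="blind locations")
    if fit is not None and fit.converged:
        a, b, c = fit.coeffs
        ax.plot(fit.grid, a * np.exp(-b * fit.grid) + c, "k-")
        ax.fill_between(fit.grid, fit.band_low, fit.band_high, color="0.8", alpha=0.6)
    ax.axhline(0.0, color="0.3", linewidth=0.6)
    ax.set_xlabel("NDR threshold")
    ax.set_ylabel("open-loop PFR gain")
    ax.legend(frameon=False, fontsize=8)
    return ax
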