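"""Matplotlib views: prevalence trends, tornado diagram, CE plane, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["prevalence_trends", "tornado", "ce_plane", "ceac_curve"]


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    return ax


def prevalence_trends(trajectories: dict, ax=None):
    """Anaemia prevalence per cycle for each arm."""
    ax = _axes(ax)
    for arm, traj in sorted(trajectories.items()):
        prev = traj.prevalence_series()
        ax.plot(np.arange(1, len(prev) + 1), 100 * prev, marker="o", ms=3, label=arm)
    ax.set_xlabel("cycle (6 months each)")
    ax.set_ylabel("anaemia prevalence (%)")
    ax.set_ylim(bottom=0)
    ax.legend()
    ax.set_title("Projected anaemia prevalence by arm")
    return ax


def tornado(oneway, ax=None):
    """Horizontal-bar tornado diagram of one-way ICER swings."""
    ax = _axes(ax)
    t = oneway.table.iloc[::-1]  # largest swing on top
    y = np.arange(len(t))
    lo = np.minimum(t["low_icer"], t["high_icer"])
    hi = np.maximum(t["low_icer"], t["high_icer"])
    ax.barh(y, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(oneway.base_icer, color="k", lw=1, ls="--", label="base ICER")
    ax.set_yticks(y, t["parameter"])
    ax.set_xlabel("ICER (USD per disability day)")
    ax.set_title("One-way sensitivity (tornado)")
    ax.legend()
    return ax


def ce_plane(psa, wtp: float | None = None, ax=None):
    """Incremental cost vs effect scatter of PSA draws."""
    ax = _axes(ax)
    s = psa.samples
    ax.scatter(s["delta_effect"], s["delta_cost"], s=6, alpha=0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        x = np.linspace(*ax.get_xlim(), 10)
        ax.plot(x, wtp * x, "r--", lw=1, label=f"WTP = {wtp} USD/day")
        ax.legend()
    ax.set_xlabel("disability days averted")
    ax.set_ylabel("incremental cost (USD)")
    ax.set_title("Cost-effectiveness plane")
    return ax


def ceac_curve(curve, ax=None):
    """Cost-effectiveness acceptability curve."""
    ax = _axes(ax)
    ax.plot(curve.wtp_grid, curve.p_cost_effective, lw=2)
    ax.set_xlabel("willingness to pay (USD per disability day averted)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax
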