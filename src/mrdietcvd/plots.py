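"""Plain plotting hooks: scatter, forest, funnel, leave-one-out.

Unstyled matplotlib figures for eyeballing an analysis; each helper returns
the figure so callers can save or restyle it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .instruments import HarmonizedSet
from .mr_estimators import MrEstimate, wald_ratios


def scatter_plot(h: HarmonizedSet, estimates: list[MrEstimate] | None = None):
    """Exposure vs outcome effects with fitted method lines."""
    fig, ax = plt.subplots()
    p = h.pairs
    ax.errorbar(p["beta_x"], p["beta_y"], xerr=p["se_x"], yerr=p["se_y"],
                fmt="o", ms=3, lw=0.5)
    if estimates:
        xs = np.linspace(0, p["beta_x"].abs().max(), 10)
        for est in estimates:
            icpt = est.extra.get("intercept", 0.0)
            ax.plot(xs, icpt + est.beta * xs, label=est.method)
        ax.legend(fontsize=7)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    return fig


def forest_plot(estimates: list[MrEstimate]):
    """Per-method odds ratios with 95% CIs."""
    fig, ax = plt.subplots()
    ys = np.arange(len(estimates))
    for y, est in zip(ys, estimates):
        ax.plot([est.or_lci95, est.or_uci95], [y, y], "-", color="C0")
        ax.plot(est.or_, y, "s", color="C0")
    ax.axvline(1.0, ls=":", color="grey")
    ax.set_yticks(ys, [e.method for e in estimates])
    ax.set_xlabel("OR (95% CI)")
    return fig


def funnel_plot(h: HarmonizedSet):
    """Per-SNP ratio vs precision; asymmetry suggests directional pleiotropy."""
    w = wald_ratios(h)
    fig, ax = plt.subplots()
    ax.plot(w["ratio"], 1.0 / w["ratio_se"], "o", ms=3)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    return fig


def loo_plot(loo, full_beta: float):
    """Leave-one-out estimates around the full-set IVW estimate."""
    fig, ax = plt.subplots()
    ys = np.arange(len(loo))
    lo = loo["beta"] - 1.959964 * loo["se"]
    hi = loo["beta"] + 1.959964 * loo["se"]
    for y, (l, h_) in enumerate(zip(lo, hi)):
        ax.plot([l, h_], [y, y], "-", color="C0")
    ax.plot(loo["beta"], ys, "s", ms=3, color="C0")
    ax.axvline(full_beta, ls=":", color="grey")
    ax.set_yticks(ys, loo["rsid"])
    ax.set_xlabel("IVW estimate omitting SNP")
    return fig
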