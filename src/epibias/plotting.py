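"""Convenience plots for bias curves and positional conservation.

Numbers are the contract of this package; these box-style plots are a
visual aid for the analysis drivers (boxes 25th-75th percentile, whiskers
1.0 interquartile ranges beyond the box).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bias import BiasCurve
from .conservation import PositionalConservation


def _boxes(ax, centers, p25, p75, w_lo, w_hi, point, width=0.12):
    for c, lo, hi, wl, wh, pt in zip(centers, p25, p75, w_lo, w_hi, point):
        ax.add_patch(
            plt.Rectangle((c - width / 2, lo), width, hi - lo,
                          fill=False, edgecolor="black")
        )
        ax.plot([c, c], [wl, lo], "k-", lw=0.8)
        ax.plot([c, c], [hi, wh], "k-", lw=0.8)
        ax.plot(c, pt, "k_", ms=14)


def plot_bias_curve(curve: BiasCurve, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    _boxes(ax, curve.bin_centers, curve.boot_p25, curve.boot_p75,
           curve.whisker_lo, curve.whisker_hi, curve.ratio)
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("normalized position")
    ax.set_ylabel("p(x|positive) / p(x|negative)")
    ax.set_xlim(0, 1)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_positional_conservation(pc: PositionalConservation, path,
                                 title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    _boxes(ax, pc.bin_centers, pc.boot_p25, pc.boot_p75,
           pc.whisker_lo, pc.whisker_hi, pc.mean_score)
    ax.axhline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("normalized position")
    ax.set_ylabel("mean conservation (z)")
    ax.set_xlim(0, 1)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
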