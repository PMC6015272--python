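"""Standard figures: CE plane, CEAC, and the ICER-vs-users curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import BootstrapCloud
from .sensitivity import ScalingResult


def plot_ce_plane(cloud: BootstrapCloud, path, wtp_lines=(20_000, 30_000)):
    """Scatter of (dEffect, dCost) replicates with WTP threshold lines."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(cloud.delta_effect, cloud.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = cloud.delta_effect
    span = (xs.min(), xs.max())
    for wtp in wtp_lines:
        ax.plot(span, [wtp * x for x in span], "--", lw=1,
                label=f"WTP £{wtp:,}/QALY")
    ax.set_xlabel(f"Incremental effect ({cloud.effect_label})")
    ax.set_ylabel("Incremental cost (£)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"])
    for wtp in (20_000, 30_000):
        ax.axvline(wtp, color="grey", ls=":", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (£ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_icer_vs_users(result: ScalingResult, path, wtp_lines=(20_000, 30_000)):
    fig, ax = plt.subplots(figsize=(6, 4))
    t = result.table
    ax.plot(t["n_users"], t["icer"])
    ax.axhline(0, color="k", lw=0.8)
    for wtp in wtp_lines:
        ax.axhline(wtp, color="grey", ls=":", lw=0.8)
    if result.breakeven_n is not None:
        ax.axvline(result.breakeven_n, color="red", ls="--", lw=0.8,
                   label=f"break-even at {result.breakeven_n} users")
        ax.legend(fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("Number of users")
    ax.set_ylabel("ICER (£ per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
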