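"""Score-profile plots along reaction coordinates."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .channels import ChannelLibrary
from .scores import ScoreTable, display_score

__all__ = ["plot_score_profiles", "plot_channel_comparison"]


def plot_score_profiles(
    table: ScoreTable,
    enzymes: Sequence[str],
    channel: str,
    lib: ChannelLibrary,
    convention: str = "minus10",
    out: str | Path | None = None,
):
    """Per-enzyme docking-score profiles along one channel.

    Failed dockings are drawn at the chosen display sentinel (+100 or −10
    kcal/mol); the sentinel never participates in any ranking.
    """
    chan = lib.channel(channel)
    xs = [i.id for i in chan.intermediates]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for enzyme in enzymes:
        ys = []
        for inter in chan.intermediates:
            status = table.get(enzyme, inter.id)
            ys.append(None if status is None else display_score(status, convention))
        ax.plot(xs, ys, marker="o", label=enzyme)
    ax.set_xlabel("reaction coordinate (carbocationic intermediate)")
    ax.set_ylabel("docking score (kcal/mol)")
    ax.set_title(f"Channel {channel} score profiles")
    if len(enzymes) <= 12:
        ax.legend(fontsize="x-small")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


def plot_channel_comparison(
    table: ScoreTable,
    enzyme: str,
    lib: ChannelLibrary,
    convention: str = "plus100",
    out: str | Path | None = None,
):
    """One enzyme's profiles along all enabled channels (crystal-structure
    style comparison)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for chan in lib.enabled_channels():
        xs, ys = [], []
        for inter in chan.intermediates:
            status = table.get(enzyme, inter.id)
            if status is None:
                continue
            xs.append(inter.index)
            ys.append(display_score(status, convention))
        if xs:
            ax.plot(xs, ys, marker="o", label=f"Channel {chan.id}")
    ax.set_xlabel("intermediate index along channel")
    ax.set_ylabel("docking score (kcal/mol)")
    ax.set_title(f"{enzyme}: channel comparison")
    ax.legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
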