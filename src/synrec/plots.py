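"""Headless-safe plots for recombination maps and window landscapes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .recombination import RecombinationMap  # noqa: E402


def plot_cumulative_map(rec_map: RecombinationMap, path: str | Path) -> None:
    """Cumulative crossover-frequency curve; position 0 is the centromere."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = (rec_map.bin_edges[:-1] + rec_map.bin_edges[1:]) / 2
    ax.step(centers, rec_map.cumulative, where="post",
            label=f"CO class: {rec_map.co_class} (n={rec_map.n_cells})")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("position on SC (% from centromere)")
    ax.set_ylabel("cumulative CO frequency")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_window_landscape(windows, value: str, path: str | Path) -> None:
    """Per-window statistic along each chromosome, coloured by region label."""
    fig, ax = plt.subplots(figsize=(6, 3))
    for label, sub in windows.groupby("label", dropna=False):
        ax.scatter(sub["start"] / 1e6, sub[value], s=4,
                   label=str(label), alpha=0.6)
    ax.set_xlabel("position (Mbp)")
    ax.set_ylabel(value)
    ax.legend(frameon=False, fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
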