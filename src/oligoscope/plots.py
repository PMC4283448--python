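"""Heatmaps and RDA triplots (matplotlib, headless backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from oligoscope.oligotyping import OligotypeTable
from oligoscope.ordination import RDAResults, hellinger
from oligoscope.screening import order_rows


def heatmap(table: OligotypeTable, path: str | Path, title: str = "") -> None:
    """Hellinger-transformed abundance heatmap, rows in UPGMA leaf order."""
    x = hellinger(table.counts.to_numpy(float))
    order = order_rows(table)
    fig, ax = plt.subplots(
        figsize=(0.6 * x.shape[1] + 2, 0.35 * x.shape[0] + 1.5)
    )
    ax.imshow(x[order], cmap="Greys", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(x.shape[1]), table.counts.columns, rotation=90, fontsize=7)
    labels = table.meta["label"].to_numpy()[order]
    ax.set_yticks(range(x.shape[0]), labels, fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def triplot(res: RDAResults, path: str | Path, title: str = "") -> None:
    """Type-2 scaling triplot: sites, oligotypes and constraint arrows."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if res.site_scores.shape[1] >= 2:
        ax1, ax2 = res.site_scores.columns[:2]
    elif res.site_scores.shape[1] == 1:
        ax1 = res.site_scores.columns[0]
        ax2 = None
    else:
        plt.close(fig)
        return
    xs = res.site_scores[ax1]
    ys = res.site_scores[ax2] if ax2 else np.zeros(len(xs))
    for name, x, y in zip(res.site_scores.index, xs, ys):
        ax.text(x, y, str(name), fontsize=7, color="black")
    ox = res.oligotype_scores[ax1]
    oy = res.oligotype_scores[ax2] if ax2 else np.zeros(len(ox))
    scale = max(np.abs(xs).max(), 1e-9) / max(np.abs(ox).max(), 1e-9)
    for name, x, y in zip(res.oligotype_scores.index, ox * scale, oy * scale):
        ax.text(x, y, str(name).split(":")[-1], fontsize=8, color="red",
                fontweight="bold")
    bx = res.biplot_scores[ax1]
    by = res.biplot_scores[ax2] if ax2 else np.zeros(len(bx))
    arrow_scale = max(np.abs(xs).max(), 1e-9)
    for name, x, y in zip(res.biplot_scores.index, bx, by):
        ax.annotate(
            "", xy=(x * arrow_scale, y * arrow_scale), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="gray"),
        )
        ax.text(x * arrow_scale * 1.05, y * arrow_scale * 1.05, name,
                fontsize=8, color="gray")
    lim = 1.2 * max(np.abs(xs).max(), np.abs(ys).max(), 1e-9)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, lw=0.3, color="k")
    ax.axvline(0, lw=0.3, color="k")
    ax.set_xlabel(ax1)
    ax.set_ylabel(ax2 or "")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
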