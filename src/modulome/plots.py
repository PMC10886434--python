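"""Figure export: QC histograms, activity heatmaps, trade-off scatters.

All figures are written as vector graphics (SVG by default); matplotlib's
Agg backend is forced so plotting works headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import QcReport


def plot_qc_histogram(report: QcReport, path) -> None:
    """Overlaid replicate vs non-replicate PCC histograms."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.linspace(-1, 1, 41)
    ax.hist(report.nonreplicate_pccs, bins=bins, alpha=0.6, label="non-replicates", color="goldenrod")
    ax.hist(report.replicate_pccs, bins=bins, alpha=0.6, label="replicates", color="steelblue")
    ax.set_xlabel("Pearson correlation")
    ax.set_ylabel("sample pairs")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_activity_heatmap(table: pd.DataFrame, path) -> None:
    """Conditions x iModulons mean-activity heatmap."""
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * table.shape[1]), max(3, 0.3 * table.shape[0])))
    vmax = np.nanmax(np.abs(table.to_numpy())) or 1.0
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean activity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_tradeoff_scatter(A: pd.DataFrame, im_a: str, im_b: str, r: float, p: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(A.loc[im_a], A.loc[im_b], s=18, alpha=0.8)
    ax.set_xlabel(f"{im_a} activity")
    ax.set_ylabel(f"{im_b} activity")
    ax.set_title(f"r = {r:.2f}, p = {p:.2g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
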