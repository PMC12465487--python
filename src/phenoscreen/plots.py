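"""Publication-style figures: clustered fingerprint heatmap with the
window-tag barcode, phenospace scatter with error bars, pulse-aligned
response curves, and sub-sampling p-value histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
import seaborn as sns  # noqa: E402

from .config import StimulusProtocol, WINDOW_TAGS  # noqa: E402
from .phenospace import Fingerprint, PhenospaceProjection  # noqa: E402

WINDOW_COLOURS = {"prestim": "#f2a0c0", "bluelight": "#7fb2e5", "poststim": "#8fd18f"}
WINDOW_MARKERS = {"prestim": "o", "bluelight": "x", "poststim": "s"}


def fingerprint_heatmap(fp: Fingerprint, path: str | Path | None = None):
    """Clustered heatmap of strain z-score profiles with the stim-type barcode."""
    col_colors = None
    if fp.window_tags is not None:
        col_colors = pd.Series(
            [WINDOW_COLOURS.get(t, "#bbbbbb") for t in fp.window_tags],
            index=fp.matrix.columns, name="stim type",
        )
    grid = sns.clustermap(
        fp.matrix, row_linkage=fp.row_linkage, col_linkage=fp.col_linkage,
        col_colors=col_colors, cmap="vlag", center=0,
        xticklabels=False, figsize=(10, max(3, 0.4 * len(fp.matrix))),
    )
    grid.ax_heatmap.set_xlabel("feature (z-score)")
    if path is not None:
        grid.savefig(path, dpi=150)
        plt.close(grid.fig)
    return grid


def phenospace_plot(proj: PhenospaceProjection, path: str | Path | None = None,
                    components: tuple[str, str] = ("PC1", "PC2")):
    """Strain trajectories through phenospace across the three windows."""
    cx, cy = components
    fig, ax = plt.subplots(figsize=(7, 6))
    strains = proj.centroids.index.get_level_values("strain").unique()
    palette = sns.color_palette("husl", len(strains))
    for colour, strain in zip(palette, strains):
        pts = []
        for tag in WINDOW_TAGS:
            if (strain, tag) not in proj.centroids.index:
                continue
            c = proj.centroids.loc[(strain, tag)]
            d = proj.dispersions.loc[(strain, tag)]
            ax.errorbar(c[cx], c[cy], xerr=d[cx], yerr=d[cy], color=colour,
                        marker=WINDOW_MARKERS[tag], capsize=2, lw=0.8, alpha=0.9)
            pts.append((c[cx], c[cy]))
        if len(pts) > 1:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, color=colour, lw=0.6, alpha=0.5, label=str(strain))
    evr = proj.explained_variance_ratio
    ax.set_xlabel(f"{cx} ({evr[0] * 100:.1f}% var)")
    if len(evr) > 1:
        ax.set_ylabel(f"{cy} ({evr[1] * 100:.1f}% var)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def response_curve_plot(curve: pd.DataFrame, protocol: StimulusProtocol,
                        path: str | Path | None = None, label: str = "fraction moving"):
    """Pulse-aligned mean curve with its bootstrap CI band and pulse shading."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(curve["time"], curve["ci_lower"], curve["ci_upper"],
                    alpha=0.3, lw=0)
    ax.plot(curve["time"], curve["fraction"], lw=1.2)
    ax.axvspan(0, protocol.pulse_duration, color="#7fb2e5", alpha=0.3)
    ax.set_xlabel("time relative to pulse onset (s)")
    ax.set_ylabel(label)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pvalue_histogram(draws: pd.DataFrame, feature: str, alpha: float = 0.05,
                     path: str | Path | None = None):
    """Histogram of per-draw p-values for one feature, with the alpha line."""
    sub = draws.loc[draws["feature"] == feature, "p_raw"].dropna()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(sub, bins=np.linspace(0, 1, 21), color="#888888", edgecolor="white")
    ax.axvline(alpha, color="red", lw=1.2)
    ax.set_xlabel("p-value")
    ax.set_ylabel("draws")
    ax.set_title(feature, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
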