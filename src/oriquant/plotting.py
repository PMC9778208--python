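"""Optional matplotlib displays (chromosome profiles, scatters, boxplots,
heatmaps). All functions take an Axes or create one, and return the figure."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .origins import OriginSet
from .preprocess import StrainProfile

GROUP_COLORS = {
    "cen_proximal": "tab:red",
    "fkh_activated": "tab:blue",
    "fkh1_sensitive": "tab:purple",
    "confirmed": "0.5",
}


def plot_chromosome_profiles(
    profiles: Sequence[StrainProfile],
    chrom: str,
    origin_set: OriginSet | None = None,
    path: str | None = None,
):
    """Overlayed per-strain signal along one chromosome, with origin-group
    glyphs below the axis."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for p in profiles:
        v = p.track.values[chrom]
        x = (np.arange(len(v)) + 0.5) * p.track.bin_width / 1000.0
        ax.plot(x, v, lw=0.8, label=p.strain_label)
    if origin_set is not None:
        ymin = ax.get_ylim()[0]
        for group in ("confirmed", "fkh_activated", "cen_proximal"):
            mids = [o.midpoint / 1000.0 for o in origin_set.groups[group]
                    if o.chrom == chrom]
            ax.plot(mids, [ymin] * len(mids), "o", ms=3,
                    color=GROUP_COLORS[group], clip_on=False, label=group)
    ax.set_xlabel(f"{chrom} position (kb)")
    ax.set_ylabel("signal")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scatter(
    table: pd.DataFrame,
    x_strain: str,
    y_strain: str,
    groups: Mapping[str, Sequence[str]],
    fits: Mapping[str, dict] | None = None,
    path: str | None = None,
):
    fig, ax = plt.subplots(figsize=(4, 4))
    for group, names in groups.items():
        names = [n for n in names if n in table.index]
        if not names:
            continue
        sub = table.loc[names]
        ax.plot(sub[x_strain], sub[y_strain], "o", ms=3,
                color=GROUP_COLORS.get(group, None), alpha=0.6, label=group)
        if fits and group in fits:
            f = fits[group]
            xs = np.linspace(sub[x_strain].min(), sub[x_strain].max(), 10)
            ax.plot(xs, f["slope"] * xs + f["intercept"], "-",
                    color=GROUP_COLORS.get(group, "k"), lw=1)
    ax.set_xlabel(x_strain)
    ax.set_ylabel(y_strain)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_group_boxes(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    path: str | None = None,
):
    """Per-strain boxplots of window signal for each origin group."""
    strains = list(table.columns)
    fig, axes = plt.subplots(
        1, len(groups), figsize=(2.2 * len(groups), 3), sharey=True
    )
    if len(groups) == 1:
        axes = [axes]
    for ax, (group, names) in zip(axes, groups.items()):
        names = [n for n in names if n in table.index]
        data = [table.loc[names, s].to_numpy() for s in strains]
        ax.boxplot(data, tick_labels=strains)
        ax.set_title(f"{group} (n={len(names)})", fontsize=8)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmap(matrix: pd.DataFrame, path: str | None = None, title: str = ""):
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(
        matrix.to_numpy(), aspect="auto", interpolation="nearest",
        extent=[matrix.columns.min() / 1000, matrix.columns.max() / 1000,
                len(matrix), 0],
        cmap="viridis",
    )
    ax.set_xlabel("offset from feature midpoint (kb)")
    ax.set_ylabel("features")
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
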