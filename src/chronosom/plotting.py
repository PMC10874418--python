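"""Figure rendering: portraits, summary maps, DEG bars, trajectory fits.

All portrait-style images use one fixed symmetric diverging blue-green-red
scale per figure set (blue = under-, red = over-expression relative to the
gene's cohort mean) so that portraits are directly cross-comparable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from chronosom.perturbation_time import (
    GPHyperParams,
    PerturbationResult,
    TimeCoursePair,
    predict_curves,
)
from chronosom.spots import Spot

#: blue -> green -> red, the conventional under/invariant/over palette
PORTRAIT_CMAP = LinearSegmentedColormap.from_list(
    "portrait", ["#0000b0", "#00b050", "#b00000"]
)


def plot_portraits(
    portraits: list,
    path: str | Path,
    vmax: float | None = None,
    ncols: int = 4,
) -> None:
    """Grid of portraits on a shared symmetric color scale."""
    if vmax is None:
        vmax = max(float(np.abs(p.values).max()) for p in portraits) or 1.0
    n = len(portraits)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, p in zip(axes.ravel(), portraits):
        ax.imshow(p.values, cmap=PORTRAIT_CMAP, vmin=-vmax, vmax=vmax)
        ax.set_title(p.label, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_summary_map(
    summary_map: np.ndarray,
    spots: list[Spot] | None,
    path: str | Path,
    title: str = "variance summary map",
) -> None:
    """Summary map with spot outlines and labels overlaid."""
    k = summary_map.shape[0]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(summary_map, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    for spot in spots or []:
        mask = np.zeros((k, k))
        for mg in spot.metagenes:
            mask[divmod(mg, k)] = 1.0
        ax.contour(mask, levels=[0.5], colors="blue", linewidths=1.2)
        ci, cj = np.mean([divmod(mg, k) for mg in spot.metagenes], axis=0)
        ax.text(cj, ci, spot.label, color="white", ha="center", va="center", fontsize=10)
    ax.set_title(title)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deg_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Per-disease bars of up (red) and down (blue) DEG counts by age group."""
    diseases = counts["disease"].unique()
    fig, axes = plt.subplots(1, max(len(diseases), 1), figsize=(4 * max(len(diseases), 1), 3.5), squeeze=False)
    for ax, disease in zip(axes.ravel(), diseases):
        sub = counts[counts["disease"] == disease]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["up"], width=0.4, color="#c03030", label="up")
        ax.bar(x + 0.2, sub["down"], width=0.4, color="#3030c0", label="down")
        ax.set_xticks(x)
        ax.set_xticklabels(sub["age_group"], rotation=45, ha="right", fontsize=8)
        ax.set_title(disease)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_perturbation(
    pair: TimeCoursePair,
    result: PerturbationResult,
    path: str | Path,
    title: str = "",
) -> None:
    """Two-arm trajectory fit with 95% credible bands and the tau posterior."""
    fig, (ax_post, ax_fit) = plt.subplots(
        2, 1, figsize=(6, 5), sharex=True, height_ratios=[1, 3]
    )
    ax_post.fill_between(result.tau_grid, result.posterior, color="gray", alpha=0.7)
    ax_post.axvline(result.map_tau, color="black", linestyle="--", linewidth=1)
    ax_post.set_ylabel("posterior")

    grid = np.linspace(pair.ages.min(), pair.ages.max(), 120)
    curves = predict_curves(pair, result.params, result.map_tau, grid)
    for arm, color, band in (("ctrl", "tab:blue", "#ffe090"), ("dis", "tab:red", "#90c0ff")):
        mean = curves[f"mean_{arm}"]
        sd = np.sqrt(curves[f"var_{arm}"] + result.params.noise_var)
        ax_fit.fill_between(grid, mean - 1.96 * sd, mean + 1.96 * sd, color=band, alpha=0.5)
        ax_fit.plot(grid, mean, color=color)
    ax_fit.plot(pair.t_ctrl, pair.y_ctrl, "o", color="tab:blue", ms=4, label="control")
    ax_fit.plot(pair.t_dis, pair.y_dis, "o", color="tab:red", ms=4, label="disease")
    ax_fit.set_xlabel("age (years)")
    ax_fit.set_ylabel("spot expression (log2)")
    ax_fit.legend(fontsize=8)
    if title:
        ax_post.set_title(
            f"{title}  (MAP tau = {result.map_tau:.1f} y, LR = {result.likelihood_ratio:.2f})"
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
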