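"""Figure rendering: per-muscle histograms with thresholds, Bland-Altman and
correlation plots, and per-model mean +/- SD summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import IntensitySample
from .thresholding import VoxelClassification

__all__ = [
    "plot_histogram_with_thresholds",
    "plot_bland_altman",
    "plot_correlation",
    "plot_model_means",
]

# muscle red, undefined orange, fat yellow
_CLASS_COLORS = {0: "#c0392b", 1: "#e67e22", 2: "#f1c40f"}
_CLASS_NAMES = {0: "muscle", 1: "undefined", 2: "fat"}


def plot_histogram_with_thresholds(
    sample: IntensitySample,
    classification: VoxelClassification,
    imf_percent: float,
    path: str | Path,
    bins: int = 80,
) -> Path:
    """Intensity histogram shaded by tissue class with threshold lines."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    edges = np.histogram_bin_edges(sample.values, bins=bins)
    for cls in np.unique(classification.labels):
        ax.hist(
            sample.values[classification.labels == cls],
            bins=edges,
            color=_CLASS_COLORS[int(cls)],
            label=_CLASS_NAMES[int(cls)],
            alpha=0.9,
        )
    for t in classification.thresholds or ():
        ax.axvline(t, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("T2 intensity (a.u.)")
    ax.set_ylabel("voxel count")
    ax.set_title(
        f"{sample.muscle_label} {classification.model_id}: IMF {imf_percent:.1f}%"
    )
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(
    model_values: np.ndarray,
    reference_values: np.ndarray,
    title: str,
    path: str | Path,
) -> Path:
    """Bland-Altman plot: difference vs mean with bias and 95% LOA lines."""
    m = np.asarray(model_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    d = m - r
    bias = d.mean()
    sd = d.std(ddof=1)
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.scatter((m + r) / 2, d, s=14, alpha=0.7)
    ax.axhline(bias, color="k")
    for loa in (bias - 1.96 * sd, bias + 1.96 * sd):
        ax.axhline(loa, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("mean of model and Dixon IMF (%)")
    ax.set_ylabel("model − Dixon IMF (%)")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_correlation(
    model_values: np.ndarray,
    reference_values: np.ndarray,
    title: str,
    path: str | Path,
) -> Path:
    """Scatter of model vs reference IMF with identity and trend lines."""
    m = np.asarray(model_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    fig, ax = plt.subplots(figsize=(4.0, 3.6))
    ax.scatter(r, m, s=14, alpha=0.7)
    lims = [min(r.min(), m.min()), max(r.max(), m.max())]
    ax.plot(lims, lims, linestyle=":", color="grey", label="identity")
    slope, intercept = np.polyfit(r, m, 1)
    xs = np.linspace(lims[0], lims[1], 10)
    ax.plot(xs, slope * xs + intercept, color="k", label="trend")
    ax.set_xlabel("Dixon IMF (%)")
    ax.set_ylabel("model IMF (%)")
    ax.set_title(title, fontsize=10)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_model_means(imf_table: pd.DataFrame, reference_table: pd.DataFrame,
                     path: str | Path) -> Path:
    """Mean +/- SD of IMF per model (and the Dixon reference) per muscle."""
    fig, ax = plt.subplots(figsize=(6.4, 3.6))
    summary = (
        imf_table.groupby(["muscle_label", "model_id"])["imf_percent"]
        .agg(["mean", "std"])
        .reset_index()
    )
    if len(reference_table):
        ref = (
            reference_table.groupby("muscle_label")["imf_percent"]
            .agg(["mean", "std"])
            .reset_index()
        )
        ref["model_id"] = "DIXON"
        summary = pd.concat([summary, ref], ignore_index=True)
    muscles = sorted(summary["muscle_label"].unique())
    models = sorted(summary["model_id"].unique())
    width = 0.8 / len(models)
    for j, model in enumerate(models):
        sub = summary[summary["model_id"] == model].set_index("muscle_label")
        xs = np.arange(len(muscles)) + j * width
        means = [sub["mean"].get(m, np.nan) for m in muscles]
        sds = [sub["std"].get(m, np.nan) for m in muscles]
        ax.bar(xs, means, width=width, yerr=sds, capsize=2, label=model)
    ax.set_xticks(np.arange(len(muscles)) + 0.4 - width / 2)
    ax.set_xticklabels(muscles)
    ax.set_ylabel("IMF (%)")
    ax.legend(frameon=False, fontsize=8, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
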