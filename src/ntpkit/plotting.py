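"""Basic matrix heatmaps for predictions and gene-set summaries."""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written to files
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import NOT_ASSIGNED, TemplateSet, validate_expression
from .preprocess import row_center_scale

__all__ = ["plot_prediction_heatmap", "plot_gsa_heatmap"]


def plot_prediction_heatmap(
    emat: pd.DataFrame,
    preds: pd.DataFrame,
    templates: TemplateSet,
    path=None,
    clip: float = 2.0,
):
    """Row-scaled template-gene expression, samples ordered by prediction.

    Genes are grouped by template class (horizontal lines separate the
    blocks); samples are ordered by predicted class with not-assigned
    samples last.  Returns the matplotlib figure.
    """
    emat = validate_expression(emat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = row_center_scale(emat.dropna(axis=0))
    genes = [g for g in templates.genes if g in scaled.index]
    order_key = {cls: i for i, cls in enumerate(templates.classes)}
    order_key[NOT_ASSIGNED] = len(order_key)
    samples = sorted(
        [s for s in scaled.columns if s in preds.index],
        key=lambda s: (order_key.get(preds.loc[s, "prediction"], len(order_key)), s),
    )
    block = scaled.loc[genes, samples].clip(-clip, clip)

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(block.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-clip, vmax=clip)
    boundary = 0
    for cls in templates.classes[:-1]:
        boundary += sum(1 for g in templates[cls] if g in scaled.index)
        ax.axhline(boundary - 0.5, color="black", linewidth=0.7)
    ax.set_xlabel(f"samples (n={len(samples)}, ordered by prediction)")
    ax.set_ylabel(f"template genes (p={len(genes)}, grouped by class)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row-scaled log2 expression")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gsa_heatmap(summary: pd.DataFrame, path=None, cap: float = 10.0):
    """Class x gene-set heatmap of signed -log10 adjusted p-values."""
    pivot = summary.pivot(index="set", columns="class", values="signed_log10_adj_p")
    fig, ax = plt.subplots(figsize=(2 + 0.8 * pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    data = np.clip(pivot.to_numpy(dtype=float), -cap, cap)
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-cap, vmax=cap)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label="signed -log10 adjusted p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
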