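"""Diagnostic figures: residual-variance scree plots and mean-dimensionality
bar charts (means with one standard error)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .isomap import EmbeddingResult

__all__ = ["scree_plot", "dimensionality_bars"]


def scree_plot(result: EmbeddingResult, path: str | Path | None = None):
    """Residual variance R(d) against candidate dimension d, with the
    detection threshold drawn as a horizontal line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    d = np.arange(1, result.d_max + 1)
    ax.plot(d, result.residuals, "o-", color="k")
    ax.axhline(result.threshold, color="r", ls="--",
               label=f"threshold {result.threshold}")
    if not result.censored:
        ax.axvline(result.dimensionality, color="b", ls=":",
                   label=f"$\\hat d$ = {result.dimensionality}")
    ax.set_xlabel("dimension $d$")
    ax.set_ylabel("residual variance $R(d)$")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def dimensionality_bars(trials: pd.DataFrame, by: str = "species",
                        path: str | Path | None = None):
    """Mean embedding dimensionality per group with one-standard-error bars."""
    g = trials.groupby(by)["dimensionality"]
    means = g.mean()
    sem = g.sem()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(means.index.astype(str), means.to_numpy(), yerr=sem.to_numpy(),
           capsize=4, color="0.7", edgecolor="k")
    ax.set_ylabel("mean dimensionality")
    ax.set_xlabel(by)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
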