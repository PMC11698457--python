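"""Diagnostic figures: response-permutation plot and correlation heat map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .validity import PermutationRun


def permutation_plot(
    runs: list[PermutationRun],
    r2y: float,
    q2: float,
    r2_intercept: float,
    q2_intercept: float,
    path: str | Path,
    title: str = "",
) -> None:
    """R2Y and Q2 of permuted refits vs |corr| to the original response."""
    xs = np.array([r.correlation for r in runs] + [1.0])
    r2s = np.array([r.r2y_perm for r in runs] + [r2y])
    q2s = np.array([r.q2_perm for r in runs] + [q2])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, r2s, marker="o", color="tab:green", label="R$^2$Y")
    ax.scatter(xs, q2s, marker="s", color="tab:blue", label="Q$^2$")
    grid = np.array([0.0, 1.0])
    ax.plot(grid, np.polyval(np.polyfit(xs, r2s, 1), grid), color="tab:green", lw=1)
    ax.plot(grid, np.polyval(np.polyfit(xs, q2s, 1), grid), color="tab:blue", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("|correlation| of permuted Y to original Y")
    ax.set_ylabel("value")
    ax.set_title(title or f"intercepts: R$^2$={r2_intercept:.2f}, Q$^2$={q2_intercept:.2f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_heatmap(corr: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
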