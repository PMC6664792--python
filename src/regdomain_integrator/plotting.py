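"""Thin matplotlib layer over the profile and heatmap tables.

Everything scientific lives upstream; these helpers only render the TSV/
DataFrame outputs. matplotlib is an optional dependency (``pip install
regdomain-integrator[plot]``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .coloc import DistanceProfile


def plot_profiles(
    real: DistanceProfile, random: DistanceProfile, path: str | Path
) -> None:
    """Side-by-side real vs random distance profiles (counts per bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    centers = (real.bin_edges[:-1] + real.bin_edges[1:]) / 2
    ax.step(centers, real.counts, where="mid", label=real.label or "real")
    ax.step(centers, random.counts, where="mid", label=random.label or "random")
    ax.set_xlabel("distance to peak midpoint (bp)")
    ax.set_ylabel(f"pairs per {real.bin_width} bp bin")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render the genes x contrasts log2FC matrix (rows already ordered)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(2 + matrix.shape[1], 6))
    vmax = max(1.0, float(matrix.abs().max().max()))
    im = ax.imshow(matrix.values, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} genes (sorted by {matrix.columns[0]})")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
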