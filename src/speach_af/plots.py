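"""Diagnostic plots: TM-score landscape and PC1/PC2 scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from speach_af.filtering import PCAResult

__all__ = ["plot_tm_landscape", "plot_pca"]


def plot_tm_landscape(df: pd.DataFrame, path: str | Path) -> None:
    """Scatter of TM vs reference A against TM vs reference B, one point per
    model, colored by relative MolProbity score when present; the dashed
    iso-lines mark the reference-vs-reference TM-score."""
    fig, ax = plt.subplots(figsize=(5, 5))
    color = df["relative_mp"] if "relative_mp" in df else None
    sc = ax.scatter(df["tm_vs_a"], df["tm_vs_b"], c=color, cmap="viridis", s=18)
    if color is not None:
        fig.colorbar(sc, ax=ax, label="relative MP")
    tm_ab = df.attrs.get("tm_ref_ab")
    if tm_ab is not None:
        ax.axvline(tm_ab, ls="--", c="gray", lw=0.8)
        ax.axhline(tm_ab, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("TM-score vs reference A")
    ax.set_ylabel("TM-score vs reference B")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(pca: PCAResult, path: str | Path) -> None:
    """PC1/PC2 scatter of model projections with references as stars."""
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [p[0] for p in pca.projections.values()]
    ys = [p[1] for p in pca.projections.values()]
    ax.scatter(xs, ys, s=18, label="models")
    for rid, p in pca.ref_projections.items():
        ax.scatter([p[0]], [p[1]], marker="*", s=160, label=rid)
    share = pca.variance_share(2)
    ax.set_xlabel(f"PC1 ({100 * share[0]:.0f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * share[1]:.0f}% variance)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
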