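"""Plot helpers for selection analytics: rank-abundance curves, Venn
diagrams (2 or 3 sets, drawn directly with matplotlib patches), abundance
scatter, and embedding scatter colored by cluster."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrichment import OverlapReport

__all__ = [
    "rank_abundance_plot",
    "venn_plot",
    "scatter_plot",
    "embedding_plot",
]


def rank_abundance_plot(profiles: dict[str, pd.DataFrame], path) -> None:
    """Log-log rank-abundance curves, one line per sample."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, profile in profiles.items():
        ax.plot(profile["rank"], profile["frequency"], label=label, lw=1.2)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("abundance rank")
    ax.set_ylabel("read frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


_VENN2_CENTERS = [(-0.35, 0.0), (0.35, 0.0)]
_VENN3_CENTERS = [(-0.35, 0.25), (0.35, 0.25), (0.0, -0.35)]


def venn_plot(report: OverlapReport, path) -> None:
    """Proportional-ish Venn of 2 or 3 sets with region sizes annotated."""
    centers = _VENN2_CENTERS if len(report.sets) == 2 else _VENN3_CENTERS
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (x, y), name, color in zip(centers, report.sets, colors):
        ax.add_patch(
            plt.Circle((x, y), 0.55, alpha=0.3, color=color, label=name)
        )
    # annotate each exclusive region at the mean of its member-set centers
    for region in report.regions:
        idx = [i for i, name in enumerate(report.sets) if name in region.members_of]
        cx = float(np.mean([centers[i][0] for i in idx]))
        cy = float(np.mean([centers[i][1] for i in idx]))
        # push exclusive single-set labels outward, shared labels inward
        scale = 1.4 if len(idx) == 1 else 0.6 if len(idx) == len(report.sets) else 1.0
        label = f"{region.size}"
        if np.isfinite(region.abundance_fraction):
            label += f"\n{100 * region.abundance_fraction:.1f}%"
        ax.text(cx * scale, cy * scale, label, ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_plot(pairs: pd.DataFrame, path, label_x: str = "x", label_y: str = "y") -> None:
    """Abundance scatter of two samples with Venn-region coloring."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    colors = {"both": "tab:purple", "x-only": "tab:blue", "y-only": "tab:orange"}
    floor = 1e-7
    for region, sub in pairs.groupby("region"):
        ax.scatter(
            sub["freq_x"] + floor,
            sub["freq_y"] + floor,
            s=8,
            alpha=0.5,
            color=colors.get(str(region), "gray"),
            label=region,
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"frequency in {label_x}")
    ax.set_ylabel(f"frequency in {label_y}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def embedding_plot(coordinates: pd.DataFrame, path) -> None:
    """2-D embedding colored by DBSCAN cluster (-1 = noise, gray)."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for label, sub in coordinates.groupby("cluster"):
        color = "lightgray" if label == -1 else None
        name = "noise" if label == -1 else f"cluster {label}"
        ax.scatter(sub["x"], sub["y"], s=12, alpha=0.7, color=color, label=name)
    ax.set_xlabel("embedding 1")
    ax.set_ylabel("embedding 2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
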