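"""SVG figures for the pipeline report.

Module-trait dot plot (−log10 p by trait, per region), EWCE bar chart of
sd-from-mean with significance stars, conditional-enrichment heatmap, and
Kaplan-Meier strata curves.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "module_trait_dotplot",
    "ewce_barplot",
    "conditional_heatmap",
    "km_plot",
]


def module_trait_dotplot(
    results: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """One dot per module x trait at -log10 p, with 0.05 and Bonferroni lines."""
    traits = list(results["trait"].unique())
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(4, len(traits))))
    cmap = plt.get_cmap("tab10")
    for i, trait in enumerate(traits):
        sub = results[results["trait"] == trait]
        y = np.full(len(sub), i, float)
        ax.scatter(
            -np.log10(sub["p"]),
            y + np.random.default_rng(0).uniform(-0.15, 0.15, len(sub)),
            s=20 + 80 * sub["coefficient"].abs(),
            color=cmap(i % 10),
            alpha=0.7,
            label=trait,
        )
    ax.axvline(-np.log10(0.05), ls="--", color="grey", lw=1)
    if len(results):
        ax.axvline(
            -np.log10(results["bonferroni_threshold"].iloc[0]),
            ls="--", color="black", lw=1,
        )
    ax.set_yticks(range(len(traits)), traits)
    ax.set_xlabel("-log10(p)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def ewce_barplot(result: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """sd-from-mean per cell type, stars marking q < 0.05."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(result)), 4))
    x = np.arange(len(result))
    ax.bar(x, result["sd_from_mean"], color="steelblue")
    for i, (_, row) in enumerate(result.iterrows()):
        if row["q"] < 0.05:
            ax.text(i, row["sd_from_mean"], "*", ha="center", fontsize=14)
    ax.set_xticks(x, result["celltype"], rotation=60, ha="right")
    ax.set_ylabel("SD from mean")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def conditional_heatmap(
    results: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Heatmap of sd-from-mean, tested type x controlled type, stars at q<0.05."""
    mat = results.pivot(index="celltype", columns="controlled", values="sd_from_mean")
    qmat = results.pivot(index="celltype", columns="controlled", values="q")
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * mat.shape[1], 1 + 0.5 * mat.shape[0])
    )
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", aspect="auto")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if qmat.iloc[i, j] < 0.05:
                ax.text(j, i, "*", ha="center", va="center")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=60, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_xlabel("controlled cell type")
    fig.colorbar(im, label="SD from mean")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def km_plot(curves: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Step survival curves per PRS stratum."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for stratum, sub in curves.groupby("stratum"):
        ax.step(
            sub["time"], sub["survival"], where="post",
            label=f"{stratum} (n={int(sub['n'].iloc[0])})",
        )
    ax.set_xlabel("months")
    ax.set_ylabel("free of confirmed depression")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
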