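"""Figure rendering from report TSVs.

Figures are always regenerated from the stage tables, never computed inline,
so every plotted number is traceable to a TSV.  Color scaling is
presentation-only.
"""

from __future__ import annotations

import math
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def hexamer_tile_plot(table: pd.DataFrame, ax, top_n: int = 16, title: str = ""):
    """Square-tile heat map of the most common terminal hexamers."""
    df = table.head(top_n)
    side = max(1, math.ceil(math.sqrt(len(df))))
    grid = np.full((side, side), np.nan)
    for i, count in enumerate(df["count"]):
        grid[i // side, i % side] = count
    im = ax.imshow(grid, cmap="Reds")
    for i, row in enumerate(df.itertuples(index=False)):
        ax.text(i % side, i // side, row.kmer, ha="center", va="center", fontsize=6)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title, fontsize=8)
    return im


def render_report_figures(report_dir) -> list[str]:
    """Render PNG figures next to the TSVs of an analysis report."""
    written = []
    for name in sorted(os.listdir(report_dir)):
        path = os.path.join(report_dir, name)
        if name.startswith("hexamers.") and name.endswith(".tsv"):
            df = pd.read_csv(path, sep="\t")
            if not len(df):
                continue
            fig, ax = plt.subplots(figsize=(3, 3))
            hexamer_tile_plot(df, ax, title=name[len("hexamers."):-4])
            fig.tight_layout()
            out = path[:-4] + ".png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)
        elif name.startswith("motif_metacurve.") and name.endswith(".tsv"):
            df = pd.read_csv(path, sep="\t")
            fig, ax = plt.subplots(figsize=(4, 3))
            for _, row in df.iterrows():
                ax.plot(row.drop("bin").to_numpy(dtype=float), label=row["bin"])
            ax.set_xlabel("meta-position (10 nt flank | run | 10 nt flank)")
            ax.set_ylabel("mean log2 change")
            ax.legend(fontsize=6)
            fig.tight_layout()
            out = path[:-4] + ".png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)
        elif name.startswith("distance_bins.") and name.endswith(".tsv"):
            df = pd.read_csv(path, sep="\t")
            fig, ax = plt.subplots(figsize=(3.5, 3))
            ax.bar(df["bin"], df["stabilized_end_reads"])
            ax.set_xlabel("T-run distance from TSS")
            ax.set_ylabel("stabilized end reads")
            fig.tight_layout()
            out = path[:-4] + ".png"
            fig.savefig(out, dpi=120)
            plt.close(fig)
            written.append(out)
    return written
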