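"""Plot helpers: LOD profile along the genome, optionally with a gene-class
density track on a secondary axis."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_lod_profile"]


def plot_lod_profile(
    lod_frame: pd.DataFrame,
    out_path,
    density_frame: pd.DataFrame | None = None,
    lod_threshold: float = 3.0,
):
    """LOD (and optional density) vs genomic position, one panel per
    chromosome, written to ``out_path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(lod_frame["chromosome"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = lod_frame[lod_frame["chromosome"] == chrom]
        ax.plot(sub["position"] / 1e6, sub["lod"], color="tab:blue", marker="o")
        ax.axhline(lod_threshold, color="grey", linestyle="--", linewidth=0.8)
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
        if density_frame is not None:
            dsub = density_frame[density_frame["chromosome"] == chrom]
            twin = ax.twinx()
            twin.plot(
                dsub["start"] / 1e6,
                dsub["density_per_mb"],
                color="tab:red",
                linewidth=0.8,
            )
            twin.set_ylabel("genes / Mb")
    axes[0][0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
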