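"""Genome-scan plots: per-chromosome panels of raw statistic, smoothed
track and association threshold."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .bsa_stats import GenomeScan  # noqa: E402


def plot_scan(scan: GenomeScan, path: str | Path) -> Path:
    """One panel per chromosome: raw statistic (points), smoothed track
    (line) and the genome-wide threshold (dashed)."""
    chroms = list(dict.fromkeys(scan.loci["chrom"]))
    fig, axes = plt.subplots(1, max(len(chroms), 1), sharey=True,
                             figsize=(max(2 * len(chroms), 4), 3.2))
    if len(chroms) <= 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        sub = scan.loci.loc[scan.loci["chrom"] == chrom]
        mb = sub["pos"] / 1e6
        ax.scatter(mb, sub["raw_stat"], s=2, c="0.7", rasterized=True)
        ax.plot(mb, sub["smoothed_stat"], c="black", lw=1)
        ax.axhline(scan.threshold, c="red", lw=0.8, ls="--")
        ax.set_title(chrom, fontsize=8)
        ax.tick_params(labelsize=6)
    axes[0].set_ylabel(scan.method)
    fig.suptitle(f"{scan.method} scan ({scan.threshold_quantile:.1%} threshold)",
                 fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
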