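"""Optional figures: coverage track, AF histogram, variant-density track."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .af_ploidy import AFSpectrum


def plot_coverage(windows: pd.DataFrame, path) -> None:
    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = windows[windows["chrom"] == chrom]
        ax.step(sub["start"] / 1e6, sub["copy_ratio"], where="post", lw=1)
        art = sub[sub["artifact"]]
        if not art.empty:
            ax.scatter(art["start"] / 1e6, art["copy_ratio"], c="gray", s=8,
                       label="N-gap artifact")
            ax.legend(fontsize=7)
        ax.set_ylabel("copy ratio")
        ax.set_title(chrom, fontsize=8)
    axes[-1, 0].set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_af_spectrum(spectrum: AFSpectrum, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(spectrum.bin_centers, spectrum.counts,
           width=spectrum.bin_edges[1] - spectrum.bin_edges[0])
    for x in (1 / 3, 0.5, 2 / 3):
        ax.axvline(x, color="k", lw=0.5)
    ax.set_xlabel("reference-allele frequency")
    ax.set_ylabel("SNV count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density(density: pd.DataFrame, path) -> None:
    chroms = list(dict.fromkeys(density["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = density[density["chrom"] == chrom]
        ax.plot(sub["start"] / 1e6, sub["snv_count"], lw=1, label="SNVs")
        ax2 = ax.twinx()
        ax2.plot(sub["start"] / 1e6, sub["indel_count"], lw=1, color="m",
                 label="InDels")
        ax.set_ylabel("SNVs / window")
        ax2.set_ylabel("InDels / window")
        ax.set_title(chrom, fontsize=8)
    axes[-1, 0].set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
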