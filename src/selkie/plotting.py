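"""Matplotlib figures: coverage heatmaps, heterozygosity violins, synteny
dot plots, and k-mer spectra."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .covsex import CoverageWindowTrack
from .hetscan import HetTrack
from .syntkar import SyntenyBlockSet

__all__ = [
    "plot_coverage_heatmap",
    "plot_het_violin",
    "plot_dotplot",
    "plot_kmer_spectrum",
]


def plot_coverage_heatmap(track: CoverageWindowTrack, level: float, path: str | Path) -> None:
    """One horizontal band per chromosome, colored by normalized window depth."""
    chroms = track.chromosomes
    n_max = max(len(track.windows[c]) for c in chroms)
    mat = np.full((len(chroms), n_max), np.nan)
    for i, c in enumerate(chroms):
        meds = track.chrom_medians(c) / level
        mat[i, : len(meds)] = meds
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(chroms) + 1.5))
    im = ax.imshow(mat, aspect="auto", vmin=0, vmax=1.5, cmap="viridis",
                   interpolation="nearest")
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel(f"window ({track.window_size // 1000} kbp)")
    fig.colorbar(im, ax=ax, label="depth / genome level")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_het_violin(tracks: Mapping[str, HetTrack], path: str | Path) -> None:
    """Violin of window heterozygosity densities, one violin per sample."""
    labels = list(tracks)
    data = [tracks[l].densities() for l in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=30, ha="right")
    ax.set_ylabel("heterozygous SNPs / kbp")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_dotplot(
    block_set: SyntenyBlockSet,
    ref_chrom: str,
    query_chrom: str,
    path: str | Path,
) -> None:
    """Two-band dot plot: same-orientation blocks on the top band, opposite
    orientation on the bottom band, positioned by reference coordinate."""
    fig, ax = plt.subplots(figsize=(10, 2))
    for b in block_set.blocks:
        if b.ref_chrom != ref_chrom or b.query_chrom != query_chrom:
            continue
        y = 1.0 if b.orientation == "+" else 0.0
        color = "tab:blue" if b.orientation == "+" else "tab:red"
        ax.plot([b.ref_start, b.ref_end], [y, y], lw=4, color=color,
                solid_capstyle="butt")
    ax.set_ylim(-0.5, 1.5)
    ax.set_yticks([0, 1], ["-", "+"])
    ax.set_xlabel(f"{ref_chrom} (bp)")
    ax.set_title(f"{query_chrom} vs {ref_chrom}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_kmer_spectrum(hist: Mapping[int, int], path: str | Path,
                       max_mult: int | None = None) -> None:
    mults = sorted(hist)
    if max_mult:
        mults = [m for m in mults if m <= max_mult]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(mults, [hist[m] for m in mults], lw=1.5)
    ax.set_xlabel("multiplicity")
    ax.set_ylabel("distinct k-mers")
    ax.set_yscale("log")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
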