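"""Plot helpers: coverage scatter with expected levels, AF densities, expression bars."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .allele_frequency import AFDensity
from .coverage_analysis import ChromosomeCoverageSummary, StandardizedWindow
from .expression_analysis import ExpressionSummary, reference_levels


def plot_coverage_windows(
    windows: Sequence[StandardizedWindow],
    expected_levels: Mapping[int, float],
    path: str | Path,
    title: str = "Standardized read coverage",
) -> Path:
    """Per-chromosome scatter of standardized window coverage with expected copy-number lines."""
    chroms = sorted({w.chrom for w in windows}, key=str)
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(2.2 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = [w for w in windows if w.chrom == chrom]
        ax.plot([w.start for w in sub], [w.ratio for w in sub], ".", ms=1, alpha=0.5)
        for copies, level in expected_levels.items():
            ax.axhline(level, color="grey", lw=0.6)
        ax.set_title(chrom)
        ax.set_xticks([])
    axes[0][0].set_ylabel("coverage ratio")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_coverage_summaries(
    summaries: Sequence[ChromosomeCoverageSummary],
    expected_levels: Mapping[int, float],
    path: str | Path,
) -> Path:
    """Mean standardized coverage per chromosome with +/- 2 SE error bars."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = range(len(summaries))
    ax.errorbar(
        x,
        [s.mean_ratio for s in summaries],
        yerr=[2 * s.se for s in summaries],
        fmt="o",
        capsize=3,
    )
    for copies, level in expected_levels.items():
        ax.axhline(level, color="grey", lw=0.6)
        ax.annotate(f"{copies}", (len(summaries) - 0.5, level), fontsize=7, color="grey")
    ax.set_xticks(list(x), [s.chrom for s in summaries])
    ax.set_xlabel("chromosome")
    ax.set_ylabel("mean coverage ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_af_densities(
    densities: Mapping[str, AFDensity | None], path: str | Path
) -> Path:
    """Faceted within-sample allele-frequency densities, one panel per chromosome."""
    chroms = [c for c in densities]
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(2.2 * len(chroms), 2.6), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        dens = densities[chrom]
        if dens is not None:
            ax.plot(dens.grid, dens.density, lw=1)
            for m in dens.modes:
                ax.axvline(m, color="red", lw=0.6, ls="--")
        else:
            ax.text(0.5, 0.5, "insufficient\ndata", ha="center", va="center")
        ax.set_title(chrom)
        ax.set_xlim(0, 1)
    axes[0][0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_expression_summaries(
    summaries: Sequence[ExpressionSummary], path: str | Path
) -> Path:
    """Per-chromosome mean log10 TPM with the overall mean and 0.5x / 1.5x lines."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = range(len(summaries))
    ax.bar(list(x), [s.mean_log10_tpm for s in summaries])
    if summaries:
        overall = summaries[0].overall_mean
        low, high = reference_levels(overall)
        ax.axhline(overall, color="red", lw=1)
        ax.axhline(low, color="blue", lw=0.8)
        ax.axhline(high, color="blue", lw=0.8)
    ax.set_xticks(list(x), [s.chrom for s in summaries])
    ax.set_xlabel("chromosome")
    ax.set_ylabel("mean log10 TPM")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
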