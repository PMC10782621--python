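"""Standardized read-coverage analysis for chromosome-scale copy-number inference.

Window read counts are standardized by dividing by the median count over a set
of baseline chromosomes assumed to carry the most common copy number, so that a
ratio of 1.0 corresponds to the baseline ploidy. Per-chromosome means with
standard errors, together with horizontal reference levels c / baseline_ploidy
for candidate copy numbers c, make aneuploid chromosomes visible directly.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import DEFAULT_CHROM_ORDER, WindowCount

log = logging.getLogger(__name__)

#: Baseline chromosomes used for the PK15 cell-line analyses.
PK15_BASELINE_CHROMS = ("1", "2", "3", "6", "13", "14", "15", "16")

#: Default window size in bp.
DEFAULT_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class StandardizedWindow:
    """A window count together with its coverage ratio (count / baseline median)."""

    chrom: str
    start: int
    end: int
    count: int
    ratio: float


@dataclass(frozen=True)
class ChromosomeCoverageSummary:
    """Per-chromosome mean standardized coverage with its standard error.

    The reporting convention for intervals is mean +/- 2 * se.
    """

    chrom: str
    mean_ratio: float
    se: float
    n_windows: int


def standardize_coverage(
    windows: Sequence[WindowCount], baseline_chroms: Iterable[str]
) -> tuple[list[StandardizedWindow], float]:
    """Divide every window count by the median count over baseline chromosomes.

    Returns the standardized windows and the baseline median itself. The median
    is taken over all raw window counts on the baseline chromosomes (standard
    midpoint convention for even counts); it must be positive.
    """
    baseline = set(baseline_chroms)
    if not baseline:
        raise ValueError("baseline_chroms must be non-empty")
    present = {w.chrom for w in windows}
    unknown = baseline - present
    if unknown:
        raise ValueError(f"baseline chromosome(s) {sorted(unknown)} have no windows")
    counts = np.array([w.count for w in windows if w.chrom in baseline], dtype=float)
    median = float(np.median(counts))
    if median <= 0:
        raise ValueError("baseline median coverage is zero; cannot standardize")
    std = [
        StandardizedWindow(w.chrom, w.start, w.end, w.count, w.count / median)
        for w in windows
    ]
    return std, median


def summarize_chromosomes(
    standardized_windows: Sequence[StandardizedWindow],
    chrom_order: Sequence[str] = DEFAULT_CHROM_ORDER,
) -> list[ChromosomeCoverageSummary]:
    """Mean and standard error of standardized coverage per chromosome.

    SE is the sample standard deviation (ddof=1) divided by sqrt(n_windows);
    a single-window chromosome gets SE 0. Chromosomes appear in ``chrom_order``
    first, then any remaining chromosomes in lexicographic order.
    """
    by_chrom: dict[str, list[float]] = {}
    for w in standardized_windows:
        by_chrom.setdefault(w.chrom, []).append(w.ratio)
    ordered = [c for c in chrom_order if c in by_chrom]
    ordered += sorted(c for c in by_chrom if c not in set(chrom_order))
    summaries = []
    for chrom in ordered:
        ratios = np.asarray(by_chrom[chrom], dtype=float)
        n = ratios.size
        mean = float(ratios.mean())
        se = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        summaries.append(ChromosomeCoverageSummary(chrom, mean, se, n))
    return summaries


def expected_coverage_levels(
    baseline_ploidy: int, copy_numbers: Iterable[int]
) -> dict[int, float]:
    """Expected standardized-coverage level c / baseline_ploidy for each copy number c."""
    if not isinstance(baseline_ploidy, int) or baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be an integer >= 1")
    levels = {}
    for c in copy_numbers:
        if not isinstance(c, (int, np.integer)) or c < 0:
            raise ValueError("copy numbers must be integers >= 0")
        levels[int(c)] = c / baseline_ploidy
    return levels


def suggest_baseline_chromosomes(
    windows: Sequence[WindowCount], rel_tol: float = 0.1
) -> list[str]:
    """Suggest baseline chromosomes as the largest cluster of per-chromosome medians.

    Chromosome medians are sorted and greedily clustered: a chromosome joins the
    current cluster while its median is within ``rel_tol`` (relative) of the
    cluster's first member. Intended as a helper only — it never overrides an
    explicit user choice, which mirrors how baselines are normally picked by
    inspecting the coverage plot.
    """
    medians: dict[str, float] = {}
    by_chrom: dict[str, list[int]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w.count)
    for chrom, counts in by_chrom.items():
        medians[chrom] = float(np.median(counts))
    items = sorted(medians.items(), key=lambda kv: kv[1])
    clusters: list[list[str]] = []
    anchor = None
    for chrom, med in items:
        if anchor is None or (anchor > 0 and abs(med - anchor) > rel_tol * anchor):
            clusters.append([])
            anchor = med
        clusters[-1].append(chrom)
    best = max(clusters, key=len)
    return sorted(best, key=lambda c: (len(c), c))


def mask_windows(
    windows: Sequence[WindowCount],
    mask: Iterable[tuple[str, int, int]],
) -> list[WindowCount]:
    """Exclude windows overlapping any (chrom, start, end) interval of a mask.

    Intervals use BED conventions (0-based half-open). Useful for dropping
    low-mappability regions before standardization.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in mask:
        by_chrom.setdefault(chrom, []).append((start, end))
    kept = []
    for w in windows:
        intervals = by_chrom.get(w.chrom, ())
        if any(w.start < end and start < w.end for start, end in intervals):
            continue
        kept.append(w)
    return kept
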