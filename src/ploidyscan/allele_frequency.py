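"""Within-sample allele frequencies at heterozygous sites: densities and modes.

The within-sample allele frequency (the B-allele-frequency analogue used here)
is alt_depth / (ref_depth + alt_depth) at sites called heterozygous. Its
per-chromosome density is estimated with a fixed-bandwidth Gaussian kernel on
[0, 1] and its local maxima ("modes") carry the allelic-relationship signal:
0.5 for a balanced diploid or 2:2 tetrasomic chromosome, 1/3 and 2/3 for
trisomy, 1/5 and 4/5 for a 1:4 pentasomic relationship, and so on.

Chromosomes where one allele is fixed (loss of heterozygosity, monosomy,
uniparental disomy) pile density at the boundaries, where kernel modes are
unreliable; they are summarized instead by the fixed-allele fraction, the
fraction of sites with AF <= 0.05 or >= 0.95.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm

from .io_formats import SNP, AllelicSite

log = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 0.02
DEFAULT_GRID_SIZE = 512
DEFAULT_MIN_SITES = 200
DEFAULT_PROMINENCE_FRACTION = 0.1


@dataclass(frozen=True)
class AFObservation:
    """One site's within-sample allele frequency."""

    chrom: str
    pos: int
    af: float
    total_depth: int


@dataclass
class AFDensity:
    """Kernel density of allele frequencies on a uniform grid over [0, 1].

    The density is renormalized to integrate to 1 on [0, 1] (trapezoid rule);
    ``modes`` are the retained local maxima in increasing AF order.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    modes: tuple[float, ...] = ()


def select_sites_genomic(
    sites: Iterable[AllelicSite],
    samples: Sequence[str],
    policy: str = "either",
    min_reads_per_allele: int = 0,
) -> dict[str, list[AllelicSite]]:
    """Select SNV sites for per-sample AF analysis of genome sequencing.

    Under policy ``"either"`` (appropriate for jointly called samples) a site
    enters every sample's set when it is called REF/ALT in at least one of the
    named samples; under ``"self"`` only sites called REF/ALT in the evaluated
    sample are used. In all cases the evaluated sample must have total depth
    > 0 at the site. Sites where the evaluated sample shows only one allele are
    kept by default (they are evidence of allele loss and feed the fixed-allele
    fraction); set ``min_reads_per_allele`` >= 1 to require both alleles.
    """
    if policy not in ("either", "self"):
        raise ValueError(f"unknown site-selection policy {policy!r}; use 'either' or 'self'")
    selected: dict[str, list[AllelicSite]] = {s: [] for s in samples}
    for site in sites:
        if site.variant_class != SNP:
            continue
        het_any = any(site.calls[s].genotype == "REF/ALT" for s in samples)
        for name in samples:
            call = site.calls[name]
            keep = het_any if policy == "either" else call.genotype == "REF/ALT"
            if keep and min_reads_per_allele > 0:
                keep = (
                    call.ref_depth >= min_reads_per_allele
                    and call.alt_depth >= min_reads_per_allele
                )
            if keep and call.ref_depth + call.alt_depth > 0:
                selected[name].append(site)
    return selected


def select_sites_rnaseq(
    sites: Iterable[AllelicSite], sample: str, min_reads_per_allele: int = 5
) -> list[AllelicSite]:
    """Select SNV sites for RNA-seq AF analysis: both alleles need enough reads.

    RNA-seq coverage varies far more than genome sequencing, so a site is
    retained only when at least ``min_reads_per_allele`` reads support each
    allele in the evaluated sample.
    """
    if min_reads_per_allele < 1:
        raise ValueError("min_reads_per_allele must be >= 1")
    kept = []
    for site in sites:
        if site.variant_class != SNP:
            continue
        call = site.calls[sample]
        if call.ref_depth >= min_reads_per_allele and call.alt_depth >= min_reads_per_allele:
            kept.append(site)
    return kept


def compute_af(
    sites: Iterable[AllelicSite], sample: str
) -> tuple[list[AFObservation], int]:
    """Exact within-sample allele frequencies alt/(ref+alt) for one sample.

    Returns the observations and the number of zero-depth sites skipped.
    """
    observations: list[AFObservation] = []
    skipped = 0
    for site in sites:
        call = site.calls[sample]
        total = call.ref_depth + call.alt_depth
        if total == 0:
            skipped += 1
            continue
        observations.append(
            AFObservation(site.chrom, site.pos, call.alt_depth / total, total)
        )
    if skipped:
        log.info("compute_af: skipped %d zero-depth sites for sample %s", skipped, sample)
    return observations, skipped


def fixed_allele_fraction(
    afs: Sequence[float] | np.ndarray, low: float = 0.05, high: float = 0.95
) -> float:
    """Fraction of sites whose AF is at or beyond the boundary bands [0, low] / [high, 1]."""
    arr = np.asarray(afs, dtype=float)
    if arr.size == 0:
        raise ValueError("fixed_allele_fraction needs at least one observation")
    return float(np.mean((arr <= low) | (arr >= high)))


def estimate_af_density(
    afs: Sequence[float] | np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_sites: int = DEFAULT_MIN_SITES,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> AFDensity | None:
    """Fixed-bandwidth Gaussian kernel density of AFs on a uniform [0, 1] grid.

    Returns ``None`` when fewer than ``min_sites`` observations are available
    (the chromosome is then reported as having insufficient data rather than
    raising). The density is renormalized to unit mass on [0, 1]; modes are
    detected immediately with :func:`detect_modes`.
    """
    arr = np.asarray(afs, dtype=float)
    if arr.size < min_sites:
        return None
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, 1.0, grid_size)
    density = np.zeros(grid_size)
    # chunk over observations to bound the grid x sites matrix
    for chunk in np.array_split(arr, max(1, arr.size // 4096)):
        density += norm.pdf((grid[:, None] - chunk[None, :]) / bandwidth).sum(axis=1)
    density /= arr.size * bandwidth
    area = float(np.trapezoid(density, grid))
    density /= area
    result = AFDensity(grid=grid, density=density, bandwidth=bandwidth)
    result.modes = tuple(detect_modes(result, prominence_fraction))
    return result


def detect_modes(
    density: AFDensity, prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
) -> list[float]:
    """Local maxima of the density retained above a relative prominence threshold.

    A maximum is kept when its prominence exceeds ``prominence_fraction`` times
    the density's global maximum; equal-height ties are all retained. Modes are
    returned in increasing AF order. Boundary grid points cannot be maxima by
    construction — boundary mass is the fixed-allele fraction's job.
    """
    peaks, _ = find_peaks(
        density.density, prominence=prominence_fraction * float(density.density.max())
    )
    return [float(density.grid[p]) for p in peaks]


def observations_by_chromosome(
    observations: Iterable[AFObservation],
) -> dict[str, np.ndarray]:
    """Group AF observations into per-chromosome arrays."""
    grouped: dict[str, list[float]] = {}
    for obs in observations:
        grouped.setdefault(obs.chrom, []).append(obs.af)
    return {chrom: np.asarray(vals) for chrom, vals in grouped.items()}
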