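"""End-to-end chromosome karyotype calling: coverage + AF modes + classification."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import allele_frequency as af
from . import coverage_analysis as cov
from . import ploidy_models as pm
from .io_formats import AllelicSite, WindowCount


@dataclass
class KaryotypeReport:
    """Everything the per-sample analysis produces, keyed by chromosome."""

    calls: dict[str, pm.ChromosomeCall]
    coverage_summaries: list[cov.ChromosomeCoverageSummary]
    baseline_median: float
    densities: dict[str, af.AFDensity | None] = field(default_factory=dict)


def analyze_sample(
    windows: Sequence[WindowCount],
    sites: Sequence[AllelicSite],
    sample: str,
    baseline_chroms: Sequence[str],
    baseline_ploidy: int = 2,
    policy: str = "either",
    policy_samples: Sequence[str] | None = None,
    candidates: Sequence[pm.MixtureState] | None = None,
    bandwidth: float = af.DEFAULT_BANDWIDTH,
    min_sites: int = af.DEFAULT_MIN_SITES,
    **classify_kwargs,
) -> KaryotypeReport:
    """Run the full aneuploidy analysis for one sample.

    Standardizes window coverage by the baseline-chromosome median, computes
    within-sample allele frequencies at selected heterozygous SNVs, estimates
    per-chromosome AF densities and modes, and classifies each chromosome
    against the candidate karyotype space (single clones plus 1:1 two-clone
    mixtures by default). ``policy_samples`` names the jointly called samples
    for the "either" het-selection policy; it defaults to just ``sample``.
    """
    std_windows, baseline_median = cov.standardize_coverage(windows, baseline_chroms)
    summaries = cov.summarize_chromosomes(std_windows)

    joint = list(policy_samples) if policy_samples is not None else [sample]
    if sample not in joint:
        joint.append(sample)
    selected = af.select_sites_genomic(sites, joint, policy=policy)[sample]
    observations, _ = af.compute_af(selected, sample)
    afs_by_chrom = af.observations_by_chromosome(observations)

    pool = list(candidates) if candidates is not None else pm.enumerate_candidates()
    calls: dict[str, pm.ChromosomeCall] = {}
    densities: dict[str, af.AFDensity | None] = {}
    for summary in summaries:
        chrom = summary.chrom
        values = afs_by_chrom.get(chrom, np.array([]))
        fixed = af.fixed_allele_fraction(values) if values.size else None
        density = af.estimate_af_density(values, bandwidth=bandwidth, min_sites=min_sites)
        densities[chrom] = density
        modes = density.modes if density is not None else ()
        call = pm.classify_chromosome(
            observed_ratio=summary.mean_ratio,
            observed_modes=modes,
            fixed_fraction=fixed,
            candidates=pool,
            baseline_ploidy=baseline_ploidy,
            chrom=chrom,
            **classify_kwargs,
        )
        if density is None:
            call.note = f"insufficient AF data ({values.size} sites < {min_sites})"
        calls[chrom] = call
    return KaryotypeReport(
        calls=calls,
        coverage_summaries=summaries,
        baseline_median=baseline_median,
        densities=densities,
    )


def report_to_frame(report: KaryotypeReport) -> pd.DataFrame:
    """Flatten a karyotype report into one row per chromosome."""
    rows = []
    for summary in report.coverage_summaries:
        call = report.calls[summary.chrom]
        rows.append(
            {
                "chrom": summary.chrom,
                "observed_ratio": call.observed_ratio,
                "se": summary.se,
                "n_windows": summary.n_windows,
                "observed_modes": ";".join(f"{m:.3f}" for m in call.observed_modes),
                "fixed_fraction": call.fixed_fraction,
                "best_state": str(call.best_state),
                "best_score": call.best_score,
                "degeneracy_class": " | ".join(str(s) for s in call.degeneracy_class),
                "note": call.note,
            }
        )
    return pd.DataFrame(rows)
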