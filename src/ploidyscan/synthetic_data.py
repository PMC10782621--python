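"""Synthetic karyotype data: window counts, allelic-depth VCFs and TPM tables.

Generates complete, format-valid inputs for the whole pipeline from a declared
per-chromosome karyotype, so every analysis step can be exercised end-to-end
without sequencing data. Window counts are Poisson (optionally negative
binomial) around depth_mean scaled by each chromosome's copy ratio; allelic
depths follow the Poisson-total / Binomial-alt model of
:func:`ploidyscan.ploidy_models.simulate_af_sample`; transcript TPMs carry a
log10(copy ratio) dosage shift. Heterozygous sites are placed uniformly (no
linkage or mutation-rate variation — the AF mode analysis is
position-agnostic), and no read-level artefacts (mapping bias, sequencing
error) are modelled.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_formats import WindowCount
from .ploidy_models import CloneState, MixtureState, expected_af

_BASES = np.array(list("ACGT"))

# Disjoint RNG streams per product so one simulation never perturbs another.
_STREAM_WINDOWS, _STREAM_VCF, _STREAM_TPM = 1, 2, 3


@dataclass
class KaryotypeSpec:
    """Configuration of a synthetic genome: per-chromosome states and depths.

    ``depth_mean`` is the expected reads per window at baseline ploidy;
    ``het_density`` is heterozygous sites per bp; ``site_depth_mean`` the
    expected total reads per heterozygous site at baseline ploidy. Setting
    ``overdispersion`` k switches window counts from Poisson to negative
    binomial with variance mu + mu^2 / k.
    """

    chromosome_lengths: dict[str, int]
    states: dict[str, MixtureState]
    baseline_ploidy: int = 2
    depth_mean: float = 100.0
    window_size: int = 10_000
    het_density: float = 5e-4
    site_depth_mean: float = 50.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        if any(length <= 0 for length in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        missing = set(self.chromosome_lengths) - set(self.states)
        if missing:
            raise ValueError(f"chromosomes {sorted(missing)} have no karyotype state")
        if self.depth_mean <= 0 or self.het_density <= 0 or self.site_depth_mean <= 0:
            raise ValueError("depth_mean, het_density and site_depth_mean must be > 0")
        if self.baseline_ploidy < 1:
            raise ValueError("baseline_ploidy must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    def coverage_ratio(self, chrom: str) -> float:
        """Expected standardized coverage of a chromosome under its state."""
        return float(self.states[chrom].total_copy_number()) / self.baseline_ploidy

    @classmethod
    def default(cls, seed: int = 0) -> "KaryotypeSpec":
        """Five 5-Mb chromosomes spanning the canonical states.

        Disomic 2:1, trisomic 3:1, tetrasomic 4:2, pentasomic 5:1 and
        monosomic 1:1 — 500 windows and ~2,500 heterozygous sites per
        chromosome: large enough for stable density modes, small enough for
        seconds-scale runs.
        """
        states = {
            "1": MixtureState.single(2, 1),
            "2": MixtureState.single(3, 1),
            "3": MixtureState.single(4, 2),
            "4": MixtureState.single(5, 1),
            "5": MixtureState.single(1, 1),
        }
        lengths = {chrom: 5_000_000 for chrom in states}
        return cls(chromosome_lengths=lengths, states=states, seed=seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chromosome_lengths": dict(self.chromosome_lengths),
            "states": {
                chrom: [[c.n, c.a, str(f)] for c, f in state.clones]
                for chrom, state in self.states.items()
            },
            "baseline_ploidy": self.baseline_ploidy,
            "depth_mean": self.depth_mean,
            "window_size": self.window_size,
            "het_density": self.het_density,
            "site_depth_mean": self.site_depth_mean,
            "overdispersion": self.overdispersion,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "KaryotypeSpec":
        states = {
            chrom: MixtureState.of(
                [(CloneState(int(n), int(a)), Fraction(f)) for n, a, f in clones]
            )
            for chrom, clones in data["states"].items()
        }
        return cls(
            chromosome_lengths={k: int(v) for k, v in data["chromosome_lengths"].items()},
            states=states,
            baseline_ploidy=int(data.get("baseline_ploidy", 2)),
            depth_mean=float(data.get("depth_mean", 100.0)),
            window_size=int(data.get("window_size", 10_000)),
            het_density=float(data.get("het_density", 5e-4)),
            site_depth_mean=float(data.get("site_depth_mean", 50.0)),
            overdispersion=data.get("overdispersion"),
            seed=int(data.get("seed", 0)),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "KaryotypeSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rng(spec: KaryotypeSpec, stream: int, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng([spec.seed, stream])


def simulate_window_counts(
    spec: KaryotypeSpec, rng: np.random.Generator | None = None
) -> list[WindowCount]:
    """Draw window read counts per chromosome under the spec's copy ratios."""
    rng = _rng(spec, _STREAM_WINDOWS, rng)
    windows: list[WindowCount] = []
    for chrom, length in spec.chromosome_lengths.items():
        mu = spec.depth_mean * spec.coverage_ratio(chrom)
        n_windows = math.ceil(length / spec.window_size)
        if spec.overdispersion is None:
            counts = rng.poisson(mu, size=n_windows)
        else:
            k = spec.overdispersion
            counts = rng.negative_binomial(k, k / (k + mu), size=n_windows)
        for i in range(n_windows):
            start = i * spec.window_size
            end = min(start + spec.window_size, length)
            windows.append(WindowCount(chrom, start, end, int(counts[i])))
    return windows


def _vcf_header(spec: KaryotypeSpec, sample_names: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in spec.chromosome_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("QD", 1, "Float", "Variant quality by depth")
    header.info.add("FS", 1, "Float", "Fisher strand bias score")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("MQRankSum", 1, "Float", "Mapping quality rank sum score")
    header.info.add("ReadPosRankSum", 1, "Float", "Read position rank sum score")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for name in sample_names:
        header.add_sample(name)
    return header


def simulate_allelic_vcf(
    spec: KaryotypeSpec,
    sample_names: Sequence[str],
    path: str | Path,
    fail_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write a plain-text VCF of heterozygous SNVs with simulated allelic depths.

    Sites are placed uniformly at the spec's het density; every record carries
    GT=0/1 for each sample with AD drawn under the chromosome's karyotype state
    (independent draws per sample). INFO metrics are drawn from ranges that
    pass the default hard filters; a ``fail_fraction`` of records instead get
    QD=1.0 so that filter behaviour can be tested by construction.
    """
    if not 0 <= fail_fraction <= 1:
        raise ValueError("fail_fraction must lie in [0, 1]")
    rng = _rng(spec, _STREAM_VCF, rng)
    path = Path(path)
    header = _vcf_header(spec, sample_names)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, length in spec.chromosome_lengths.items():
            state = spec.states[chrom]
            p = float(expected_af(state))
            depth_mu = spec.site_depth_mean * spec.coverage_ratio(chrom)
            n_sites = int(rng.poisson(length * spec.het_density))
            positions = np.unique(rng.integers(1, length, size=n_sites))
            for pos in positions:
                ref_base, alt_base = rng.choice(4, size=2, replace=False)
                rec = vcf.new_record(
                    contig=chrom,
                    start=int(pos) - 1,
                    alleles=(str(_BASES[ref_base]), str(_BASES[alt_base])),
                )
                rec.qual = 100.0
                failing = rng.random() < fail_fraction
                rec.info["QD"] = 1.0 if failing else float(rng.uniform(10, 30))
                rec.info["FS"] = float(rng.uniform(0, 10))
                rec.info["MQ"] = float(rng.uniform(55, 60))
                rec.info["MQRankSum"] = float(rng.uniform(-2, 2))
                rec.info["ReadPosRankSum"] = float(rng.uniform(-2, 2))
                for name in sample_names:
                    depth = int(rng.poisson(depth_mu))
                    p_site = p if rng.random() < 0.5 else 1.0 - p
                    alt_depth = int(rng.binomial(depth, p_site)) if depth > 0 else 0
                    rec.samples[name]["GT"] = (0, 1)
                    rec.samples[name]["AD"] = (depth - alt_depth, alt_depth)
                vcf.write(rec)
    return path


def simulate_tpm_table(
    spec: KaryotypeSpec,
    transcripts_per_chrom: int = 200,
    base_log10_tpm: float = 1.0,
    base_log10_tpm_sd: float = 0.5,
    zero_read_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a transcript TPM table with a copy-dosage effect, plus its map.

    Per transcript, log10 TPM ~ Normal(base + log10(coverage ratio), sd); a
    ``zero_read_fraction`` of transcripts are unexpressed (TPM 0, 0 reads).
    Returns (TPM table with target_id/tpm/est_counts, transcript map with
    transcript_id/gene_id/chrom), both reproducible given the spec's seed.
    """
    rng = _rng(spec, _STREAM_TPM, rng)
    rows, map_rows = [], []
    for chrom in spec.chromosome_lengths:
        shift = math.log10(spec.coverage_ratio(chrom))
        log_tpm = rng.normal(base_log10_tpm + shift, base_log10_tpm_sd, transcripts_per_chrom)
        tpm = 10.0 ** log_tpm
        zero = rng.random(transcripts_per_chrom) < zero_read_fraction
        counts = np.maximum(1, rng.poisson(tpm * 5.0))
        tpm[zero] = 0.0
        counts[zero] = 0
        for i in range(transcripts_per_chrom):
            tx = f"tx_{chrom}_{i}"
            rows.append({"target_id": tx, "tpm": float(tpm[i]), "est_counts": int(counts[i])})
            map_rows.append({"transcript_id": tx, "gene_id": f"g_{chrom}_{i // 2}", "chrom": chrom})
    return pd.DataFrame(rows), pd.DataFrame(map_rows)
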