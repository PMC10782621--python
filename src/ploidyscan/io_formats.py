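"""Readers, writers and hard filters for standard variant, coverage and expression formats.

This module is the only place that touches file formats: VCF (via pysam),
BED-like 4-column window-count text, and tab-separated TPM expression tables.
Coordinate conventions are centralized here: VCF positions are 1-based,
window intervals are 0-based half-open (BED).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: Genotype categories used throughout (per-sample diploid calls on biallelic sites).
GENOTYPES = ("missing", "REF/REF", "REF/ALT", "ALT/ALT")

#: Site-level INFO annotations consumed by the hard filters.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: Display order for pig chromosomes; chromosome names are otherwise opaque strings.
DEFAULT_CHROM_ORDER = tuple(str(i) for i in range(1, 19)) + ("X", "Y")

SNP = "SNP"
INDEL = "indel"


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call and allelic depths at a site."""

    genotype: str
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype encoding {self.genotype!r}; expected one of {GENOTYPES}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allelic depths must be non-negative")


@dataclass
class AllelicSite:
    """A biallelic variant with per-sample calls/depths and site-level filter metrics.

    Multiallelic VCF rows are never represented; they are excluded at parse time.
    ``flagged`` marks sites whose AD field was absent or malformed (depths set to 0,0).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    calls: dict[str, SampleCall]
    info_metrics: dict[str, float | None] = field(default_factory=dict)
    variant_class: str = SNP
    flagged: bool = False

    def __post_init__(self) -> None:
        expected = SNP if (len(self.ref_allele) == 1 and len(self.alt_allele) == 1) else INDEL
        if self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele} (expected {expected})"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds on site annotations; a strict inequality fails a site.

    Defaults follow common GATK germline hard-filtering practice: separate
    threshold sets for SNVs and indels, with MQ/MQRankSum applied to SNVs only.
    """

    snp_qd_min: float = 2.0
    snp_fs_max: float = 60.0
    snp_mq_min: float = 40.0
    snp_mq_rank_sum_min: float = -12.5
    snp_read_pos_rank_sum_min: float = -8.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_read_pos_rank_sum_min: float = -20.0


@dataclass(frozen=True)
class WindowCount:
    """Read count in one genomic window (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    count: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.start >= self.end:
            raise ValueError("window start must be < end")
        if self.count < 0:
            raise ValueError("window count must be >= 0")


def _genotype_label(gt: tuple | None) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    if any(a is None for a in gt):
        return "missing"
    alleles = sorted(gt)
    if alleles == [0, 0]:
        return "REF/REF"
    if alleles == [0, 1]:
        return "REF/ALT"
    if alleles == [1, 1]:
        return "ALT/ALT"
    raise ValueError(f"unexpected genotype {gt!r} on a biallelic site")


def read_allelic_sites(
    vcf_source: str | Path,
    sample_names: Sequence[str] | None = None,
    snvs_only: bool = False,
) -> list[AllelicSite]:
    """Parse biallelic variants with GT/AD from a VCF (plain or bgzipped).

    Multiallelic rows are excluded. Indel rows are parsed (they participate in
    filtering and genotype cross-tabulation) unless ``snvs_only`` is set; the
    allele-frequency analysis itself is restricted to SNVs downstream.

    Rows lacking a usable AD field yield depths (0, 0) and are ``flagged``
    rather than silently dropped.
    """
    with pysam.VariantFile(str(vcf_source)) as vcf:
        available = list(vcf.header.samples)
        if sample_names is None:
            sample_names = available
        missing = [s for s in sample_names if s not in available]
        if missing:
            raise ValueError(
                f"sample(s) {missing} not present in VCF; available samples: {available}"
            )
        sites: list[AllelicSite] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic or ALT-less rows are out of scope
            ref, alt = rec.ref, rec.alts[0]
            vclass = SNP if (len(ref) == 1 and len(alt) == 1) else INDEL
            if snvs_only and vclass != SNP:
                continue
            info: dict[str, float | None] = {}
            for key in INFO_KEYS:
                value = rec.info.get(key)
                info[key] = float(value) if value is not None else None
            calls: dict[str, SampleCall] = {}
            flagged = False
            for name in sample_names:
                data = rec.samples[name]
                genotype = _genotype_label(data.get("GT"))
                ad = data.get("AD")
                if ad is None or len(ad) < 2 or any(d is None for d in ad[:2]):
                    ref_depth, alt_depth = 0, 0
                    flagged = True
                else:
                    ref_depth, alt_depth = int(ad[0]), int(ad[1])
                calls[name] = SampleCall(genotype, ref_depth, alt_depth)
            sites.append(
                AllelicSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    calls=calls,
                    info_metrics=info,
                    variant_class=vclass,
                    flagged=flagged,
                )
            )
    return sites


def _fails_filters(site: AllelicSite, t: FilterThresholds) -> bool:
    metrics = site.info_metrics

    def below(key: str, bound: float) -> bool:
        value = metrics.get(key)
        return value is not None and value < bound

    def above(key: str, bound: float) -> bool:
        value = metrics.get(key)
        return value is not None and value > bound

    if site.variant_class == SNP:
        return (
            below("QD", t.snp_qd_min)
            or above("FS", t.snp_fs_max)
            or below("MQ", t.snp_mq_min)
            or below("MQRankSum", t.snp_mq_rank_sum_min)
            or below("ReadPosRankSum", t.snp_read_pos_rank_sum_min)
        )
    return (
        below("QD", t.indel_qd_min)
        or above("FS", t.indel_fs_max)
        or below("ReadPosRankSum", t.indel_read_pos_rank_sum_min)
    )


def apply_hard_filters(
    sites: Iterable[AllelicSite], thresholds: FilterThresholds | None = None
) -> list[AllelicSite]:
    """Remove sites failing any strict hard-filter inequality for their variant class.

    Absent metrics never fail a site (rank-sum annotations are only emitted for
    heterozygous sites by common callers). The operation is idempotent.
    """
    t = thresholds or FilterThresholds()
    return [s for s in sites if not _fails_filters(s, t)]


def genotype_crosstab(
    sites: Iterable[AllelicSite], sample_a: str, sample_b: str
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate genotype calls of two samples, separately for SNPs and indels.

    Returns ``{"SNP": 4x4 DataFrame, "indel": 4x4 DataFrame}`` with rows indexed
    by sample A's genotype and columns by sample B's, over the categories
    ``missing, REF/REF, REF/ALT, ALT/ALT``. Each table's total equals the number
    of input sites of that variant class.
    """
    tables = {
        vclass: pd.DataFrame(0, index=list(GENOTYPES), columns=list(GENOTYPES))
        for vclass in (SNP, INDEL)
    }
    for site in sites:
        for name in (sample_a, sample_b):
            if name not in site.calls:
                raise ValueError(f"sample {name!r} has no call at {site.chrom}:{site.pos}")
        ga = site.calls[sample_a].genotype
        gb = site.calls[sample_b].genotype
        if ga not in GENOTYPES or gb not in GENOTYPES:
            raise ValueError(f"unknown genotype encoding ({ga!r}, {gb!r})")
        tables[site.variant_class].loc[ga, gb] += 1
    return tables


def read_window_counts(source: str | Path) -> list[WindowCount]:
    """Read BED-like window counts (chrom, start, end, count; tab-separated).

    Windows must be sorted by start within each chromosome and non-overlapping;
    malformed records raise with their line number rather than being coerced.
    """
    windows: list[WindowCount] = []
    last_end: dict[str, int] = {}
    with open(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{source}: line {lineno}: expected 4 tab-separated fields")
            chrom = parts[0]
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{source}: line {lineno}: non-integer field ({exc})") from None
            if start < 0 or count < 0:
                raise ValueError(f"{source}: line {lineno}: negative start or count")
            if start >= end:
                raise ValueError(f"{source}: line {lineno}: start {start} >= end {end}")
            if chrom in last_end and start < last_end[chrom]:
                raise ValueError(
                    f"{source}: line {lineno}: window overlaps or is unsorted on chromosome {chrom}"
                )
            last_end[chrom] = end
            windows.append(WindowCount(chrom, start, end, count))
    return windows


def write_window_counts(windows: Iterable[WindowCount], sink: str | Path) -> Path:
    """Write window counts as 4-column BED-like text, sorted by (chrom, start)."""
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    sink = Path(sink)
    with open(sink, "w") as handle:
        for w in ordered:
            handle.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.count}\n")
    return sink


_TRANSCRIPT_COLS = ("target_id", "transcript_id", "transcript", "tx_id")
_TPM_COLS = ("tpm", "TPM")
_COUNT_COLS = ("est_counts", "est_count", "counts", "reads")


def read_tpm_table(
    tsv_source: str | Path,
    transcript_col: str | None = None,
    tpm_col: str | None = None,
    counts_col: str | None = None,
) -> pd.DataFrame:
    """Read a transcript expression table (tab-separated, with header).

    Column names compatible with common quantifier output are auto-detected;
    returns a DataFrame with columns ``transcript_id``, ``tpm`` and, when
    present, ``est_counts``. Negative TPM values are rejected.
    """
    df = pd.read_csv(tsv_source, sep="\t")

    def pick(explicit: str | None, candidates: tuple[str, ...], what: str, required: bool) -> str | None:
        if explicit is not None:
            if explicit not in df.columns:
                raise ValueError(f"{what} column {explicit!r} not in table columns {list(df.columns)}")
            return explicit
        for cand in candidates:
            if cand in df.columns:
                return cand
        if required:
            raise ValueError(f"no {what} column found among {list(df.columns)}")
        return None

    tx = pick(transcript_col, _TRANSCRIPT_COLS, "transcript-id", required=True)
    tpm = pick(tpm_col, _TPM_COLS, "TPM", required=True)
    cnt = pick(counts_col, _COUNT_COLS, "read-count", required=False)

    out = pd.DataFrame({"transcript_id": df[tx].astype(str), "tpm": df[tpm].astype(float)})
    if (out["tpm"] < 0).any():
        bad = out.loc[out["tpm"] < 0, "transcript_id"].iloc[0]
        raise ValueError(f"negative TPM for transcript {bad!r}")
    if cnt is not None:
        out["est_counts"] = df[cnt].astype(float)
    return out
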