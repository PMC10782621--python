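"""Per-chromosome expression-dosage summaries from TPM tables.

Chromosome-scale copy-number changes leave a dosage footprint in RNA-seq:
chromosomes with extra copies show elevated average expression. The summary is
the mean of log10(TPM) over expressed transcripts per chromosome, compared to
the genome-wide mean, with reference lines at 0.5x and 1.5x of that mean
(applied to the log-scale mean itself, matching the plotting convention this
analysis reproduces, even though scaling a log-scale mean is unconventional).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionSummary:
    """Mean log10 TPM over expressed transcripts on one chromosome."""

    chrom: str
    mean_log10_tpm: float
    n_transcripts: int
    overall_mean: float


def chromosome_expression_summary(
    tpm_records: pd.DataFrame,
    transcript_chrom_map: pd.DataFrame,
    exclude_chroms: Iterable[str] = ("Y",),
    gene_level: bool = False,
) -> tuple[list[ExpressionSummary], int]:
    """Per-chromosome mean log10 TPM over expressed transcripts.

    ``tpm_records`` needs columns ``transcript_id`` and ``tpm`` (and optionally
    ``est_counts``); ``transcript_chrom_map`` needs ``transcript_id`` and
    ``chrom`` (and ``gene_id`` when ``gene_level`` is requested, in which case
    TPM is summed per gene before taking logs). A transcript is "expressed"
    when its estimated read count is > 0, or — when no count column is present
    — when its TPM is > 0. Chromosomes in ``exclude_chroms`` (the Y by
    default, whose expression is uninformative here) are omitted from both the
    per-chromosome output and the overall mean.

    Returns the summaries plus the number of transcripts with no chromosome
    mapping (excluded from every mean).
    """
    excluded = set(exclude_chroms)
    df = tpm_records.merge(transcript_chrom_map, on="transcript_id", how="left")
    unmapped = int(df["chrom"].isna().sum())
    if unmapped:
        log.warning("%d transcripts had no chromosome mapping and were excluded", unmapped)
    df = df.dropna(subset=["chrom"])
    if "est_counts" in df.columns:
        df = df[df["est_counts"] > 0]
    else:
        df = df[df["tpm"] > 0]
    df = df[df["tpm"] > 0]  # log10 of zero-TPM entries is undefined regardless
    df = df[~df["chrom"].isin(excluded)]
    if gene_level:
        if "gene_id" not in df.columns:
            raise ValueError("gene_level summaries need a gene_id column in the transcript map")
        df = (
            df.groupby(["chrom", "gene_id"], as_index=False)
            .agg(tpm=("tpm", "sum"))
        )
    df = df.assign(log10_tpm=np.log10(df["tpm"]))
    overall = float(df["log10_tpm"].mean()) if len(df) else float("nan")
    summaries = [
        ExpressionSummary(
            chrom=str(chrom),
            mean_log10_tpm=float(group["log10_tpm"].mean()),
            n_transcripts=int(len(group)),
            overall_mean=overall,
        )
        for chrom, group in df.groupby("chrom", sort=True)
    ]
    return summaries, unmapped


def reference_levels(overall_mean: float) -> tuple[float, float]:
    """The 0.5x and 1.5x reference lines around the genome-wide mean log10 TPM."""
    return 0.5 * overall_mean, 1.5 * overall_mean


def summaries_to_frame(summaries: Sequence[ExpressionSummary]) -> pd.DataFrame:
    """Tabular form of per-chromosome expression summaries."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in summaries],
            "mean_log10_tpm": [s.mean_log10_tpm for s in summaries],
            "n_transcripts": [s.n_transcripts for s in summaries],
            "overall_mean": [s.overall_mean for s in summaries],
        }
    )
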