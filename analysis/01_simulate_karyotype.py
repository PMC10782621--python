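#!/usr/bin/env python
"""Generate the synthetic study genome: window counts, allelic-depth VCF, TPM table.

Five 5-Mb chromosomes with karyotype states 2:1 (disomic), 3:1 (trisomic),
4:2 (balanced tetrasomic), 5:1 (pentasomic) and 1:1 (monosomic), sequenced to
~100 reads per 10-kb window and ~50 reads per heterozygous site at baseline
ploidy, with two jointly called samples. Everything downstream
(02_coverage_analysis.py onwards) consumes only these files.
"""
import argparse
from pathlib import Path

from ploidyscan.io_formats import write_window_counts
from ploidyscan.synthetic_data import (
    KaryotypeSpec,
    simulate_allelic_vcf,
    simulate_tpm_table,
    simulate_window_counts,
)

SAMPLES = ["lineA", "lineB"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240111)
    parser.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = KaryotypeSpec.default(seed=args.seed)
    spec.to_json(args.outdir / "karyotype.json")

    windows = simulate_window_counts(spec)
    write_window_counts(windows, args.outdir / "windows.bed")
    simulate_allelic_vcf(spec, SAMPLES, args.outdir / "variants.vcf")
    tpm, tx_map = simulate_tpm_table(spec)
    tpm.to_csv(args.outdir / "tpm.tsv", sep="\t", index=False)
    tx_map.to_csv(args.outdir / "transcripts.tsv", sep="\t", index=False)

    print(f"synthetic genome written to {args.outdir}/ (seed {args.seed})")
    print("true per-chromosome states:")
    for chrom, state in spec.states.items():
        print(f"  chr{chrom}: {state} (coverage ratio {spec.coverage_ratio(chrom):.2f})")
    print(f"{len(windows)} windows, samples {SAMPLES}, {len(tpm)} transcripts")


if __name__ == "__main__":
    main()
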