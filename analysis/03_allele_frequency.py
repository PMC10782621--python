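#!/usr/bin/env python
"""Within-sample allele frequencies: per-chromosome densities and modes.

Parses the jointly called VCF, applies the hard filters, selects SNVs
heterozygous in either sample, and estimates each chromosome's AF density and
modes for one sample. Mode positions near 0.5, {1/3, 2/3} and {1/5, 4/5}
identify balanced, trisomic and 1:4 allelic relationships; a high
fixed-allele fraction flags chromosomes where one allele has been lost.
"""
import argparse
from pathlib import Path

import pandas as pd

from ploidyscan.allele_frequency import (
    compute_af,
    estimate_af_density,
    fixed_allele_fraction,
    observations_by_chromosome,
    select_sites_genomic,
)
from ploidyscan.io_formats import apply_hard_filters, read_allelic_sites
from ploidyscan.plots import plot_af_densities

SAMPLES = ["lineA", "lineB"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--sample", default="lineA")
    args = parser.parse_args()
    (args.outdir / "figures").mkdir(parents=True, exist_ok=True)

    sites = read_allelic_sites(args.indir / "variants.vcf")
    kept = apply_hard_filters(sites)
    print(f"{len(sites)} biallelic SNVs parsed, {len(kept)} pass hard filters")

    selected = select_sites_genomic(kept, SAMPLES, policy="either")[args.sample]
    observations, skipped = compute_af(selected, args.sample)
    print(f"{len(observations)} AF observations for {args.sample} ({skipped} zero-depth skipped)")

    rows, densities = [], {}
    for chrom, afs in sorted(observations_by_chromosome(observations).items()):
        density = estimate_af_density(afs)
        densities[chrom] = density
        modes = ";".join(f"{m:.3f}" for m in density.modes) if density else "insufficient"
        rows.append(
            {
                "chrom": chrom,
                "n_sites": len(afs),
                "modes": modes,
                "fixed_fraction": fixed_allele_fraction(afs),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(args.outdir / "af_modes.tsv", sep="\t", index=False)
    plot_af_densities(densities, args.outdir / "figures" / "af_densities.png")
    print(frame.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
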