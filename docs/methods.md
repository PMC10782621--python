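# Methods

## Problem and model

Cultured cell lines accumulate chromosome-scale copy-number changes, and the
karyotype of a line can differ between isolates. `ploidyscan` infers
per-chromosome copy-number states from two orthogonal signals in short-read
genome sequencing, with RNA-seq expression dosage as corroboration:

1. **Standardized read coverage.** The genome is tiled in fixed windows
   (default 10 kbp) and each window's read count is divided by the median
   count over *baseline* chromosomes assumed to carry the most common copy
   number. A chromosome with copy number `c` under baseline ploidy `P` is
   expected at ratio `c / P`. The median (not the mean) is used so that
   aneuploid outlier windows on baseline chromosomes do not shift the scale;
   ties use the standard midpoint convention.

2. **Within-sample allele frequency (AF).** At biallelic heterozygous SNVs
   the fraction of reads carrying the alternative allele, `alt/(ref+alt)`,
   clusters around ratios set by the allelic copy split. A chromosome whose
   cells carry `n` copies, `a` of them bearing the alternative allele, shows
   AF modes at `a/n` and `(n-a)/n`: 0.5 for disomy (or balanced 2:2
   tetrasomy), {1/3, 2/3} for trisomy, {1/5, 4/5} for a 1:4 pentasomic
   relationship.

### Clonal mixtures and degeneracy

A sample may be a mixture of clones `j` with fractions `f_j`, each clone with
copy number `n_j` and alternative-copy count `a_j`. The expected AF of the
mixture is the copy-weighted average

    E[AF] = (Σ_j f_j a_j) / (Σ_j f_j n_j),

and the expected coverage ratio is `Σ_j f_j n_j / P`. Because a heterozygous
site's alternative allele sits on either haplotype role with equal
probability, the observable mode set of a state is `{p, 1 − p}` with
`p = E[AF]`. All of this arithmetic is done in exact rationals
(`fractions.Fraction`), which lets the key degeneracy identities be asserted
without numerical tolerance:

* a 1:1 mixture of diploid (2:1) and monosomic (1:1) cells has
  `E[AF] = 2/3` — the same mode set {1/3, 2/3} as a fully trisomic (3:1)
  population;
* a 1:1 mixture of diploid (2:0) and trisomic (3:1) cells has
  `E[AF] = 1/5` — the same mode set {1/5, 4/5} as a pentasomic (5:1)
  population.

Relative coverage cannot break these ties on its own: the standardization
baseline's ploidy is itself an assumption, so a genome-wide mixture rescales
all ratios together. Classification therefore reports a **degeneracy class**,
never a single state (see below).

## AF density estimation and mode detection

Per chromosome, AFs of selected sites are smoothed with a fixed-bandwidth
Gaussian kernel evaluated on a uniform 512-point grid over [0, 1] and
renormalized to unit mass on the interval. Defaults: bandwidth 0.02 on the AF
scale, minimum 200 sites (fewer → the chromosome is reported as having
insufficient data, not an exception), mode prominence threshold 0.1 × the
density maximum, equal-height ties all retained. These settings resolve modes
spaced 1/5 apart at site depths ≥ 20 in simulation while suppressing sampling
ripple; bandwidth is absolute rather than data-driven because the expected
mode spacing is known a priori and a variance-scaled bandwidth degenerates on
fixed-allele chromosomes.

Boundary modes (AF ≈ 0 or 1) are intentionally not reported by the peak
detector — kernel estimates are unreliable at the interval edge. Chromosomes
with lost heterozygosity (monosomy, uniparental disomy, allele loss) are
instead summarized by the **fixed-allele fraction**: the fraction of sites
with AF ≤ 0.05 or ≥ 0.95.

### Site selection

Genome sequencing: under the `either` policy (for jointly called samples) a
site enters each sample's AF set when it is called REF/ALT in at least one of
the samples and has nonzero depth in the evaluated sample; under `self`, only
the sample's own heterozygous calls are used. Sites where the evaluated
sample shows a single allele are kept by default — an AF of exactly 0 or 1
carries no heterozygosity information but is direct evidence of allele loss,
so it feeds the fixed-allele fraction; a per-allele read floor is available
as a parameter for users who want the stricter set. RNA-seq: at least five
reads from each allele (configurable), because RNA coverage is far more
variable than genomic coverage.

## Hard filters

Variant sites are removed when any strict inequality in the applicable set
holds — SNVs: QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0; indels: QD < 2.0, FS > 200.0, ReadPosRankSum < −20.0.
Absent annotations never fail a site (callers emit the rank-sum metrics only
for heterozygous sites), boundary values are retained, and the operation is
idempotent. Multiallelic rows are dropped rather than decomposed: the
analysis is defined over biallelic variants. Indels are parsed for filtering
and genotype cross-tabulation but excluded from AF analysis.

## Classification and the degeneracy class

The candidate space is every single clone with `1 ≤ n ≤ 6`, `0 ≤ a ≤ n`,
plus all 1:1 two-clone mixtures of such clones (canonically deduplicated;
the fraction grid is configurable). Each candidate is scored against the
observations:

    score = w_cov · (observed ratio − expected ratio)²
          + w_af · assignment(observed modes, expected modes)

where `assignment` optimally pairs observed with expected modes
(Hungarian algorithm on squared differences) and charges a penalty
λ = 0.25 per unmatched mode on either side. Defaults `w_cov = w_af = 1`.
A fixed-allele fraction ≥ 0.6 restricts candidates to states with an AF-0/1
orientation (loss-of-heterozygosity-compatible states). Ties between equal
scores break by parsimony (fewer clones first), so a pure trisomy is
reported ahead of an equivalent mixture.

The degeneracy class of a call is the union of (a) all candidates within
10⁻³ of the best score and (b) all candidates whose mode signature is
indistinguishable from the best candidate's within 0.02 — (b) captures the
mixtures that coverage alone cannot exclude once the baseline ploidy is an
assumption. The class for a monosomic chromosome always contains both `1:0`
and `1:1`: with one copy the two orientations are the same physical state.

## HDR arithmetic

For genome-editing planning, the probability that an assay with per-copy
homology-directed repair efficiency `e` repairs **all** copies at a site of
copy number `n` is `e^n` under independence: a 20% assay yields 4% at disomic
and 0.8% at trisomic sites. This is the package's quantitative argument for
checking ploidy before designing editing experiments.

## Synthetic data generator

The simulator emulates the post-alignment, post-calling inputs (window
counts, a jointly called VCF with GT/AD and the five INFO annotations, a
TPM table with transcript→chromosome map) — never reads, alignments or the
calling itself.

* Window counts: Poisson with mean `depth_mean × (Σ f_j n_j / P)` per
  window; an optional negative-binomial overdispersion parameter `k`
  (variance `μ + μ²/k`) is available for robustness experiments.
* Allelic depths: total depth Poisson around `site_depth_mean` scaled by the
  chromosome's coverage ratio; orientation uniform between the two mode
  positions; alternative reads Binomial. This is the minimal generative
  model consistent with the mode analysis, and its defaults
  (`depth_mean = 100` reads/window, `site_depth_mean = 50`,
  `het_density = 5 × 10⁻⁴`/bp) put the synthetic genome in the depth regime
  of a well-covered short-read cell-line experiment.
* TPM: per transcript, `log10 TPM ~ Normal(base + log10(coverage ratio),
  sd)` with base 1.0 and sd 0.5 — a pure dosage effect with log-normal
  biological spread; a 5% zero-read fraction exercises the expressed-only
  inclusion rule.
* Heterozygous sites are placed uniformly; INFO metrics are drawn from
  ranges that pass the default filters (QD 10–30, FS 0–10, MQ 55–60,
  rank sums ±2), with failures injected only by explicit request
  (`fail_fraction`, which sets QD = 1.0).

The default genome is five 5-Mb chromosomes (500 windows, ~2,500
heterozygous sites each) carrying the canonical states 2:1, 3:1, 4:2, 5:1
and 1:1 — large enough for stable density modes, small enough that the full
simulate→standardize→AF→classify round trip runs in seconds. What passing
recovery tests on this generator shows is that the inference is consistent
with its own generative model at realistic depths; real data add GC and
mappability bias, segmental (sub-chromosomal) events, mapping artefacts and
correlated noise that the generator deliberately omits, so recovery here is
a necessary, not sufficient, check.

## Expression dosage

Per chromosome, the mean of log10 TPM over transcripts with more than zero
estimated reads (or TPM > 0 when the table carries no count column),
compared with the genome-wide mean of the same quantity; reference lines at
0.5× and 1.5× of that mean follow the plotting convention this analysis
reproduces, even though scaling a log-scale mean is unconventional — fidelity
to the source analysis was preferred over convention. The Y chromosome is
excluded by default (its average expression is uninformative); a
`gene_level` flag sums transcript TPM per gene before taking logs, since the
transcript-vs-gene level of the averaging is genuinely ambiguous in this
kind of analysis.

## Degenerate inputs and numerical choices

* Zero-depth sites are skipped with a reported count; zero-count windows are
  retained (ratio 0) unless masked.
* A baseline median of zero raises; an all-`n=0` mixture raises.
* Mixture fractions are validated to sum to 1 within 10⁻⁹ and renormalized
  exactly; clone order and fraction symmetry never distinguish states.
* KDE on a point mass (all AFs equal) is well-defined because the bandwidth
  is absolute.
* Reported problem sizes: the flagship run and the acceptance computations
  use 5,000 sites per simulated AF sample and the five-chromosome default
  genome, sizes at which the stochastic checks are stable across seeds.

## Known limitations

Sub-chromosomal (segmental) events are out of scope: windows are summarized
per chromosome and no changepoint segmentation is attempted, so a partial
trisomy surfaces only as an intermediate coverage ratio. Coverage bias
(GC, mappability) is not corrected — the mask hook exists but no mask is
bundled. The candidate space caps copies at six and mixtures at two clones
on a configurable fraction grid; more complex clonal structures will be
reported as their closest degenerate representative.
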