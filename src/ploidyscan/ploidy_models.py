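"""Karyotype hypotheses: expected AF modes, coverage signatures, degeneracy, HDR.

The inferential core. A chromosome's state is modelled as a mixture of clones,
each clone carrying ``n`` total copies of the chromosome with ``a`` of them
bearing the alternative allele at a heterozygous site. The expected
within-sample allele frequency of the mixture is the copy-weighted average

    E[AF] = sum_j f_j * a_j / sum_j f_j * n_j

and its expected standardized coverage is sum_j f_j * n_j / baseline_ploidy.
Because a heterozygous site's alternative allele sits on either haplotype role
with equal probability, the observable mode set contains both allele
orientations, {p, 1 - p}. Different mixtures can share the same signature —
e.g. a 1:1 mixture of diploid and monosomic cells produces the same AF modes
as a fully trisomic population — so classification reports a degeneracy class
rather than a single state.

All mode arithmetic is exact (``fractions.Fraction``), which lets the
degeneracy identities be asserted without tolerance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

DEFAULT_MAX_COPIES = 6
DEFAULT_FIXED_THRESHOLD = 0.6
DEFAULT_SCORE_TOL = 1e-3
DEFAULT_MODE_TOL = 0.02
DEFAULT_UNMATCHED_PENALTY = 0.25


@dataclass(frozen=True, order=True)
class CloneState:
    """One clone's chromosome state: n total copies, a of them alt-bearing."""

    n: int
    a: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("copy number n must be >= 0")
        if not 0 <= self.a <= self.n:
            raise ValueError(f"alt copy count a={self.a} must satisfy 0 <= a <= n={self.n}")

    def __str__(self) -> str:
        return f"{self.n}:{self.a}"


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(float(x))


@dataclass(frozen=True)
class MixtureState:
    """A clonal mixture: clones with positive fractions summing to one.

    Stored canonically — equal clones merged, clones sorted — so a single-clone
    mixture compares equal to any construction of the same clone, and clone
    order / fraction symmetry never distinguishes states.
    """

    clones: tuple[tuple[CloneState, Fraction], ...]

    @classmethod
    def of(cls, clones: Iterable[tuple[CloneState, object]]) -> "MixtureState":
        merged: dict[CloneState, Fraction] = {}
        for clone, frac in clones:
            f = _as_fraction(frac)
            if f <= 0:
                raise ValueError("clone fractions must be > 0")
            merged[clone] = merged.get(clone, Fraction(0)) + f
        if not merged:
            raise ValueError("a mixture needs at least one clone")
        total = sum(merged.values())
        if abs(total - 1) > Fraction(1, 10**9):
            raise ValueError(f"clone fractions sum to {float(total)}, not 1")
        normalized = tuple(
            sorted(((clone, f / total) for clone, f in merged.items()), key=lambda t: t[0])
        )
        return cls(normalized)

    @classmethod
    def single(cls, n: int, a: int) -> "MixtureState":
        return cls.of([(CloneState(n, a), Fraction(1))])

    @property
    def is_single_clone(self) -> bool:
        return len(self.clones) == 1

    def total_copy_number(self) -> Fraction:
        """Mixture-average copy number sum_j f_j * n_j."""
        return sum((f * c.n for c, f in self.clones), Fraction(0))

    def complement(self) -> "MixtureState":
        """Swap allele orientation in every clone (a -> n - a)."""
        return MixtureState.of([(CloneState(c.n, c.n - c.a), f) for c, f in self.clones])

    def __str__(self) -> str:
        if self.is_single_clone:
            return str(self.clones[0][0])
        return " + ".join(f"{float(f):g}*{c}" for c, f in self.clones)


@dataclass(frozen=True)
class ExpectedSignature:
    """Observable fingerprint of a karyotype state: coverage ratio and AF mode set."""

    coverage_ratio: Fraction
    af_modes: tuple[Fraction, ...]


@dataclass
class ChromosomeCall:
    """Per-chromosome inference result with ranked candidates and degeneracy class."""

    chrom: str | None
    observed_ratio: float
    observed_modes: tuple[float, ...]
    fixed_fraction: float | None
    candidates: list[tuple[MixtureState, float]]  # sorted by ascending score
    degeneracy_class: list[MixtureState]
    note: str = ""

    @property
    def best_state(self) -> MixtureState:
        return self.candidates[0][0]

    @property
    def best_score(self) -> float:
        return self.candidates[0][1]


def expected_af(state: MixtureState) -> Fraction:
    """Copy-weighted expected alternative-allele frequency of a mixture.

    Exact rational arithmetic; raises when every clone has zero copies.
    """
    numerator = sum((f * c.a for c, f in state.clones), Fraction(0))
    denominator = state.total_copy_number()
    if denominator == 0:
        raise ValueError("expected_af undefined: all clones have copy number 0")
    return numerator / denominator


def signature(
    state: MixtureState, baseline_ploidy: int = 2, orientation_rule: str = "both"
) -> ExpectedSignature:
    """Expected (coverage ratio, AF mode set) of a state.

    Under the default ``"both"`` orientation rule a heterozygous site's alt
    allele occupies either haplotype role with equal probability, so the mode
    set is {p, 1-p} (deduplicated); ``"fixed"`` keeps only the as-specified
    orientation.
    """
    if baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be >= 1")
    p = expected_af(state)
    if orientation_rule == "both":
        modes = tuple(sorted({p, 1 - p}))
    elif orientation_rule == "fixed":
        modes = (p,)
    else:
        raise ValueError(f"unknown orientation_rule {orientation_rule!r}")
    return ExpectedSignature(
        coverage_ratio=state.total_copy_number() / baseline_ploidy, af_modes=modes
    )


def signatures_equal(
    s1: ExpectedSignature,
    s2: ExpectedSignature,
    tol_modes: float = 1e-9,
    compare_coverage: bool = False,
    tol_ratio: float = 0.05,
) -> bool:
    """Whether two signatures are indistinguishable at the given tolerances.

    Mode sets must have the same cardinality and match pairwise (sorted order)
    within ``tol_modes``; coverage ratios are compared only when
    ``compare_coverage`` is set, reflecting that relative coverage cannot pin
    absolute copy number once the baseline ploidy is itself an assumption.
    """
    if tol_modes <= 0 or tol_ratio <= 0:
        raise ValueError("tolerances must be > 0")
    if len(s1.af_modes) != len(s2.af_modes):
        return False
    for m1, m2 in zip(sorted(s1.af_modes), sorted(s2.af_modes)):
        if abs(float(m1) - float(m2)) > tol_modes:
            return False
    if compare_coverage and abs(float(s1.coverage_ratio) - float(s2.coverage_ratio)) > tol_ratio:
        return False
    return True


def simulate_af_sample(
    state: MixtureState,
    depth_mean: float,
    n_sites: int,
    seed: int | np.random.Generator | None = None,
    min_reads_per_allele: int = 0,
    depth_factor: float = 1.0,
) -> pd.DataFrame:
    """Simulate allelic read counts at heterozygous sites under a karyotype state.

    Per site: total depth ~ Poisson(depth_mean * depth_factor); the allele
    orientation is chosen uniformly between the two orientations of the
    signature; alt reads ~ Binomial(depth, E[AF] of that orientation). Sites
    with zero depth, or failing ``min_reads_per_allele`` on either allele, are
    discarded. Returns a DataFrame with columns ref_depth, alt_depth, af;
    reproducible given a seed.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = float(expected_af(state))
    depth = rng.poisson(depth_mean * depth_factor, size=n_sites)
    p_site = np.where(rng.random(n_sites) < 0.5, p, 1.0 - p)
    alt = rng.binomial(depth, p_site)
    ref = depth - alt
    keep = (depth > 0) & (ref >= min_reads_per_allele) & (alt >= min_reads_per_allele)
    frame = pd.DataFrame(
        {
            "ref_depth": ref[keep].astype(int),
            "alt_depth": alt[keep].astype(int),
        }
    )
    frame["af"] = frame["alt_depth"] / (frame["ref_depth"] + frame["alt_depth"])
    return frame


def enumerate_candidates(
    max_copies: int = DEFAULT_MAX_COPIES,
    max_clones: int = 2,
    fraction_grid: Sequence[object] = (Fraction(1, 2),),
) -> list[MixtureState]:
    """Enumerate the candidate hypothesis space, canonically deduplicated.

    All single clones with 1 <= n <= max_copies and 0 <= a <= n, plus (when
    ``max_clones`` is 2) all two-clone mixtures on the fraction grid. Clone
    order and fraction symmetry never produce duplicates.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    if max_clones not in (1, 2):
        raise ValueError("max_clones must be 1 or 2")
    clone_pool = [
        CloneState(n, a) for n in range(1, max_copies + 1) for a in range(n + 1)
    ]
    states = [MixtureState.single(c.n, c.a) for c in clone_pool]
    seen = {s.clones for s in states}
    if max_clones == 2:
        for frac in fraction_grid:
            f = _as_fraction(frac)
            if not 0 < f < 1:
                raise ValueError("fraction grid values must lie in (0, 1)")
            for i, c1 in enumerate(clone_pool):
                for c2 in clone_pool[i:]:
                    state = MixtureState.of([(c1, f), (c2, 1 - f)])
                    if state.clones not in seen:
                        seen.add(state.clones)
                        states.append(state)
    return states


def _mode_assignment_cost(
    observed: Sequence[float], expected: Sequence[float], unmatched_penalty: float
) -> float:
    """Optimal-assignment sum of squared mode differences, plus a penalty per unmatched mode."""
    n_obs, n_exp = len(observed), len(expected)
    if n_obs == 0 and n_exp == 0:
        return 0.0
    matched_cost = 0.0
    n_matched = 0
    if n_obs and n_exp:
        cost = (np.asarray(observed, float)[:, None] - np.asarray(expected, float)[None, :]) ** 2
        rows, cols = linear_sum_assignment(cost)
        matched_cost = float(cost[rows, cols].sum())
        n_matched = len(rows)
    return matched_cost + unmatched_penalty * (n_obs + n_exp - 2 * n_matched)


def classify_chromosome(
    observed_ratio: float,
    observed_modes: Sequence[float],
    fixed_fraction: float | None,
    candidates: Sequence[MixtureState],
    baseline_ploidy: int = 2,
    w_cov: float = 1.0,
    w_af: float = 1.0,
    unmatched_penalty: float = DEFAULT_UNMATCHED_PENALTY,
    score_tol: float = DEFAULT_SCORE_TOL,
    mode_tol: float = DEFAULT_MODE_TOL,
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    chrom: str | None = None,
) -> ChromosomeCall:
    """Rank candidate karyotype states against observed coverage and AF modes.

    score = w_cov * (ratio difference)^2 + w_af * mode-assignment cost, the
    latter an optimal pairing of observed and expected modes with
    ``unmatched_penalty`` per unpaired mode on either side. A high
    fixed-allele fraction (>= ``fixed_threshold``) restricts candidates to
    loss-of-heterozygosity-compatible states (some orientation with AF 0 or 1).

    The degeneracy class contains every candidate within ``score_tol`` of the
    best score, together with every candidate whose mode signature is
    indistinguishable from the best candidate's within ``mode_tol`` — the
    latter capturing mixtures that coverage alone cannot separate once the
    baseline ploidy is an assumption.
    """
    if observed_ratio < 0:
        raise ValueError("observed_ratio must be >= 0")
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    pool = list(candidates)
    if fixed_fraction is not None and fixed_fraction >= fixed_threshold:
        restricted = [
            c
            for c in pool
            if any(m in (0, 1) for m in signature(c, baseline_ploidy).af_modes)
        ]
        if restricted:
            pool = restricted
    scored: list[tuple[MixtureState, float]] = []
    for cand in pool:
        sig = signature(cand, baseline_ploidy)
        score = w_cov * (observed_ratio - float(sig.coverage_ratio)) ** 2
        score += w_af * _mode_assignment_cost(
            observed_modes, [float(m) for m in sig.af_modes], unmatched_penalty
        )
        if not math.isfinite(score):
            continue
        scored.append((cand, score))
    if not scored:
        raise ValueError("no candidate obtained a finite score")
    # parsimony tie-break: a single clone outranks a mixture with the same score
    scored.sort(key=lambda t: (t[1], len(t[0].clones), str(t[0])))
    best_state, best_score = scored[0]
    best_sig = signature(best_state, baseline_ploidy)
    degenerate = [
        cand
        for cand, score in scored
        if score <= best_score + score_tol
        or signatures_equal(signature(cand, baseline_ploidy), best_sig, tol_modes=mode_tol)
    ]
    return ChromosomeCall(
        chrom=chrom,
        observed_ratio=float(observed_ratio),
        observed_modes=tuple(float(m) for m in observed_modes),
        fixed_fraction=fixed_fraction,
        candidates=scored,
        degeneracy_class=degenerate,
    )


def hdr_all_copy_rate(per_copy_efficiency, copy_number: int):
    """Probability that independent homology-directed repair hits every copy.

    With per-copy efficiency e and copy number n, the all-copy repair rate is
    e ** n — e.g. a 20% assay repairs all copies of a disomic site 4% of the
    time but only 0.8% of the time at a trisomic site, which is why ploidy
    should be checked before designing an editing assay.
    """
    e = per_copy_efficiency
    if not 0 <= e <= 1:
        raise ValueError("per-copy efficiency must lie in [0, 1]")
    if not isinstance(copy_number, (int, np.integer)) or copy_number < 1:
        raise ValueError("copy_number must be an integer >= 1")
    return e ** copy_number
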