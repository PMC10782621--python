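"""Site selection, allele-frequency computation, KDE densities and mode detection."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ploidyscan.allele_frequency import (
    AFDensity,
    compute_af,
    detect_modes,
    estimate_af_density,
    fixed_allele_fraction,
    select_sites_genomic,
    select_sites_rnaseq,
)
from ploidyscan.io_formats import AllelicSite, SampleCall


def site(ga, gb, depths_a=(10, 10), depths_b=(10, 10), pos=100):
    return AllelicSite(
        chrom="1",
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        calls={
            "A": SampleCall(ga, *depths_a),
            "B": SampleCall(gb, *depths_b),
        },
    )


class TestSiteSelection:
    def test_either_policy_includes_both_samples(self):
        s = site("REF/ALT", "REF/REF", depths_b=(25, 1))
        selected = select_sites_genomic([s], ["A", "B"], policy="either")
        assert selected["A"] == [s] and selected["B"] == [s]

    def test_hom_ref_in_both_excluded(self):
        s = site("REF/REF", "REF/REF")
        selected = select_sites_genomic([s], ["A", "B"], policy="either")
        assert selected["A"] == [] and selected["B"] == []

    def test_self_policy_requires_own_het_call(self):
        s = site("REF/ALT", "REF/REF")
        selected = select_sites_genomic([s], ["A", "B"], policy="self")
        assert selected["A"] == [s] and selected["B"] == []

    def test_counts_by_construction(self):
        sites = [site("REF/ALT", "REF/REF", pos=i) for i in range(40)]
        sites += [site("REF/ALT", "REF/ALT", pos=100 + i) for i in range(30)]
        sites += [site("REF/REF", "REF/REF", pos=200 + i) for i in range(30)]
        selected = select_sites_genomic(sites, ["A", "B"], policy="either")
        assert len(selected["A"]) == 70
        assert len(selected["B"]) == 70
        assert len(select_sites_genomic(sites, ["A", "B"], policy="self")["B"]) == 30

    def test_min_reads_per_allele_floor(self):
        s = site("REF/ALT", "REF/REF", depths_b=(25, 0))
        selected = select_sites_genomic([s], ["A", "B"], policy="either", min_reads_per_allele=1)
        assert selected["A"] == [s] and selected["B"] == []

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="policy"):
            select_sites_genomic([], ["A"], policy="both")

    @pytest.mark.parametrize(
        "depths,kept", [((5, 5), True), ((4, 6), False), ((100, 0), False), ((7, 9), True)]
    )
    def test_rnaseq_per_allele_floor(self, depths, kept):
        s = site("REF/ALT", "REF/ALT", depths_a=depths)
        assert (select_sites_rnaseq([s], "A") == [s]) == kept

    def test_rnaseq_min_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_sites_rnaseq([], "A", min_reads_per_allele=0)


class TestComputeAF:
    @pytest.mark.parametrize(
        "depths,expected", [((10, 10), 0.5), ((20, 10), 1 / 3), ((0, 25), 1.0)]
    )
    def test_exact_values(self, depths, expected):
        obs, skipped = compute_af([site("REF/ALT", "REF/ALT", depths_a=depths)], "A")
        assert skipped == 0
        assert obs[0].af == pytest.approx(expected, abs=0)
        assert obs[0].total_depth == sum(depths)

    def test_zero_depth_skipped_and_counted(self):
        sites = [site("REF/ALT", "REF/ALT", depths_a=(0, 0)), site("REF/ALT", "REF/ALT")]
        obs, skipped = compute_af(sites, "A")
        assert len(obs) == 1 and skipped == 1

    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_matches_exact_rational_arithmetic(self, ref, alt):
        if ref + alt == 0:
            alt = 1
        obs, _ = compute_af([site("REF/ALT", "REF/ALT", depths_a=(ref, alt))], "A")
        assert obs[0].af == float(Fraction(alt, ref + alt))


class TestDensityAndModes:
    def test_degenerate_point_mass(self):
        dens = estimate_af_density(np.full(500, 0.5))
        assert dens.modes == (pytest.approx(0.5, abs=0.01),)

    def test_binomial_half_unimodal(self, rng):
        afs = rng.binomial(30, 0.5, 10_000) / 30
        dens = estimate_af_density(afs)
        assert len(dens.modes) == 1
        assert abs(dens.modes[0] - 0.5) < 0.02

    def test_trisomic_pattern_two_modes(self, rng):
        afs = np.concatenate(
            [rng.binomial(30, 1 / 3, 5000) / 30, rng.binomial(30, 2 / 3, 5000) / 30]
        )
        dens = estimate_af_density(afs)
        assert len(dens.modes) == 2
        assert abs(dens.modes[0] - 1 / 3) < 0.03
        assert abs(dens.modes[1] - 2 / 3) < 0.03

    def test_pentasomic_pattern(self, rng):
        afs = np.concatenate(
            [rng.binomial(50, 0.2, 5000) / 50, rng.binomial(50, 0.8, 5000) / 50]
        )
        dens = estimate_af_density(afs)
        assert len(dens.modes) == 2
        assert abs(dens.modes[0] - 0.2) < 0.03
        assert abs(dens.modes[1] - 0.8) < 0.03

    def test_unit_mass_on_interval(self, rng):
        afs = rng.beta(5, 5, 2000)
        dens = estimate_af_density(afs)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=0.01)

    def test_too_few_sites_reports_none(self):
        assert estimate_af_density(np.array([0.5] * 10)) is None

    def test_modes_sorted_increasing(self, rng):
        afs = np.concatenate(
            [rng.binomial(40, 0.25, 4000) / 40, rng.binomial(40, 0.75, 4000) / 40]
        )
        modes = estimate_af_density(afs).modes
        assert list(modes) == sorted(modes)

    def test_mirror_symmetry(self, rng):
        afs = np.concatenate(
            [rng.binomial(40, 0.3, 4000) / 40, rng.binomial(40, 0.7, 2000) / 40]
        )
        modes = estimate_af_density(afs).modes
        mirrored = estimate_af_density(1.0 - afs).modes
        step = 1 / 511
        assert len(modes) == len(mirrored)
        for m, mm in zip(sorted(modes), sorted(1 - np.array(mirrored))):
            assert abs(m - mm) <= step + 1e-12

    def test_mode_count_non_increasing_in_bandwidth(self, rng):
        afs = np.concatenate(
            [rng.binomial(30, 1 / 3, 4000) / 30, rng.binomial(30, 2 / 3, 4000) / 30]
        )
        counts = [
            len(estimate_af_density(afs, bandwidth=h).modes)
            for h in (0.01, 0.02, 0.05, 0.15)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_detect_modes_prominence_threshold(self):
        grid = np.linspace(0, 1, 512)
        # one dominant peak plus a tiny bump below the prominence cut
        density = np.exp(-(((grid - 0.5) / 0.03) ** 2)) + 0.02 * np.exp(
            -(((grid - 0.1) / 0.01) ** 2)
        )
        dens = AFDensity(grid=grid, density=density, bandwidth=0.02)
        assert detect_modes(dens, prominence_fraction=0.1) == [pytest.approx(0.5, abs=0.01)]
        assert len(detect_modes(dens, prominence_fraction=0.001)) == 2


class TestFixedFraction:
    def test_fixed_and_balanced(self):
        assert fixed_allele_fraction([0.0, 1.0, 0.97, 0.02]) == 1.0
        assert fixed_allele_fraction([0.5, 0.4, 0.6]) == 0.0
        assert fixed_allele_fraction([0.0, 0.5]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fixed_allele_fraction([])
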