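"""Expected AF modes, signatures, degeneracy, classification and HDR arithmetic."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ploidyscan.allele_frequency import estimate_af_density
from ploidyscan.ploidy_models import (
    CloneState,
    MixtureState,
    classify_chromosome,
    enumerate_candidates,
    expected_af,
    hdr_all_copy_rate,
    signature,
    signatures_equal,
    simulate_af_sample,
)

HALF = Fraction(1, 2)


def mix(*clones):
    return MixtureState.of([(CloneState(n, a), f) for n, a, f in clones])


class TestCloneAndMixture:
    def test_clone_invariants(self):
        with pytest.raises(ValueError):
            CloneState(2, 3)
        with pytest.raises(ValueError):
            CloneState(-1, 0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            mix((2, 1, HALF), (1, 1, Fraction(1, 4)))

    def test_single_clone_canonical_equality(self):
        assert MixtureState.single(3, 1) == mix((3, 1, HALF), (3, 1, HALF))

    def test_clone_order_symmetry(self):
        assert mix((2, 1, HALF), (1, 1, HALF)) == mix((1, 1, HALF), (2, 1, HALF))


class TestExpectedAF:
    @pytest.mark.parametrize(
        "n,a,expected",
        [(3, 1, Fraction(1, 3)), (5, 1, Fraction(1, 5)), (4, 2, HALF), (2, 1, HALF)],
    )
    def test_single_clone_modes_exact(self, n, a, expected):
        assert expected_af(MixtureState.single(n, a)) == expected

    def test_mixture_weighted_average(self):
        state = mix((2, 1, HALF), (1, 1, HALF))
        assert expected_af(state) == Fraction(2, 3)

    def test_all_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            expected_af(MixtureState.single(0, 0))

    @given(
        st.lists(
            st.tuples(st.integers(1, 6), st.fractions(min_value=0, max_value=1)),
            min_size=1,
            max_size=3,
        )
    )
    def test_complement_property(self, raw):
        clones = []
        for n, frac_a in raw:
            a = round(frac_a * n)
            clones.append(CloneState(n, int(a)))
        f = Fraction(1, len(clones))
        state = MixtureState.of([(c, f) for c in clones])
        assert expected_af(state) + expected_af(state.complement()) == 1


class TestSignature:
    def test_diploid_identity(self):
        sig = signature(MixtureState.single(2, 1), baseline_ploidy=2)
        assert sig.coverage_ratio == 1
        assert sig.af_modes == (HALF,)

    def test_balanced_tetrasomy(self):
        sig = signature(MixtureState.single(4, 2), baseline_ploidy=2)
        assert sig.coverage_ratio == 2
        assert sig.af_modes == (HALF,)

    def test_pentasomy_on_triploid_baseline(self):
        sig = signature(MixtureState.single(5, 1), baseline_ploidy=3)
        assert sig.coverage_ratio == Fraction(5, 3)
        assert sig.af_modes == (Fraction(1, 5), Fraction(4, 5))

    def test_single_clone_mixture_consistency(self):
        clone = MixtureState.single(3, 2)
        redundant = mix((3, 2, Fraction(1, 3)), (3, 2, Fraction(2, 3)))
        assert signature(clone) == signature(redundant)


class TestDegeneracy:
    def test_diploid_monosomic_mixture_mimics_trisomy(self):
        mixture = mix((2, 1, HALF), (1, 1, HALF))
        trisomic = MixtureState.single(3, 1)
        # exact rational identity of the mode sets
        assert signature(mixture).af_modes == signature(trisomic).af_modes
        assert signatures_equal(signature(mixture), signature(trisomic))

    def test_diploid_trisomic_mixture_mimics_pentasomy(self):
        mixture = mix((2, 0, HALF), (3, 1, HALF))
        pentasomic = MixtureState.single(5, 1)
        assert signature(mixture).af_modes == signature(pentasomic).af_modes
        assert signature(mixture).af_modes == (Fraction(1, 5), Fraction(4, 5))
        assert signatures_equal(signature(mixture), signature(pentasomic))

    def test_diploid_differs_from_trisomy(self):
        assert not signatures_equal(
            signature(MixtureState.single(2, 1)), signature(MixtureState.single(3, 1))
        )

    def test_coverage_comparison_separates_when_enabled(self):
        mixture = mix((2, 1, HALF), (1, 1, HALF))
        trisomic = MixtureState.single(3, 1)
        assert not signatures_equal(
            signature(mixture), signature(trisomic), compare_coverage=True, tol_ratio=0.05
        )


class TestSimulateAFSample:
    def test_determinism(self):
        state = MixtureState.single(3, 1)
        a = simulate_af_sample(state, 30, 500, seed=42)
        b = simulate_af_sample(state, 30, 500, seed=42)
        assert a.equals(b)

    def test_diploid_mode_recovery(self):
        frame = simulate_af_sample(MixtureState.single(2, 1), 30, 5000, seed=7)
        modes = estimate_af_density(frame["af"]).modes
        assert len(modes) == 1
        assert abs(modes[0] - 0.5) < 0.02

    def test_pentasomic_mode_recovery(self):
        frame = simulate_af_sample(MixtureState.single(5, 1), 50, 5000, seed=7)
        modes = estimate_af_density(frame["af"]).modes
        assert len(modes) == 2
        assert abs(modes[0] - 0.2) < 0.03
        assert abs(modes[1] - 0.8) < 0.03

    def test_min_reads_filter_applied(self):
        frame = simulate_af_sample(
            MixtureState.single(2, 1), 30, 2000, seed=3, min_reads_per_allele=5
        )
        assert (frame[["ref_depth", "alt_depth"]].min(axis=1) >= 5).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_af_sample(MixtureState.single(2, 1), 0, 100)
        with pytest.raises(ValueError):
            simulate_af_sample(MixtureState.single(2, 1), 30, 0)


class TestEnumerateCandidates:
    def test_single_clone_count(self):
        states = enumerate_candidates(max_copies=3, max_clones=1)
        assert len(states) == 9  # n in 1..3, a in 0..n

    def test_contains_diploid_monosomic_mixture(self):
        states = enumerate_candidates(max_copies=2, max_clones=2, fraction_grid=[HALF])
        assert mix((2, 1, HALF), (1, 1, HALF)) in states

    def test_no_duplicates_under_symmetry(self):
        states = enumerate_candidates(max_copies=4)
        assert len(states) == len(set(states))
        assert mix((2, 1, HALF), (1, 1, HALF)) == mix((1, 1, HALF), (2, 1, HALF))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(fraction_grid=[Fraction(3, 2)])


class TestClassify:
    def test_trisomic_observation(self):
        candidates = enumerate_candidates()
        call = classify_chromosome(1.5, [0.33, 0.67], 0.0, candidates)
        assert MixtureState.single(3, 1) in call.degeneracy_class
        assert float(signature(call.best_state).coverage_ratio) == pytest.approx(1.5)
        # the diploid+monosomic mixture is degenerate with the trisomic call
        assert mix((2, 1, HALF), (1, 1, HALF)) in call.degeneracy_class

    def test_null_diploid_observation(self):
        call = classify_chromosome(1.0, [0.5], 0.0, enumerate_candidates(max_clones=1))
        assert call.best_state == MixtureState.single(2, 1)

    def test_pentasomic_on_triploid_baseline(self):
        call = classify_chromosome(
            5 / 3, [0.2, 0.8], 0.0, enumerate_candidates(max_clones=1), baseline_ploidy=3
        )
        assert call.best_state == MixtureState.single(5, 1)

    def test_fixed_fraction_restricts_to_loh_states(self):
        call = classify_chromosome(0.5, [], 1.0, enumerate_candidates(max_clones=1))
        for state, _ in call.candidates:
            modes = signature(state).af_modes
            assert 0 in modes or 1 in modes
        assert MixtureState.single(1, 1) in call.degeneracy_class

    def test_candidates_sorted_by_score(self):
        call = classify_chromosome(1.5, [0.33, 0.67], 0.0, enumerate_candidates())
        scores = [s for _, s in call.candidates]
        assert scores == sorted(scores)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            classify_chromosome(1.0, [0.5], 0.0, [])

    @pytest.mark.parametrize("n", range(1, 6))
    def test_parameter_recovery_single_clones(self, n):
        """Every single-clone state n<=5 is recovered from its own simulation."""
        candidates = enumerate_candidates()
        for a in range(n + 1):
            state = MixtureState.single(n, a)
            frame = simulate_af_sample(state, 50, 5000, seed=1000 + 10 * n + a)
            afs = frame["af"].to_numpy()
            dens = estimate_af_density(afs)
            modes = dens.modes if dens is not None else ()
            fixed = float(np.mean((afs <= 0.05) | (afs >= 0.95)))
            call = classify_chromosome(n / 2, modes, fixed, candidates)
            assert state in call.degeneracy_class, f"state {state} not recovered"


class TestHdrAllCopyRate:
    def test_printed_rates_exact(self):
        e = Fraction(1, 5)
        assert hdr_all_copy_rate(e, 2) == Fraction(1, 25)  # 4%
        assert hdr_all_copy_rate(e, 3) == Fraction(1, 125)  # 0.8%

    def test_certain_repair(self):
        assert hdr_all_copy_rate(1.0, 7) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hdr_all_copy_rate(1.2, 2)
        with pytest.raises(ValueError):
            hdr_all_copy_rate(0.5, 0)

    @given(st.floats(0.01, 0.99), st.integers(1, 9))
    def test_strictly_decreasing_in_copy_number(self, e, n):
        assert hdr_all_copy_rate(e, n + 1) < hdr_all_copy_rate(e, n)
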