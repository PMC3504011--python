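import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsurveyminer.reference import brute_force_tandem_repeats
from gsurveyminer.tandem_repeat import (
    BUILTIN_PROFILES,
    canonical_rotation,
    find_tandem_repeats,
    perfect_only,
    perfection_filter,
    repeat_density,
)

from conftest import random_dna

MICRO = BUILTIN_PROFILES["mayer_micro"]
MINI = BUILTIN_PROFILES["mayer_mini"]
MONO = BUILTIN_PROFILES["santana_mono"]

REVCOMP = str.maketrans("ACGTN", "TGCAN")


class TestClosedFormExamples:
    def test_perfect_mononucleotide_run(self):
        (m,) = find_tandem_repeats("A" * 30, MONO)
        assert (m.start, m.end, m.unit_length) == (0, 30, 1)
        assert m.score == 29 and m.perfection == 100 and m.motif == "A"

    def test_dinucleotide_min_score_boundary(self):
        (m,) = find_tandem_repeats("AC" * 7, MICRO)
        assert m.score == 12 and (m.start, m.end) == (0, 14)
        assert find_tandem_repeats("AC" * 6, MICRO) == []

    def test_interrupted_homopolymer(self):
        (m,) = find_tandem_repeats("A" * 15 + "G" + "A" * 15, MICRO)
        assert (m.start, m.end) == (0, 31)
        assert (m.n_match, m.n_mismatch, m.score) == (28, 2, 18)
        assert m.perfection == pytest.approx(93.33, abs=0.005)

    def test_smallest_period_wins(self):
        (m,) = find_tandem_repeats("AT" * 20, MICRO)
        assert m.unit_length == 2 and m.motif == "AT"

    @given(
        st.sampled_from(["A", "AC", "ACG", "AATG", "ACGTC", "AACGTG"]),
        st.integers(min_value=3, max_value=40),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_perfect_repeat_scores_region_minus_unit(self, motif, n_units):
        seq = motif * n_units
        u = len(motif)
        matches = find_tandem_repeats(seq, MICRO)
        if len(seq) - u < MICRO.min_score:
            assert matches == []
            return
        (m,) = matches
        assert m.unit_length == u
        assert m.score == m.region_bp - u
        assert m.perfection == 100


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "profile", ["mayer_micro", "mayer_mini", "santana_mono",
                    "santana_2_6", "gardner"]
    )
    def test_matches_brute_force_on_random_sequences(self, profile):
        prof = BUILTIN_PROFILES[profile]
        rng = np.random.default_rng(hash(profile) % 2**31)
        for trial in range(120):
            n = int(rng.integers(20, 201))
            seq = random_dna(rng, n, n_prob=0.03)
            if trial % 2 == 0:  # make repeats likely
                u = int(rng.integers(prof.unit_min, prof.unit_max + 1))
                motif = random_dna(rng, u)
                tract = (motif * (n // max(1, u)))[: int(rng.integers(10, n))]
                pos = int(rng.integers(0, max(1, n - len(tract))))
                seq = (seq[:pos] + tract + seq[pos + len(tract):])[:n]
            fast = [
                (m.start, m.end, m.unit_length, m.score)
                for m in find_tandem_repeats(seq, prof)
            ]
            assert fast == brute_force_tandem_repeats(seq, prof), seq

    def test_reported_matches_never_overlap(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            seq = random_dna(rng, 150)
            ms = find_tandem_repeats(seq, MICRO)
            for a, b in zip(ms, ms[1:]):
                assert a.end <= b.start

    def test_substitution_never_improves_a_perfect_repeat(self):
        rng = np.random.default_rng(5)
        for motif, reps in [("A", 20), ("AG", 10), ("ATC", 8)]:
            seq = motif * reps
            (orig,) = find_tandem_repeats(seq, MICRO)
            pos = int(rng.integers(1, len(seq) - 1))
            other = next(b for b in "ACGT" if b != seq[pos])
            mutated = seq[:pos] + other + seq[pos + 1:]
            hits = find_tandem_repeats(mutated, MICRO)
            best = max((m.score for m in hits), default=0)
            assert best <= orig.score
            assert all(m.perfection <= orig.perfection for m in hits)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            seq = random_dna(rng, 120)
            u = int(rng.integers(1, 7))
            tract = random_dna(rng, u) * 14
            seq = seq[:30] + tract + seq[30 + len(tract):]
            fwd = find_tandem_repeats(seq, MICRO)
            rc = seq.translate(REVCOMP)[::-1]
            rev = find_tandem_repeats(rc, MICRO)
            n = len(seq)
            mirrored = sorted(
                (n - m.end, n - m.start, m.unit_length, m.score) for m in rev
            )
            assert mirrored == [
                (m.start, m.end, m.unit_length, m.score) for m in fwd
            ]


class TestPerfectionFilters:
    def _perfect_and_imperfect(self):
        perfect = find_tandem_repeats("AC" * 10, MICRO)
        imperfect = find_tandem_repeats("A" * 15 + "G" + "A" * 15, MICRO)
        return perfect + imperfect

    def test_perfect_only_drops_interrupted(self):
        ms = self._perfect_and_imperfect()
        kept = perfect_only(ms)
        assert [m.perfection for m in kept] == [100]
        assert perfect_only([]) == []

    def test_threshold_is_inclusive(self):
        ms = self._perfect_and_imperfect()
        assert len(perfection_filter(ms, 95)) == 1  # 93.33 removed
        assert perfection_filter(ms, 93.33) == ms  # boundary kept
        assert perfection_filter(ms, 0) == ms


class TestRepeatDensity:
    def test_bp_per_mbp_and_percent(self):
        ms = find_tandem_repeats("A" * 50 + "C" * 20 + "G" * 50, MONO)
        assert sum(m.region_bp for m in ms) == 120
        d = repeat_density(ms, 1_000_000)
        assert d["bp_per_mbp"] == pytest.approx(120.0)
        assert d["percent_of_sequence"] == pytest.approx(0.012)

    def test_zero_total_bp_errors(self):
        with pytest.raises(ValueError):
            repeat_density([], 0)


class TestProfiles:
    def test_minisatellite_needs_30bp_region(self):
        # 7-mer x 4 = 28 bp, score 21 >= 12 but region < 30
        assert find_tandem_repeats("ACGTGTC" * 4, MINI) == []
        (m,) = find_tandem_repeats("ACGTGTC" * 5, MINI)
        assert m.unit_length == 7 and m.region_bp == 35

    def test_exact_mode_stops_at_interruption(self):
        ms = find_tandem_repeats("A" * 12 + "G" + "A" * 12, MONO)
        assert [(m.start, m.end) for m in ms] == [(0, 12), (13, 25)]

    def test_canonical_rotation(self):
        assert canonical_rotation("GAT") == "ATG"
        assert canonical_rotation("A") == "A"
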