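import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhanseq import (
    KmerList,
    PropertyScale,
    PWM,
    TrapParameters,
    all_kmers,
    dna_property_features,
    gc_content,
    kmer_composition,
    trap_affinity,
    trap_feature_vector,
    trap_mismatch_energy,
)
from enhanseq.sequence_features import reverse_complement

DNA = st.text(alphabet="ACGT", min_size=3, max_size=30)


def brute_force_trap(seq, counts, lam=0.7, pseudo=1.0, r0=None):
    """Independent per-window enumeration of the TRAP occupancy sum."""
    counts = np.asarray(counts, dtype=float)
    W = counts.shape[1]
    if r0 is None:
        r0 = math.exp(0.584 * W - 5.66)
    total = 0.0
    for strand in (seq, reverse_complement(seq)):
        for i in range(len(strand) - W + 1):
            win = strand[i : i + W]
            if any(b not in "ACGT" for b in win):
                continue
            energy = sum(
                (1.0 / lam)
                * math.log(
                    (counts[:, j].max() + pseudo)
                    / (counts["ACGT".index(win[j]), j] + pseudo)
                )
                for j in range(W)
            )
            x = r0 * math.exp(-energy)
            total += x / (1.0 + x)
    return total


@pytest.fixture
def acg_pwm():
    counts = np.zeros((4, 3))
    counts[0, 0] = counts[1, 1] = counts[2, 2] = 8.0
    return PWM("acg", counts)


class TestDnaProperties:
    def table(self, k, default=0.0, **over):
        t = {"".join(p): default for p in itertools.product("ACGT", repeat=k)}
        t.update(over)
        return t

    def test_homopolymer_returns_table_entry(self):
        scale = PropertyScale("tw", 2, self.table(2, AA=3.5))
        assert dna_property_features("AAAA", [scale])[0] == 3.5

    def test_window_average(self):
        scale = PropertyScale("tw", 2, self.table(2, AC=1, CG=2, GT=3))
        assert dna_property_features("ACGT", [scale])[0] == pytest.approx(2.0)

    def test_n_windows_skipped(self):
        scale = PropertyScale("tw", 2, self.table(2, AC=1, CG=2, GT=3))
        assert dna_property_features("ANGT", [scale])[0] == pytest.approx(3.0)

    def test_all_n_yields_zero(self):
        scale = PropertyScale("tw", 2, self.table(2, AA=9.9))
        assert dna_property_features("NNN", [scale])[0] == 0.0

    def test_sequence_shorter_than_k_rejected(self):
        scale = PropertyScale("tw", 3, self.table(3))
        with pytest.raises(ValueError):
            dna_property_features("AC", [scale])

    def test_wrong_table_size_rejected(self):
        with pytest.raises(ValueError):
            PropertyScale("bad", 2, {"AA": 1.0})


class TestMismatchEnergy:
    def test_consensus_energy_zero(self, acg_pwm):
        assert trap_mismatch_energy("ACG", acg_pwm) == pytest.approx(0.0)

    def test_single_mismatch_value(self):
        pwm = PWM("m", np.array([[8.0], [0.0], [0.0], [0.0]]))
        expected = (1 / 0.7) * math.log(9 / 1)
        assert trap_mismatch_energy("C", pwm) == pytest.approx(expected)

    def test_uniform_column_contributes_zero(self):
        pwm = PWM("u", np.full((4, 1), 2.0))
        for base in "ACGT":
            assert trap_mismatch_energy(base, pwm) == pytest.approx(0.0)

    def test_width_mismatch_rejected(self, acg_pwm):
        with pytest.raises(ValueError):
            trap_mismatch_energy("AC", acg_pwm)


class TestTrapAffinity:
    def test_uniform_pwm_closed_form(self):
        pwm = PWM("u", np.full((4, 2), 2.0))
        r0 = TrapParameters().r0(2)
        expected = 2 * (5 - 2 + 1) * r0 / (1 + r0)
        assert trap_affinity("ACGTA", pwm) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_width3(self, acg_pwm):
        seq = "ACGTTACGGT"
        expected = brute_force_trap(seq, acg_pwm.counts)
        assert trap_affinity(seq, acg_pwm) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(DNA)
    def test_reverse_complement_symmetry(self, seq):
        counts = np.zeros((4, 3))
        counts[0, 0] = counts[1, 1] = counts[2, 2] = 8.0
        pwm = PWM("acg", counts)
        a = trap_affinity(seq, pwm)
        b = trap_affinity(reverse_complement(seq), pwm)
        assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(DNA)
    def test_bounds(self, seq):
        counts = np.zeros((4, 3))
        counts[0, 0] = counts[1, 1] = counts[2, 2] = 8.0
        pwm = PWM("acg", counts)
        score = trap_affinity(seq, pwm)
        assert 0 <= score <= 2 * (len(seq) - 3 + 1)

    def test_consensus_window_is_energy_optimal(self, acg_pwm):
        # the occupancy term of any single window is maximal at consensus
        # (energy 0); hence a planted consensus bounds the affinity below
        # by the saturated single-window term
        rng = np.random.default_rng(0)
        r0 = TrapParameters().r0(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 12))
            off = int(rng.integers(0, 10))
            win = seq[off : off + 3]
            assert trap_mismatch_energy(win, acg_pwm) >= 0.0
            planted = seq[:off] + "ACG" + seq[off + 3 :]
            assert trap_affinity(planted, acg_pwm) >= r0 / (1 + r0) - 1e-12

    def test_n_windows_contribute_zero(self, acg_pwm):
        assert trap_affinity("NNNN", acg_pwm) == 0.0
        with_n = trap_affinity("ACGNACG", acg_pwm)
        assert with_n == pytest.approx(brute_force_trap("ACGNACG", acg_pwm.counts), abs=1e-12)

    def test_too_short_sequence_rejected(self, acg_pwm):
        with pytest.raises(ValueError):
            trap_affinity("AC", acg_pwm)


class TestTrapFeatureVector:
    def pwms(self):
        counts = np.zeros((4, 3))
        counts[0, 0] = counts[1, 1] = counts[2, 2] = 8.0
        return [PWM("a", counts), PWM("b", np.full((4, 2), 2.0)), PWM("a2", counts)]

    def test_vector_length_and_duplicates(self):
        v = trap_feature_vector("ACGTACGT", self.pwms())
        assert v.shape == (3,)
        assert v[0] == pytest.approx(v[2])  # identical PWMs -> identical scores

    def test_short_sequence_scores_zero_for_wide_pwm(self):
        wide = PWM("wide", np.full((4, 6), 2.0))
        v = trap_feature_vector("ACG", [wide, self.pwms()[0]])
        assert v[0] == 0.0 and v[1] > 0

    def test_empty_pwm_list_rejected(self):
        with pytest.raises(ValueError):
            trap_feature_vector("ACGT", [])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=16))
    def test_concatenation_monotonicity(self, seq):
        v1 = trap_feature_vector(seq, self.pwms())
        v2 = trap_feature_vector(seq + seq, self.pwms())
        assert (v2 >= v1 - 1e-12).all()


class TestKmers:
    def test_dinucleotide_fractions(self):
        v = kmer_composition("ACGT", KmerList(["AC", "CG", "GT"]))
        assert np.allclose(v, [1 / 3, 1 / 3, 1 / 3])

    def test_overlapping_occurrences(self):
        assert kmer_composition("AAAA", KmerList(["AA"]))[0] == pytest.approx(1.0)

    def test_complete_set_sums_to_one(self):
        for k in (1, 2, 3):
            full = KmerList(
                ["".join(p) for p in itertools.product("ACGT", repeat=k)]
            )
            v = kmer_composition("ACGTTGCAACGT", full)
            assert v.sum() == pytest.approx(1.0)

    def test_n_windows_never_match(self):
        # AA occurs nowhere in "ANAA" except the final window; the N windows
        # cannot match, but they still count in the denominator (3 windows)
        v = kmer_composition("ANAA", KmerList(["AA"]))
        assert v[0] == pytest.approx(1 / 3)

    def test_kmer_list_validation(self):
        with pytest.raises(ValueError):
            KmerList(["AA", "AA"])
        with pytest.raises(ValueError):
            KmerList(["ACGTACG"])  # length 7
        with pytest.raises(ValueError):
            KmerList(["AN"])

    def test_all_kmers_counts(self):
        assert len(all_kmers(3)) == 4 + 16 + 64


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 1.0

    def test_all_n_is_zero(self):
        assert gc_content("NNN") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
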