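"""Constraint scans and simulated-annealing pool generation.

Brute-force oracles: repeat / inverted-repeat lengths by exhaustive substring
enumeration, PWM hits by per-window rescoring.
"""

import math
import random

import numpy as np
import pytest

from guideforge.io import reverse_complement
from guideforge.pool import (
    CAS12A_DIRECT_REPEAT,
    GenerationConstraints,
    KmerIndex,
    assemble_repeat_spacer,
    evaluate_constraints,
    generate_pool,
    kmer_genome_screen,
    max_inverted_repeat_length,
    max_repeat_length,
    scan_disallowed_motifs,
    scan_pwm,
)
from guideforge.fixtures import make_random_genome, make_random_pwm


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_max_repeat(seq):
    best = 0
    n = len(seq)
    for length in range(1, n + 1):
        for i in range(n - length + 1):
            for j in range(i + 1, n - length + 1):
                if seq[i : i + length] == seq[j : j + length]:
                    best = max(best, length)
    return best


def brute_max_inverted(seq):
    best = 0
    n = len(seq)
    for length in range(1, n + 1):
        for i in range(n - length + 1):
            if reverse_complement(seq[i : i + length]) in seq:
                best = max(best, length)
    return best


class TestRepeatScans:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGTACGT", 4), ("ACGT", 0), ("AAAA", 3)],
    )
    def test_max_repeat_known_values(self, seq, expected):
        assert max_repeat_length(seq) == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [("GAATTC", 6), ("AAAA", 0), ("ACGCGT", 6)],
    )
    def test_max_inverted_known_values(self, seq, expected):
        assert max_inverted_repeat_length(seq) == expected

    def test_repeat_matches_enumeration_on_random_sample(self):
        rng = random.Random(42)
        for _ in range(1000):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert max_repeat_length(seq) == brute_max_repeat(seq), seq

    def test_inverted_matches_enumeration_on_random_sample(self):
        rng = random.Random(43)
        for _ in range(300):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert max_inverted_repeat_length(seq) == brute_max_inverted(seq), seq


class TestMotifScan:
    def test_planted_motif(self):
        assert scan_disallowed_motifs("AAGAATTCAA", ["GAATTC"]) == [("GAATTC", 2)]

    def test_absent_motif(self):
        assert scan_disallowed_motifs("AAAAAA", ["GAATTC"]) == []

    def test_minus_strand_occurrence(self):
        # GGATCC's revcomp is itself; use asymmetric motif AACCGG (rc CCGGTT)
        hits = scan_disallowed_motifs("TTCCGGTTTT", ["AACCGG"])
        assert hits == [("AACCGG", 2)]

    def test_palindromic_motif_counted_once(self):
        assert scan_disallowed_motifs("AGAATTCA", ["GAATTC"]) == [("GAATTC", 1)]


class TestPwmScan:
    @staticmethod
    def tata_pwm():
        pwm = np.full((4, 4), 0.0)
        for col, base in enumerate("TATA"):
            pwm["ACGT".index(base), col] = 1.0
        return pwm

    def test_consensus_hit_with_hand_summed_score(self):
        pwm = self.tata_pwm()
        pc = 0.01
        expected = 4 * math.log2((1 + pc) / (1 + 4 * pc) / 0.25)
        hits = scan_pwm("GGTATAGG", pwm, threshold=expected - 1e-9)
        plus = [h for h in hits if h[1] == "+"]
        assert len(plus) == 1
        pos, strand, score = plus[0]
        assert pos == 2
        assert score == pytest.approx(expected)

    def test_no_hits_on_mismatched_sequence(self):
        assert scan_pwm("GGGGGGGG", self.tata_pwm(), threshold=0.1) == []

    def test_revcomp_symmetry(self):
        seq = "GGTATAGGC"
        pwm = make_random_pwm(4, concentration=30, rng_seed=5)
        fwd = scan_pwm(seq, pwm, threshold=2.0)
        rev = scan_pwm(reverse_complement(seq), pwm, threshold=2.0)
        mirrored = sorted(
            (len(seq) - p - pwm.shape[1], "+" if s == "-" else "-", round(sc, 9))
            for p, s, sc in rev
        )
        assert mirrored == sorted((p, s, round(sc, 9)) for p, s, sc in fwd)

    def test_matches_per_window_rescoring(self):
        rng = random.Random(7)
        pwm = make_random_pwm(5, concentration=10, rng_seed=8)
        pc = 0.01
        logodds = np.log2((pwm + pc) / (1 + 4 * pc) / 0.25)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            threshold = rng.uniform(-2, 6)
            expected = []
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for i in range(len(s) - 5 + 1):
                    score = sum(
                        logodds["ACGT".index(s[i + j]), j] for j in range(5)
                    )
                    if score >= threshold:
                        pos = i if strand == "+" else len(seq) - i - 5
                        expected.append((pos, strand, pytest.approx(score)))
            assert scan_pwm(seq, pwm, threshold) == sorted(expected)

    def test_pwm_wider_than_sequence(self):
        assert scan_pwm("ACG", self.tata_pwm(), threshold=-10) == []


class TestKmerScreen:
    def test_planted_identity(self):
        genome = make_random_genome(400, rng_seed=1)
        seq = genome.seq[100:123]
        passed, count = kmer_genome_screen(seq, genome, k=11, max_hits=0)
        assert count >= 1 and not passed

    def test_disjoint_alphabets_pass(self):
        genome = make_random_genome(200, rng_seed=2)
        genome = type(genome)("g", "A" * 200)
        passed, count = kmer_genome_screen("C" * 23, genome, k=8, max_hits=0)
        assert passed and count == 0

    def test_invariant_under_genome_revcomp(self):
        rng = random.Random(9)
        genome = make_random_genome(500, rng_seed=3)
        rc_genome = type(genome)("g_rc", reverse_complement(genome.seq))
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(23))
            _, c1 = kmer_genome_screen(seq, genome, k=8, max_hits=0)
            _, c2 = kmer_genome_screen(seq, rc_genome, k=8, max_hits=0)
            assert c1 == c2


class TestGeneratePool:
    def test_determinism_under_fixed_seed(self):
        c = GenerationConstraints(pool_size=4)
        a = generate_pool(c, 123)
        b = generate_pool(c, 123)
        assert [x.spacer for x in a] == [x.spacer for x in b]
        assert [x.tm for x in a] == [x.tm for x in b]

    def test_degenerate_constraints_fill_pool(self):
        c = GenerationConstraints(
            pool_size=5,
            disallowed_motifs=(),
            tm_tolerance=100.0,
            max_repeat_len=22,
            max_inverted_repeat_len=22,
        )
        pool = generate_pool(c, 5)
        assert len(pool) == 5
        assert all(len(p.spacer) == 23 for p in pool)

    def test_candidates_pass_independent_revalidation(self):
        """Soundness oracle: every emitted candidate passes the scan
        operations under 100 random constraint settings."""
        rng = random.Random(77)
        genome = make_random_genome(800, rng_seed=12)
        for trial in range(100):
            c = GenerationConstraints(
                pool_size=1,
                max_repeat_len=rng.randint(5, 10),
                max_inverted_repeat_len=rng.randint(5, 10),
                disallowed_motifs=("GAATTC", "GGATCC") if rng.random() < 0.5 else (),
                pwms=(make_random_pwm(5, 20, rng.randint(0, 100)),)
                if rng.random() < 0.3
                else (),
                pwm_threshold=6.0,
                screen_genomes=(genome,) if rng.random() < 0.3 else (),
                kmer_k=11,
                tm_target=rng.uniform(58, 70),
                tm_tolerance=rng.uniform(1.5, 4),
            )
            for cand in generate_pool(c, trial):
                report = evaluate_constraints(cand.spacer, c)
                assert all(v["pass"] for v in report.values()), (trial, report)

    def test_spacers_are_distinct(self, small_pool):
        spacers = [c.spacer for c in small_pool]
        assert len(set(spacers)) == len(spacers)

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            GenerationConstraints(max_repeat_len=23, spacer_length=23)


class TestRepeatSpacerAssembly:
    def test_prefix_and_length(self):
        rna = assemble_repeat_spacer("ACGT" * 5 + "ACG")
        assert rna.startswith("UAAUUUCUACUAAGUGUAGAU")
        assert len(rna) == 21 + 23
        assert len(CAS12A_DIRECT_REPEAT) == 21

    def test_transcription_rule(self):
        assert assemble_repeat_spacer("A" * 23).endswith("A" * 23)
        assert assemble_repeat_spacer("T" * 23).endswith("U" * 23)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            assemble_repeat_spacer("ACGT")
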