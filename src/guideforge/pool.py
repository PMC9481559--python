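"""Candidate spacer pool generation by constrained simulated annealing.

Candidates are random DNA spacers optimised until they satisfy every
sequence-composition constraint: bounded direct and inverted repeats, no
disallowed motif on either strand, no transcription-factor PWM hit above a
log-odds threshold, a bounded number of k-mers shared with screening genomes
(a desk-scale stand-in for a BLAST e-value screen), and a melting temperature
within tolerance of the design target.  Accepted spacers are assembled into
full Cas12a repeat-spacer RNAs by prepending the fixed 21-nt direct repeat.

The annealing objective is a weighted penalty, zero iff every constraint
passes:

    (excess repeat length)^2 + (excess inverted-repeat length)^2
    + #motif hits + #PWM hits + max(0, shared k-mers - allowed)
    + (max(0, |Tm - target| - tolerance))^2

with single-base substitution moves, Boltzmann acceptance and geometric
cooling.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord, reverse_complement, transcribe
from .thermo import DEFAULT_CONDITIONS, ThermoConditions, tm_dna_duplex

#: LbCas12a direct repeat (DNA form); transcribed and prepended to every spacer.
CAS12A_DIRECT_REPEAT = "TAATTTCTACTAAGTGTAGAT"

#: Default disallowed motifs: common cloning sites (EcoRI, BamHI, XbaI, BpiI/BbsI).
DEFAULT_DISALLOWED_MOTIFS = ("GAATTC", "GGATCC", "TCTAGA", "GAAGAC")

_BASES = "ACGT"


@dataclass(frozen=True)
class AnnealSchedule:
    initial_temperature: float = 5.0
    cooling: float = 0.95
    steps: int = 4000
    retries: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class GenerationConstraints:
    spacer_length: int = 23
    max_repeat_len: int = 8
    max_inverted_repeat_len: int = 8
    disallowed_motifs: tuple = DEFAULT_DISALLOWED_MOTIFS
    pwms: tuple = ()  # (4, w) column-stochastic arrays
    pwm_threshold: float = 8.0  # bits, log-odds vs uniform background
    screen_genomes: tuple = ()  # SequenceRecords
    kmer_k: int = 11
    max_shared_kmers: int = 0
    tm_target: float = 60.0
    tm_tolerance: float = 2.0
    pool_size: int = 10
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    conditions: ThermoConditions = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if self.spacer_length < 1 or self.pool_size < 1 or self.tm_tolerance < 0:
            raise ValueError("spacer_length, pool_size >= 1 and tm_tolerance >= 0 required")
        if self.max_repeat_len >= self.spacer_length:
            raise ValueError("max_repeat_len must be < spacer_length")
        if self.max_inverted_repeat_len >= self.spacer_length:
            raise ValueError("max_inverted_repeat_len must be < spacer_length")


@dataclass
class CandidateSequence:
    """A spacer plus its repeat-spacer RNA and pipeline annotations."""

    id: str
    spacer: str
    repeat_spacer_rna: str
    tm: float
    constraint_report: dict = field(default_factory=dict)
    offtarget_score: float | None = None
    hybrid_dg: float | None = None
    stage_pass: dict = field(default_factory=dict)
    selected: bool = False


# ---------------------------------------------------------------------------
# Constraint scans


def max_repeat_length(seq: str) -> int:
    """Length of the longest substring occurring at >= 2 distinct (possibly
    overlapping) start positions."""
    n = len(seq)
    for length in range(n - 1, 0, -1):
        seen = set()
        for i in range(n - length + 1):
            sub = seq[i : i + length]
            if sub in seen:
                return length
            seen.add(sub)
    return 0


def max_inverted_repeat_length(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs
    in ``seq`` (occurrences may overlap; palindromes count against
    themselves)."""
    n = len(seq)
    for length in range(n, 0, -1):
        for i in range(n - length + 1):
            if reverse_complement(seq[i : i + length]) in seq:
                return length
    return 0


def scan_disallowed_motifs(seq: str, motifs) -> list[tuple[str, int]]:
    """All occurrences of each motif on both strands, reported in ``seq``
    coordinates as (motif, start); duplicates (palindromes) collapsed."""
    found = set()
    for motif in motifs:
        motif = motif.upper()
        for target in (motif, reverse_complement(motif)):
            start = seq.find(target)
            while start != -1:
                found.add((motif, start))
                start = seq.find(target, start + 1)
    return sorted(found)


def scan_pwm(seq: str, pwm: np.ndarray, threshold: float, pseudocount: float = 0.01):
    """Log-odds PWM scan of both strands against a uniform background.

    The pseudocount is added to each probability before normalisation and the
    log; scores are in bits.  Returns [(position, strand, score)] for windows
    scoring >= threshold, positions in forward coordinates of the window
    start.  A PWM wider than the sequence yields no hits.
    """
    pwm = np.asarray(pwm, dtype=float)
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must sum to 1")
    width = pwm.shape[1]
    if width > len(seq):
        return []
    logodds = np.log2((pwm + pseudocount) / (1.0 + 4.0 * pseudocount) / 0.25)
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - width + 1):
            window = s[i : i + width]
            if "N" in window:
                continue
            score = sum(logodds[index[base], j] for j, base in enumerate(window))
            if score >= threshold:
                pos = i if strand == "+" else len(seq) - i - width
                hits.append((pos, strand, float(score)))
    return sorted(hits)


class KmerIndex:
    """Strand-symmetric set of all k-mers of a genome (k-mers containing N
    are excluded)."""

    def __init__(self, genome: SequenceRecord, k: int):
        self.k = k
        self.genome_id = genome.id
        kmers = set()
        for s in (genome.seq, reverse_complement(genome.seq)):
            for i in range(len(s) - k + 1):
                km = s[i : i + k]
                if "N" not in km:
                    kmers.add(km)
        self._kmers = kmers

    def shared_count(self, seq: str) -> int:
        k = self.k
        return len({seq[i : i + k] for i in range(len(seq) - k + 1)} & self._kmers)


def kmer_genome_screen(seq: str, genome: SequenceRecord | KmerIndex, k: int, max_hits: int):
    """Count distinct k-mers of ``seq`` present in the genome (either strand);
    fail iff count > max_hits.  Returns (passed, count)."""
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    index = genome if isinstance(genome, KmerIndex) else KmerIndex(genome, k)
    count = index.shared_count(seq)
    return count <= max_hits, count


# ---------------------------------------------------------------------------
# Constraint evaluation & annealing


def evaluate_constraints(
    seq: str, constraints: GenerationConstraints, kmer_indexes=None
) -> dict:
    """Per-constraint report: {name: {'pass': bool, 'value': ...}}."""
    c = constraints
    if kmer_indexes is None:
        kmer_indexes = [KmerIndex(g, c.kmer_k) for g in c.screen_genomes]
    rep = max_repeat_length(seq)
    inv = max_inverted_repeat_length(seq)
    motif_hits = scan_disallowed_motifs(seq, c.disallowed_motifs)
    pwm_hits = [h for p in c.pwms for h in scan_pwm(seq, p, c.pwm_threshold)]
    shared = [idx.shared_count(seq) for idx in kmer_indexes]
    tm = tm_dna_duplex(seq, c.conditions)
    return {
        "repeat": {"pass": rep <= c.max_repeat_len, "value": rep},
        "inverted_repeat": {"pass": inv <= c.max_inverted_repeat_len, "value": inv},
        "motifs": {"pass": not motif_hits, "value": motif_hits},
        "pwm": {"pass": not pwm_hits, "value": pwm_hits},
        "kmer_screen": {
            "pass": all(s <= c.max_shared_kmers for s in shared),
            "value": shared,
        },
        "tm": {"pass": abs(tm - c.tm_target) <= c.tm_tolerance, "value": tm},
    }


DEFAULT_PENALTY_WEIGHTS = {
    "repeat": 1.0,
    "inverted_repeat": 1.0,
    "motifs": 1.0,
    "pwm": 1.0,
    "kmer_screen": 1.0,
    "tm": 1.0,
}


def _penalty(seq, constraints, kmer_indexes, weights) -> float:
    c = constraints
    w = weights
    p = 0.0
    p += w["repeat"] * max(0, max_repeat_length(seq) - c.max_repeat_len) ** 2
    p += (
        w["inverted_repeat"]
        * max(0, max_inverted_repeat_length(seq) - c.max_inverted_repeat_len) ** 2
    )
    p += w["motifs"] * len(scan_disallowed_motifs(seq, c.disallowed_motifs))
    p += w["pwm"] * sum(len(scan_pwm(seq, pwm, c.pwm_threshold)) for pwm in c.pwms)
    p += w["kmer_screen"] * sum(
        max(0, idx.shared_count(seq) - c.max_shared_kmers) for idx in kmer_indexes
    )
    excess_tm = max(0.0, abs(tm_dna_duplex(seq, c.conditions) - c.tm_target) - c.tm_tolerance)
    p += w["tm"] * excess_tm**2
    return p


class PoolGenerationError(RuntimeError):
    """Raised when annealing repeatedly fails; names the binding constraint."""


def _anneal_one(constraints, rng, kmer_indexes, weights) -> str | None:
    c = constraints
    seq = "".join(rng.choice(_BASES) for _ in range(c.spacer_length))
    energy = _penalty(seq, c, kmer_indexes, weights)
    temperature = c.anneal.initial_temperature
    for _ in range(c.anneal.steps):
        if energy == 0.0:
            return seq
        pos = rng.randrange(c.spacer_length)
        new_base = rng.choice([b for b in _BASES if b != seq[pos]])
        proposal = seq[:pos] + new_base + seq[pos + 1 :]
        new_energy = _penalty(proposal, c, kmer_indexes, weights)
        delta = new_energy - energy
        if delta <= 0 or rng.random() < math.exp(-delta / max(temperature, 1e-9)):
            seq, energy = proposal, new_energy
        temperature *= c.anneal.cooling
    return seq if energy == 0.0 else None


def generate_pool(
    constraints: GenerationConstraints,
    rng_seed: int,
    penalty_weights: dict | None = None,
) -> list[CandidateSequence]:
    """Generate ``pool_size`` distinct candidates, each passing every
    constraint (deterministic for a fixed seed)."""
    c = constraints
    weights = dict(DEFAULT_PENALTY_WEIGHTS, **(penalty_weights or {}))
    rng = random.Random(rng_seed)
    kmer_indexes = [KmerIndex(g, c.kmer_k) for g in c.screen_genomes]
    pool: list[CandidateSequence] = []
    seen: set[str] = set()
    for n in range(1, c.pool_size + 1):
        spacer = None
        for _ in range(c.anneal.retries):
            result = _anneal_one(c, rng, kmer_indexes, weights)
            if result is not None and result not in seen:
                spacer = result
                break
        if spacer is None:
            report = evaluate_constraints(
                result or "A" * c.spacer_length, c, kmer_indexes
            )
            failing = [k for k, v in report.items() if not v["pass"]] or ["uniqueness"]
            raise PoolGenerationError(
                f"annealing failed for candidate {n} after {c.anneal.retries} "
                f"retries; binding constraint(s): {', '.join(failing)}"
            )
        seen.add(spacer)
        report = evaluate_constraints(spacer, c, kmer_indexes)
        cand = CandidateSequence(
            id=f"g{n}",
            spacer=spacer,
            repeat_spacer_rna=assemble_repeat_spacer(spacer, c.spacer_length),
            tm=report["tm"]["value"],
            constraint_report=report,
            stage_pass={"generation": True},
        )
        pool.append(cand)
    return pool


def assemble_repeat_spacer(spacer: str, spacer_length: int = 23) -> str:
    """RNA form of (fixed LbCas12a direct repeat ++ spacer); length
    21 + spacer_length."""
    spacer = spacer.upper()
    if len(spacer) != spacer_length:
        raise ValueError(f"spacer length {len(spacer)} != {spacer_length}")
    if set(spacer) - set("ACGT"):
        raise ValueError(f"spacer is not plain DNA: {spacer!r}")
    return transcribe(CAS12A_DIRECT_REPEAT + spacer)
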