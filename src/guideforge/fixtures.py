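"""Synthetic test inputs: genomes with planted off-target sites and PWMs.

Everything here is deterministic under a fixed seed and self-validating:
planted genomes are re-scanned after generation and regenerated if the
background happens to contain an accidental PAM-adjacent near-match to any
planted spacer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord, reverse_complement
from .offtarget import (
    DEFAULT_MODEL,
    OffTargetHit,
    OffTargetScoringModel,
    find_offtarget_hits,
    score_hit,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class Plant:
    """One planted protospacer variant.

    ``n_mismatches`` positions (1..23, PAM-proximal first) are mutated unless
    ``mismatch_positions`` pins them explicitly.  ``position`` optionally
    pins the protospacer start on the forward strand.
    """

    spacer: str
    n_mismatches: int = 0
    strand: str = "+"
    position: int | None = None
    mismatch_positions: tuple | None = None
    pam: str = "TTTC"


@dataclass(frozen=True)
class PlantedGenomeSpec:
    length: int
    plants: tuple  # of Plant
    gc_content: float = 0.5
    rng_seed: int = 0


class FixtureError(RuntimeError):
    pass


def _random_background(length: int, gc: float, rng: random.Random) -> list[str]:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choices(_BASES, weights=weights, k=length)


def _mutate(spacer: str, positions, rng: random.Random) -> str:
    out = list(spacer)
    for p in positions:
        out[p - 1] = rng.choice([b for b in _BASES if b != spacer[p - 1]])
    return "".join(out)


def make_planted_genome(
    spec: PlantedGenomeSpec,
    model: OffTargetScoringModel = DEFAULT_MODEL,
    genome_id: str = "synthetic_genome",
    max_regen: int = 20,
) -> tuple[SequenceRecord, list[OffTargetHit]]:
    """Random genome with the requested plants plus the exact expected hit
    list (plants within ``model.max_mismatches`` only).

    The emitted genome is verified with the off-target search itself; on any
    discrepancy (overlapping plants, accidental background hits) the genome
    is regenerated with a fresh sub-seed, up to ``max_regen`` times.
    """
    site_len = len(model.pam) + model.spacer_length
    for plant in spec.plants:
        if len(plant.spacer) != model.spacer_length:
            raise FixtureError(f"plant spacer length != {model.spacer_length}")
    if spec.length < len(spec.plants) * (site_len + 2):
        raise FixtureError("genome too short for the requested plants")

    for attempt in range(max_regen):
        rng = random.Random((spec.rng_seed + 7919 * attempt) % 2**31)
        genome = _random_background(spec.length, spec.gc_content, rng)
        expected: list[OffTargetHit] = []
        used: list[tuple[int, int]] = []
        ok = True
        for plant in spec.plants:
            positions = plant.mismatch_positions
            if positions is None:
                positions = tuple(
                    sorted(rng.sample(range(1, model.spacer_length + 1), plant.n_mismatches))
                )
            proto = _mutate(plant.spacer, positions, rng)
            insert = plant.pam + proto
            if plant.strand == "-":
                insert = reverse_complement(insert)
            start = plant.position
            if start is not None and plant.strand == "+":
                start -= len(plant.pam)  # convert protospacer start to site start
            if start is None:
                for _ in range(200):
                    cand = rng.randrange(0, spec.length - site_len + 1)
                    if all(cand + site_len <= s or cand >= e for s, e in used):
                        start = cand
                        break
                else:
                    ok = False
                    break
            genome[start : start + site_len] = list(insert)
            used.append((start, start + site_len))
            if len(positions) <= model.max_mismatches:
                if plant.strand == "+":
                    proto_start = start + len(plant.pam)
                else:
                    proto_start = start
                hit = OffTargetHit(
                    genome_id=genome_id,
                    position=proto_start,
                    strand=plant.strand,
                    pam_seq=plant.pam,
                    protospacer_seq=proto,
                    mismatch_positions=positions,
                )
                hit.s_hit = score_hit(hit, model)
                expected.append(hit)
        if not ok:
            continue
        record = SequenceRecord(genome_id, "".join(genome))
        if _verify(record, spec, expected, model):
            expected.sort(key=lambda h: (h.position, h.strand))
            return record, expected
    raise FixtureError(f"could not generate a collision-free genome in {max_regen} attempts")


def _verify(record, spec, expected, model) -> bool:
    spacers = {plant.spacer for plant in spec.plants}
    for spacer in spacers:
        found = find_offtarget_hits(spacer, record, model)
        want = sorted(
            (
                (h.position, h.strand, h.mismatch_positions)
                for h in expected
                if _expected_for(h, spacer)
            ),
        )
        got = sorted((h.position, h.strand, h.mismatch_positions) for h in found)
        if want != got:
            return False
    return True


def _expected_for(hit: OffTargetHit, spacer: str) -> bool:
    proto = hit.protospacer_seq
    return all(
        (proto[i] == spacer[i]) == ((i + 1) not in hit.mismatch_positions)
        for i in range(len(spacer))
    )


def write_expected_hits_json(expected, path) -> None:
    """Manifest of a planted genome's expected hits (one object per hit)."""
    import json

    payload = [
        {
            "genome_id": h.genome_id,
            "position": h.position,
            "strand": h.strand,
            "pam": h.pam_seq,
            "protospacer": h.protospacer_seq,
            "mismatch_positions": list(h.mismatch_positions),
            "s_hit": h.s_hit,
        }
        for h in expected
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def make_random_genome(
    length: int, rng_seed: int, gc_content: float = 0.5, genome_id: str = "random_genome"
) -> SequenceRecord:
    """Plain random background genome (no plants)."""
    rng = random.Random(rng_seed)
    return SequenceRecord(genome_id, "".join(_random_background(length, gc_content, rng)))


def make_random_pwm(width: int, concentration: float, rng_seed: int) -> np.ndarray:
    """Column-stochastic (4, width) PWM; higher concentration concentrates
    each column on a random consensus base."""
    if width < 1:
        raise ValueError("width must be >= 1")
    rng = np.random.default_rng(rng_seed)
    cols = []
    for _ in range(width):
        alpha = np.ones(4)
        alpha[rng.integers(0, 4)] += concentration
        cols.append(rng.dirichlet(alpha))
    return np.column_stack(cols)
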