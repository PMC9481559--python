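"""Genome off-target search and scoring for Cas12a guides.

The search enumerates every genomic locus, on both strands, where a window
matches the PAM pattern (5'-TTTN-3' by default) and the immediately
3'-adjacent 23-nt protospacer differs from the spacer at no more than
``max_mismatches`` positions.  Mismatch positions are numbered 1..23 with
position 1 PAM-proximal (the Cas12a seed).

Each hit is scored with a position-weighted scheme: the per-hit score is

    s_hit = prod_{e in M} (1 - W[e]) * 1 / (((22 - dbar)/22) * 4 + 1) * 1 / n_mm^2

where M is the set of mismatch positions, W the 23-entry position weight
vector, dbar the mean pairwise distance between mismatch positions and n_mm
the mismatch count.  Conventions: a perfect hit scores 1; for a single
mismatch dbar is taken as 22 so the distance factor is exactly 1.  The
aggregate guide score over all enumerated hits is

    S_guide = 100 / (100 + sum_i s_hit(h_i))

and guides scoring strictly below the cutoff (default 0.8) are eliminated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .io import SequenceRecord, reverse_complement

#: Position-wise mismatch weights, index 1..23, PAM-proximal first.
DEFAULT_MISMATCH_WEIGHTS = (
    0.63, 0.59, 0.78, 0.70, 0.67, 0.72, 0.61, 0.43, 0.31, 0.23, 0.13, 0.32,
    0.21, 0.0, 0.35, 0.21, 0.08, 0.25, 0.45, 0.38, 0.34, 0.36, 0.0,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class OffTargetScoringModel:
    """Parameters of the off-target search and score."""

    weights: tuple = DEFAULT_MISMATCH_WEIGHTS
    guide_span: int = 22  # constant in the distance factor
    pam: str = "TTTN"
    max_mismatches: int = 7
    cutoff: float = 0.8

    def __post_init__(self) -> None:
        if len(self.weights) != 23:
            raise ValueError("weight vector must have 23 entries")
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")
        if set(self.pam) - set(IUPAC):
            raise ValueError(f"invalid PAM pattern {self.pam!r}")

    @property
    def spacer_length(self) -> int:
        return len(self.weights)


DEFAULT_MODEL = OffTargetScoringModel()


@dataclass
class OffTargetHit:
    """One genomic hit.  ``position`` is the 0-based half-open start of the
    protospacer on the forward strand; for minus-strand hits ``pam_seq`` and
    ``protospacer_seq`` are reported in minus-strand orientation."""

    genome_id: str
    position: int
    strand: str
    pam_seq: str
    protospacer_seq: str
    mismatch_positions: tuple  # sorted, 1 = PAM-proximal
    s_hit: float | None = None

    @property
    def n_mm(self) -> int:
        return len(self.mismatch_positions)

    @property
    def end(self) -> int:
        return self.position + len(self.protospacer_seq)


def pam_matches(pattern: str, window: str) -> bool:
    """IUPAC PAM match; genomic N never matches (N is only a wildcard in the
    pattern, not in the genome)."""
    if len(window) != len(pattern):
        return False
    return all(w in IUPAC[p] for p, w in zip(pattern, window))


from functools import lru_cache


@lru_cache(maxsize=32)
def _pam_positions(seq: str, pam: str, site_len: int) -> tuple:
    """All starts of a PAM window with room for the protospacer; cached so a
    genome is indexed once per PAM even when many spacers are screened."""
    plen = len(pam)
    return tuple(
        i
        for i in range(len(seq) - plen - site_len + 1)
        if pam_matches(pam, seq[i : i + plen])
    )


_rc_cached = lru_cache(maxsize=32)(reverse_complement)


def _scan_strand(spacer: str, seq: str, model: OffTargetScoringModel):
    """Yield (protospacer_start, pam_seq, protospacer, mismatch_positions) on
    one strand given its forward-oriented sequence."""
    plen = len(model.pam)
    slen = len(spacer)
    max_mm = model.max_mismatches
    for i in _pam_positions(seq, model.pam, slen):
        window = seq[i + plen : i + plen + slen]
        if "N" in window:
            continue
        mism = []
        for e in range(slen):
            if window[e] != spacer[e]:
                mism.append(e + 1)
                if len(mism) > max_mm:
                    break
        else:
            yield i + plen, seq[i : i + plen], window, tuple(mism)


def find_offtarget_hits(
    spacer: str,
    genome: SequenceRecord | Iterable[SequenceRecord],
    model: OffTargetScoringModel = DEFAULT_MODEL,
) -> list[OffTargetHit]:
    """All PAM-anchored hits of ``spacer`` in ``genome`` (both strands),
    scored, sorted by (genome_id, position, strand)."""
    spacer = spacer.upper()
    if len(spacer) != model.spacer_length:
        raise ValueError(
            f"spacer length {len(spacer)} != model length {model.spacer_length}"
        )
    records = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    hits: list[OffTargetHit] = []
    for rec in records:
        L = len(rec.seq)
        for start, pam, proto, mism in _scan_strand(spacer, rec.seq, model):
            hits.append(OffTargetHit(rec.id, start, "+", pam, proto, mism))
        rc = _rc_cached(rec.seq)
        for start, pam, proto, mism in _scan_strand(spacer, rc, model):
            hits.append(
                OffTargetHit(rec.id, L - start - len(proto), "-", pam, proto, mism)
            )
    for h in hits:
        h.s_hit = score_hit(h, model)
    hits.sort(key=lambda h: (h.genome_id, h.position, h.strand))
    return hits


def mean_pairwise_distance(positions: Sequence[int], guide_span: int = 22) -> float:
    """Mean |i - j| over all unordered pairs of mismatch positions.

    For fewer than two mismatches the convention returns ``guide_span`` so
    that the distance factor of the per-hit score is exactly 1.
    """
    positions = sorted(set(positions))
    if any(not 1 <= p <= 23 for p in positions):
        raise ValueError(f"mismatch positions out of range 1..23: {positions}")
    if len(positions) < 2:
        return float(guide_span)
    dists = [abs(i - j) for i, j in combinations(positions, 2)]
    return sum(dists) / len(dists)


def score_hit(hit: OffTargetHit, model: OffTargetScoringModel = DEFAULT_MODEL) -> float:
    """Per-hit score in [0, 1]; see module docstring for the formula and the
    n_mm = 0 / n_mm = 1 conventions."""
    n_mm = hit.n_mm
    if n_mm == 0:
        return 1.0
    product = 1.0
    for e in hit.mismatch_positions:
        product *= 1.0 - model.weights[e - 1]
    dbar = mean_pairwise_distance(hit.mismatch_positions, model.guide_span)
    span = model.guide_span
    distance_factor = 1.0 / (((span - dbar) / span) * 4.0 + 1.0)
    return product * distance_factor / (n_mm * n_mm)


def score_guide(
    hits: Iterable[OffTargetHit], model: OffTargetScoringModel = DEFAULT_MODEL
) -> float:
    """Aggregate guide score S_guide = 100 / (100 + sum of per-hit scores),
    summed over all enumerated hits; 1.0 when there are none."""
    total = 0.0
    for h in hits:
        total += h.s_hit if h.s_hit is not None else score_hit(h, model)
    return 100.0 / (100.0 + total)


def filter_by_offtarget_score(candidates, model: OffTargetScoringModel = DEFAULT_MODEL):
    """Partition candidates on S_guide: eliminated iff strictly below the
    cutoff (a candidate at exactly the cutoff is retained).  Candidates must
    already carry ``offtarget_score``.  Returns (retained, eliminated)."""
    retained, eliminated = [], []
    for cand in candidates:
        if cand.offtarget_score is None:
            raise ValueError(f"candidate {cand.id} has no off-target score")
        ok = cand.offtarget_score >= model.cutoff
        cand.stage_pass["offtarget"] = ok
        (retained if ok else eliminated).append(cand)
    return retained, eliminated


# ---------------------------------------------------------------------------
# Hit table output

HIT_COLUMNS = [
    "genome_id", "start", "end", "strand", "pam", "protospacer",
    "mismatch_positions", "n_mm", "d_bar", "s_hit",
]


def write_hits_tsv(hits_by_candidate: dict, path: str | os.PathLike) -> None:
    """Long-format TSV of all hits, keyed by candidate id."""
    with open(path, "w") as fh:
        fh.write("candidate\t" + "\t".join(HIT_COLUMNS) + "\n")
        for cand_id in sorted(hits_by_candidate):
            for h in hits_by_candidate[cand_id]:
                dbar = mean_pairwise_distance(h.mismatch_positions)
                fh.write(
                    "\t".join(
                        [
                            cand_id, h.genome_id, str(h.position), str(h.end),
                            h.strand, h.pam_seq, h.protospacer_seq,
                            ",".join(map(str, h.mismatch_positions)),
                            str(h.n_mm), f"{dbar:.6g}", f"{h.s_hit:.6g}",
                        ]
                    )
                    + "\n"
                )


def write_hits_bed(hits_by_candidate: dict, path: str | os.PathLike) -> None:
    """BED6: name = candidate id, score = round(1000 * s_hit)."""
    with open(path, "w") as fh:
        for cand_id in sorted(hits_by_candidate):
            for h in hits_by_candidate[cand_id]:
                fh.write(
                    f"{h.genome_id}\t{h.position}\t{h.end}\t{cand_id}\t"
                    f"{round(1000 * h.s_hit)}\t{h.strand}\n"
                )
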