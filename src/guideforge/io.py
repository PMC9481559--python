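"""FASTA / PWM / report I/O and the basic sequence record type.

All genomic coordinates emitted anywhere in the package are 0-based,
half-open, with an explicit strand field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA or RNA), upper-cased on construction.

    Genomes may contain ``N`` (which never base-pairs or matches anything);
    candidate pools may not.
    """

    id: str
    seq: str
    alphabet: str = "DNA"  # "DNA" or "RNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = (DNA_ALPHABET if self.alphabet == "DNA" else RNA_ALPHABET) | {"N"}
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_rna(seq: str) -> str:
    return str(Seq(seq).reverse_complement_rna())


def transcribe(seq: str) -> str:
    """DNA coding strand -> RNA (T -> U)."""
    return seq.replace("T", "U")


def read_fasta(path: str | os.PathLike, alphabet: str = "DNA") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved, upper-cased.

    Raises FastaParseError naming the line number for content before the
    first header or for illegal sequence characters.
    """
    allowed = (DNA_ALPHABET if alphabet == "DNA" else RNA_ALPHABET) | {"N"}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise FastaParseError(f"{path}: record {cur_id!r} has no sequence (line {lineno})")
        records.append(SequenceRecord(cur_id, seq, alphabet))

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                if cur_id in seen:
                    raise FastaParseError(f"{path}: duplicate id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
                cur_chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(f"{path}: sequence before first header at line {lineno}")
                chunk = line.upper()
                bad = set(chunk) - allowed
                if bad:
                    raise FastaParseError(
                        f"{path}: illegal characters {sorted(bad)} at line {lineno}"
                    )
                cur_chunks.append(chunk)
        _flush(lineno)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write standard 60-column-wrapped FASTA, one entry per record."""
    bio_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# PWM I/O: whitespace-delimited 4-row (A, C, G, T) count or frequency matrix.

PWM_ROW_ORDER = "ACGT"


def read_pwm(path: str | os.PathLike) -> np.ndarray:
    """Read a 4-row (A,C,G,T) count/frequency matrix; returns a column-stochastic
    (4, width) array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            rows.append([float(x) for x in line.split()])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 rows (A,C,G,T), got {len(rows)}")
    mat = np.asarray(rows, dtype=float)
    if mat.shape[1] < 1 or np.any(mat < 0):
        raise ValueError(f"{path}: PWM must be non-negative with width >= 1")
    return mat / mat.sum(axis=0, keepdims=True)


def write_pwm(pwm: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in np.asarray(pwm, dtype=float):
            fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Stage report.

REPORT_COLUMNS = [
    "id",
    "spacer",
    "tm_c",
    "hybrid_dg_kcal_mol",
    "offtarget_score",
    "generation_pass",
    "offtarget_pass",
    "hybrid_pass",
    "selected",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "pass" if value else "fail"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(candidates, path: str | os.PathLike) -> None:
    """TSV with one row per candidate and one column per pipeline annotation.

    ``candidates`` are CandidateSequence objects (see guideforge.pool); stages
    the candidate never reached are reported as NA.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in candidates:
            row = [
                c.id,
                c.spacer,
                _fmt(c.tm),
                _fmt(c.hybrid_dg),
                _fmt(c.offtarget_score),
                _fmt(c.stage_pass.get("generation")),
                _fmt(c.stage_pass.get("offtarget")),
                _fmt(c.stage_pass.get("hybrid")),
                "yes" if c.selected else "no",
            ]
            fh.write("\t".join(row) + "\n")
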