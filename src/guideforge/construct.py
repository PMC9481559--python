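"""Repressible promoter assembly.

Architecture (left to right on the forward strand):

    [4x UAS block] --36 bp-- [5' binding-site unit] [smCMV core] ... TSS
        --10 bp-- [3' binding-site unit] --spacer-- reporter insertion point

A binding-site unit is the 23-nt gRNA binding site plus its 4-nt TTTN PAM.
The 5' unit abuts the TATAA box directly (0 intervening bases); the 3' unit
sits 10 bp downstream of the TSS and 105 bp downstream of the UAS block.
Distance convention: "X bp downstream of Y" means exactly X bases strictly
between the last base of Y and the first base of the element; these are the
only readings under which the three printed distances are mutually
consistent, implying a TSS 31 nt into the 38-nt smCMV core.

Orientations (the strand carrying 5'-PAM-protospacer-3' per unit):
``outward`` (default) points both protospacers away from the TATA box with
both PAMs smCMV-proximal (5' unit on the minus strand, 3' unit on plus);
``inward`` is the mirror image; ``five_prime``/``three_prime`` point both
sites in the same direction.
"""

from __future__ import annotations

import os
import random
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .io import reverse_complement
from .pool import DEFAULT_DISALLOWED_MOTIFS, scan_disallowed_motifs

#: Super-minimal CMV core promoter; begins with the TATA box.
SMCMV_SEQ = "TATATAAGCAGAGCTCGTTTAGTGAACCGTCAGATCGC"

#: Documented placeholder for the Gal4-responsive 4x UAS operator block
#: (four copies of the 17-bp consensus UAS; synthetic stand-in, the
#: experimental block sequence is user-supplied).
DEFAULT_UAS_BLOCK = "CGGAGTACTGTCCTCCG" * 4

ORIENTATIONS = ("outward", "inward", "five_prime", "three_prime")

# direction of 5'-PAM-protospacer-3' per unit: "left" = minus strand,
# "right" = plus strand
_UNIT_DIRECTIONS = {
    "outward": ("left", "right"),
    "inward": ("right", "left"),
    "five_prime": ("left", "left"),
    "three_prime": ("right", "right"),
}


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class PromoterLayout:
    uas_seq: str = DEFAULT_UAS_BLOCK
    smcmv_seq: str = SMCMV_SEQ
    site_len: int = 23
    pam: str = "TTTC"  # concrete TTTN realisation
    gap_uas_to_5prime_site: int = 36
    dist_uas_to_3prime_site: int = 105
    dist_tss_to_3prime_site: int = 10
    orientation: str = "outward"
    tail_len: int = 10  # filler between the 3' unit and the reporter point

    def __post_init__(self) -> None:
        if not self.smcmv_seq.upper().startswith("TATATAA"):
            raise LayoutError("smCMV sequence must begin with the TATA box (TATATAA)")
        if self.orientation not in ORIENTATIONS:
            raise LayoutError(f"unknown orientation {self.orientation!r}")
        if len(self.pam) != 4 or self.pam[:3] != "TTT":
            raise LayoutError("PAM must be a concrete 4-mer of the form TTTN")

    @property
    def unit_len(self) -> int:
        return self.site_len + len(self.pam)


@dataclass(frozen=True)
class LayoutGeometry:
    tss_offset: int  # 0-based offset of the TSS within smCMV
    unit_len: int
    smcmv_len: int


def validate_layout(layout: PromoterLayout) -> LayoutGeometry:
    """Check that the three inter-element distances are mutually consistent.

    The TSS offset within smCMV implied by the distances is
    dist_uas_to_3prime - dist_tss_to_3prime - 1 - (gap_uas_to_5prime +
    unit_len); it must fall inside the smCMV sequence.
    """
    tss_offset = (
        layout.dist_uas_to_3prime_site
        - layout.dist_tss_to_3prime_site
        - 1
        - (layout.gap_uas_to_5prime_site + layout.unit_len)
    )
    if not 0 <= tss_offset < len(layout.smcmv_seq):
        raise LayoutError(
            f"inconsistent layout distances: implied TSS offset {tss_offset} "
            f"outside [0, {len(layout.smcmv_seq)})"
        )
    return LayoutGeometry(
        tss_offset=tss_offset, unit_len=layout.unit_len, smcmv_len=len(layout.smcmv_seq)
    )


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+', '-' or '.' for strandless anchors
    seq: str  # forward-strand span


@dataclass
class PromoterConstruct:
    construct_id: str
    full_seq: str
    features: dict = field(default_factory=dict)  # name -> Feature

    def feature_seq(self, name: str) -> str:
        f = self.features[name]
        return self.full_seq[f.start : f.end]


def _unit_forward_seq(spacer: str, pam: str, direction: str) -> tuple[str, str]:
    """Forward-strand sequence and strand symbol of a binding-site unit."""
    if direction == "right":
        return pam + spacer, "+"
    return reverse_complement(pam + spacer), "-"


def _random_filler(length: int, rng: random.Random, motifs, retries: int = 50) -> str:
    if length == 0:
        return ""
    for _ in range(retries):
        filler = "".join(rng.choice("ACGT") for _ in range(length))
        if not scan_disallowed_motifs(filler, motifs):
            return filler
    raise RuntimeError(f"could not generate a motif-free filler of length {length}")


def build_repressible_promoter(
    spacer: str,
    layout: PromoterLayout = PromoterLayout(),
    rng_seed: int = 0,
    disallowed_motifs=DEFAULT_DISALLOWED_MOTIFS,
    construct_id: str = "construct",
) -> PromoterConstruct:
    """Assemble the repressible promoter for one spacer.

    Filler between fixed elements is drawn from the seeded RNG and screened
    against the disallowed motifs.  A spacer containing an internal TTTN
    triggers a warning (it would create a spurious PAM).
    """
    spacer = spacer.upper()
    if len(spacer) != layout.site_len:
        raise ValueError(f"spacer length {len(spacer)} != site_len {layout.site_len}")
    geometry = validate_layout(layout)
    if any(spacer[i : i + 3] == "TTT" for i in range(len(spacer) - 3)):
        warnings.warn(
            f"spacer {spacer!r} contains TTTN and may create a spurious internal PAM",
            stacklevel=2,
        )
    rng = random.Random(rng_seed)
    dir5, dir3 = _UNIT_DIRECTIONS[layout.orientation]
    unit5_seq, unit5_strand = _unit_forward_seq(spacer, layout.pam, dir5)
    unit3_seq, unit3_strand = _unit_forward_seq(spacer, layout.pam, dir3)

    uas_end = len(layout.uas_seq)
    unit5_start = uas_end + layout.gap_uas_to_5prime_site
    smcmv_start = unit5_start + geometry.unit_len
    tss_pos = smcmv_start + geometry.tss_offset
    unit3_start = uas_end + layout.dist_uas_to_3prime_site
    smcmv_end = smcmv_start + len(layout.smcmv_seq)
    mid_filler_len = unit3_start - smcmv_end
    if mid_filler_len < 0:
        raise LayoutError("3' unit would overlap smCMV; increase dist_uas_to_3prime_site")

    filler1 = _random_filler(layout.gap_uas_to_5prime_site, rng, disallowed_motifs)
    filler2 = _random_filler(mid_filler_len, rng, disallowed_motifs)
    filler3 = _random_filler(layout.tail_len, rng, disallowed_motifs)

    full_seq = (
        layout.uas_seq + filler1 + unit5_seq + layout.smcmv_seq + filler2
        + unit3_seq + filler3
    )
    unit3_end = unit3_start + geometry.unit_len
    features = {
        "UAS": Feature("UAS", 0, uas_end, "+", layout.uas_seq),
        "five_prime_unit": Feature(
            "five_prime_unit", unit5_start, smcmv_start, unit5_strand, unit5_seq
        ),
        "smCMV": Feature("smCMV", smcmv_start, smcmv_end, "+", layout.smcmv_seq),
        "TSS": Feature("TSS", tss_pos, tss_pos + 1, "+", layout.smcmv_seq[geometry.tss_offset]),
        "three_prime_unit": Feature(
            "three_prime_unit", unit3_start, unit3_end, unit3_strand, unit3_seq
        ),
        "reporter_insertion_point": Feature(
            "reporter_insertion_point", len(full_seq), len(full_seq), ".", ""
        ),
    }
    return PromoterConstruct(construct_id=construct_id, full_seq=full_seq, features=features)


# ---------------------------------------------------------------------------
# Output


def construct_to_seqrecord(construct: PromoterConstruct) -> SeqRecord:
    record = SeqRecord(
        Seq(construct.full_seq),
        id=construct.construct_id,
        name=construct.construct_id[:16],
        description="repressible promoter construct",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    record.annotations["date"] = "01-JAN-1980"  # fixed for byte-identical output
    strand_code = {"+": 1, "-": -1, ".": 0}
    for f in construct.features.values():
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=strand_code[f.strand]),
                type="misc_feature",
                qualifiers={"label": [f.name]},
            )
        )
    return record


def write_genbank(construct: PromoterConstruct, path: str | os.PathLike) -> None:
    """GenBank flat file with annotated features (deterministic output)."""
    with open(path, "w") as fh:
        seqio_write([construct_to_seqrecord(construct)], fh, "genbank")


def write_features_bed(construct: PromoterConstruct, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in construct.features.values():
            strand = f.strand if f.strand in "+-" else "."
            fh.write(
                f"{construct.construct_id}\t{f.start}\t{f.end}\t{f.name}\t0\t{strand}\n"
            )
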