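"""Nearest-neighbor nucleic-acid thermodynamics.

Three duplex chemistries are supported, each backed by a plain-text parameter
table shipped under ``guideforge/data`` (users may substitute their own):

* DNA:DNA  — melting temperature of the spacer duplex (60 degC design target),
  unified parameter set with per-terminal initiation, symmetry and salt
  corrections.
* RNA:DNA  — hybrid free energy of the transcribed spacer against its exact
  DNA complement (the guide:protospacer hybrid screen).
* RNA:RNA  — gapless intermolecular duplex minimum free energy between two
  guide RNAs (the crosstalk screen).  All antiparallel alignment registers are
  scanned; Watson-Crick and G.U stacks are scored; no intramolecular
  structure, bulges or internal loops are modelled.

Energies are reported as Gibbs free energies at 37 degC unless stated
otherwise.  dG = dH - T * dS / 1000 with dH in kcal/mol and dS in cal/(mol K).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .io import RNA_ALPHABET, reverse_complement

R_GAS = 1.987204  # cal / (mol K)
T37_K = 310.15
ZERO_C_K = 273.15

_WC_RNA = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_RNA = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for duplex energetics.

    na_molar: monovalent cation concentration (M); the salt correction adds
    0.368 * (N-1) * ln[Na+] cal/(mol K) to dS.
    strand_conc_molar: total single-strand concentration C_T (M) for Tm.
    temp_c: reporting temperature for dG.
    """

    na_molar: float = 1.0
    strand_conc_molar: float = 0.25e-6
    temp_c: float = 37.0


DEFAULT_CONDITIONS = ThermoConditions()


@dataclass(frozen=True)
class DuplexEnergy:
    """dG (kcal/mol at the reporting temperature), dH (kcal/mol),
    dS (cal/(mol K)) and, where defined, the two-state melting temperature."""

    dg: float
    dh: float
    ds: float
    tm: float | None = None


@dataclass(frozen=True)
class NNParameterTable:
    kind: str  # DNA_DNA | RNA_DNA | RNA_RNA
    stacks: dict  # step -> (dH, dS)
    extras: dict  # init / init_AT / init_GC / sym / wobble -> (dH, dS)
    source: str

    def __post_init__(self) -> None:
        if len(self.stacks) != 16:
            raise ValueError(f"{self.kind}: expected 16 dinucleotide steps, got {len(self.stacks)}")


def _load_table(filename: str, kind: str) -> NNParameterTable:
    stacks: dict = {}
    extras: dict = {}
    source = ""
    text = resources.files("guideforge.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if not source:
                source = line.lstrip("# ")
            continue
        key, dh, ds = line.split("\t")
        (stacks if len(key) == 2 and key.isupper() and key.isalpha() else extras)[key] = (
            float(dh),
            float(ds),
        )
    return NNParameterTable(kind=kind, stacks=stacks, extras=extras, source=source)


@lru_cache(maxsize=None)
def load_nn_table(kind: str) -> NNParameterTable:
    """Load one of the shipped tables: DNA_DNA, RNA_DNA or RNA_RNA."""
    files = {
        "DNA_DNA": "nn_dna_dna.tsv",
        "RNA_DNA": "nn_rna_dna.tsv",
        "RNA_RNA": "nn_rna_rna.tsv",
    }
    return _load_table(files[kind], kind)


def _dg_at(dh: float, ds: float, temp_c: float) -> float:
    return dh - (temp_c + ZERO_C_K) * ds / 1000.0


# ---------------------------------------------------------------------------
# DNA:DNA


def dna_duplex_energy(
    seq: str, conditions: ThermoConditions = DEFAULT_CONDITIONS
) -> DuplexEnergy:
    """Full NN thermodynamics of a perfect DNA duplex given one strand 5'->3'.

    dH/dS are the sums of stack terms plus per-terminal initiation; the
    symmetry correction applies to self-complementary sequences.  Tm follows
    the two-state formula dH*1000 / (dS + R ln(C_T/x)) - 273.15 with x = 4
    (x = 1 for self-complementary duplexes) and the dS salt correction
    0.368 (N-1) ln[Na+].
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("duplex requires length >= 2")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-DNA characters in {seq!r}")
    table = load_nn_table("DNA_DNA")
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = table.stacks[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table.extras["init_GC" if terminal in "GC" else "init_AT"]
        dh += h
        ds += s
    self_complementary = seq == reverse_complement(seq)
    if self_complementary:
        h, s = table.extras["sym"]
        dh += h
        ds += s
    ds_corrected = ds + 0.368 * (len(seq) - 1) * _ln(conditions.na_molar)
    x = 1.0 if self_complementary else 4.0
    tm_k = dh * 1000.0 / (ds_corrected + R_GAS * _ln(conditions.strand_conc_molar / x))
    return DuplexEnergy(
        dg=_dg_at(dh, ds_corrected, conditions.temp_c),
        dh=dh,
        ds=ds_corrected,
        tm=tm_k - ZERO_C_K,
    )


def _ln(x: float) -> float:
    import math

    return math.log(x)


def tm_dna_duplex(seq: str, conditions: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Two-state NN melting temperature (degC) of a perfect DNA duplex."""
    return dna_duplex_energy(seq, conditions).tm


# ---------------------------------------------------------------------------
# RNA:DNA hybrid


def dg_rna_dna_hybrid(
    spacer_rna: str, conditions: ThermoConditions = DEFAULT_CONDITIONS
) -> DuplexEnergy:
    """Free energy of the RNA strand hybridised to its exact DNA complement.

    The hybrid table is asymmetric: the RNA strand is read 5'->3' and each
    step indexes the table directly, so dG(seq) need not equal
    dG(reverse(seq)).
    """
    spacer_rna = spacer_rna.upper()
    if len(spacer_rna) < 2:
        raise ValueError("hybrid requires length >= 2")
    if set(spacer_rna) - RNA_ALPHABET:
        raise ValueError(f"non-RNA characters in {spacer_rna!r}")
    table = load_nn_table("RNA_DNA")
    dh, ds = table.extras["init"]
    for i in range(len(spacer_rna) - 1):
        h, s = table.stacks[spacer_rna[i : i + 2]]
        dh += h
        ds += s
    tm_k = dh * 1000.0 / (ds + R_GAS * _ln(conditions.strand_conc_molar / 4.0))
    return DuplexEnergy(
        dg=_dg_at(dh, ds, conditions.temp_c), dh=dh, ds=ds, tm=tm_k - ZERO_C_K
    )


def filter_by_hybrid_energy(candidates, energy_range, conditions=DEFAULT_CONDITIONS):
    """Partition candidates by hybrid dG of the transcribed spacer.

    Retained iff min <= dG <= max (inclusive both ends).  Every candidate is
    annotated with its dG and a hybrid stage verdict.  Returns
    (retained, rejected).
    """
    lo, hi = energy_range
    if lo > hi:
        raise ValueError(f"invalid energy range [{lo}, {hi}]: min > max")
    retained, rejected = [], []
    for cand in candidates:
        from .io import transcribe

        dg = dg_rna_dna_hybrid(transcribe(cand.spacer), conditions).dg
        cand.hybrid_dg = dg
        ok = lo <= dg <= hi
        cand.stage_pass["hybrid"] = ok
        (retained if ok else rejected).append(cand)
    return retained, rejected


# ---------------------------------------------------------------------------
# RNA:RNA intermolecular duplex (gapless register scan)


def _pairs(x: str, y: str) -> bool:
    return (x, y) in _WC_RNA or (x, y) in _WOBBLE_RNA


def _is_wobble(x: str, y: str) -> bool:
    return (x, y) in _WOBBLE_RNA


def dg_rna_rna_duplex(
    a: str, b: str, conditions: ThermoConditions = DEFAULT_CONDITIONS
) -> DuplexEnergy:
    """Minimum free energy over all gapless antiparallel hybridisation
    registers of ``a`` (5'->3') against ``b`` (5'->3').

    At each register, consecutive positions where both bases pair (WC or G.U)
    contribute one stack term; the sums over all maximal contiguous stacking
    runs plus one duplex initiation give the register energy.  The minimum
    over registers is reported, so the result is the initiation penalty when
    no stabilising duplex exists.  Symmetric in its arguments.
    """
    a, b = a.upper(), b.upper()
    for s in (a, b):
        if set(s) - RNA_ALPHABET:
            raise ValueError(f"non-RNA characters in {s!r}")
    table = load_nn_table("RNA_RNA")
    init_h, init_s = table.extras["init"]
    wob_h, wob_s = table.extras["wobble"]
    rb = b[::-1]  # antiparallel: a[i] faces rb[i - offset]
    best_h, best_s = init_h, init_s
    best_dg = _dg_at(init_h, init_s, conditions.temp_c)
    for offset in range(-(len(b) - 1), len(a)):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        dh, ds = init_h, init_s
        for i in range(lo, hi - 1):
            x1, y1 = a[i], rb[i - offset]
            x2, y2 = a[i + 1], rb[i + 1 - offset]
            if _pairs(x1, y1) and _pairs(x2, y2):
                if _is_wobble(x1, y1) or _is_wobble(x2, y2):
                    dh += wob_h
                    ds += wob_s
                else:
                    h, s = table.stacks[a[i : i + 2]]
                    dh += h
                    ds += s
        dg = _dg_at(dh, ds, conditions.temp_c)
        if dg < best_dg:
            best_dg, best_h, best_s = dg, dh, ds
    return DuplexEnergy(dg=best_dg, dh=best_h, ds=best_s, tm=None)
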