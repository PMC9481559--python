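# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Candidate generation

Spacers are drawn by simulated annealing over single-base substitution moves
(the simplest ergodic move set) with geometric cooling (T0 = 5, factor 0.95,
4000 steps, 25 restarts per candidate). The objective is a weighted penalty,
zero iff every constraint passes:

    (excess repeat length)^2 + (excess inverted-repeat length)^2
    + #motif hits + #PWM hits + max(0, shared k-mers - allowed)
    + (max(0, |Tm - 60| - tolerance))^2

The quadratic terms keep the landscape smooth near feasibility; the counts
are already small integers. Squared-°C units for the Tm term are deliberate:
they dominate when Tm is far off and vanish inside the tolerance band.
Defaults: spacer length 23 nt, repeats and inverted repeats capped at 8 nt
(strictest reading: occurrences may overlap, palindromes count against
themselves, so hairpin-prone sequences are rejected), Tm target 60 °C ± 2 °C.
Random 23-mers average ≈ 74 °C under the shipped DNA/DNA table, so the 60 °C
target drives candidates AT-rich; this is why tolerance below ~1.5 °C slows
convergence noticeably.

Genome similarity is screened by exact shared k-mer counting (k = 11, zero
shared k-mers allowed by default, strand-symmetric). This is a behavioural
stand-in for an alignment e-value screen: it bounds the longest exact match
to the host at k−1 nt but assigns no statistical significance. PWM scanning
uses log-odds in bits against a uniform background with pseudocount 0.01
added to each probability (then renormalised); threshold default 8 bits.
Disallowed motifs default to four common cloning sites (EcoRI, BamHI, XbaI,
BpiI) and are matched exactly on both strands.

Each accepted spacer is re-validated by the independent scan functions
before emission; duplicates are rejected. Candidate pools are therefore
sound by construction, and a property test re-checks this across 100 random
constraint settings.

## Thermodynamics

Three plain-text nearest-neighbor tables ship with the package (sources in
the file headers): DNA/DNA unified parameters (SantaLucia 1998), RNA/DNA
hybrid parameters (Sugimoto 1995) and RNA/RNA Watson–Crick parameters (Xia
1998). ΔG is reported at 37 °C via ΔG = ΔH − T·ΔS/1000; DuplexEnergy keeps
ΔH/ΔS so the identity is exact by construction.

* **DNA Tm** uses the two-state formula ΔH·1000/(ΔS + R ln(C_T/x)) − 273.15
  with x = 4 (x = 1 and a −1.4 cal/(mol·K) symmetry term for
  self-complementary duplexes), per-terminal AT/GC initiation, and the salt
  correction ΔS += 0.368·(N−1)·ln[Na⁺]. Default conditions: 1 M Na⁺ and
  0.25 µM strand concentration (at 1 M the salt term vanishes, which makes
  hand-summation oracles exact). The tables carry all 16 steps explicitly;
  reverse-complement-symmetric steps share values.
* **RNA:DNA hybrids** are directional: the RNA strand is read 5'→3' against
  its exact DNA complement, so ΔG(seq) ≠ ΔG(reverse(seq)) in general.
* **RNA:RNA duplex MFE** is gapless and intermolecular only: all antiparallel
  alignment registers of one guide against the other are scanned; every
  stack between two adjacent paired positions (Watson–Crick or G·U)
  contributes, plus one duplex initiation. Wobble-containing stacks use a
  single averaged parameter rather than per-context values — adequate
  because the crosstalk stage only thresholds the energy. No intramolecular
  structure, bulges, loops or partition functions; energies are therefore
  systematically less negative than a full secondary-structure model for
  pairs whose best duplex needs a bulge. The model is exhaustively
  verifiable: a brute-force register oracle reproduces it exactly for short
  sequences.

All energy/score filters use inclusive bounds; the interaction-graph
thresholds (below) are strict, matching their "above"/"below" definitions.

The hybrid screen has **no default energy range**: the window is a design
choice that depends on the effector and host, so the pipeline refuses to
filter silently and instead skips the stage with a warning when the range is
unset. For 60 °C spacers the observed hybrid ΔG falls around −17 to −23
kcal/mol; the example config uses [−30, −12].

## Off-target search and scoring

The search indexes PAM positions once per genome (cached), then counts
mismatches with early abort; correctness is defined by a naive
position-by-position oracle, and the two agree exactly on randomized and
planted genomes. Genomic N never matches anything (neither PAM nor
protospacer); PAM matching is IUPAC on the pattern side only. Coordinates
are 0-based half-open protospacer starts on the forward strand; minus-strand
hits report PAM/protospacer in minus-strand orientation.

Scoring conventions where the formula is undefined: a perfect hit scores 1
(n_mm = 0 would otherwise divide by zero) and a single mismatch takes
d̄ = 22 so the distance factor is exactly 1. Position 1 is PAM-proximal —
the Cas12a seed — which matches the orientation of the underlying mismatch
tolerance data. The weight vector has 23 entries (positions 14 and 23 have
weight 0, i.e. mismatches there are free) while the distance term keeps the
printed constant 22; both constants are kept exactly as specified. The
aggregate sum runs over *all* enumerated hits: synthetic guides have no
intended genomic target, so there is no on-target exclusion. Elimination is
strict: S_guide = 0.8 exactly is retained.

## Crosstalk and selection

Smith–Waterman (match +2, mismatch −1, linear gap −2; parameters exposed in
config) and longest-common-substring run on the DNA **spacers**, because
every repeat-spacer shares the 21-nt direct repeat and would trivially
exceed any substring threshold; the duplex MFE runs on the full
**repeat-spacer RNAs**, where the shared repeat only matters if it actually
base-pairs. Edges are disjunctive over the three criteria and annotated with
every criterion that fired. Default thresholds (SW > 30, substring > 10 nt,
MFE < −15 kcal/mol) were chosen so that, for default-constraint pools, the
MFE criterion dominates and graphs land at low-to-moderate density; all
three are expected to be tuned per design.

Maximum independent set = maximum clique of the complement graph, enumerated
with Bron–Kerbosch (networkx `find_cliques`). Ties between equal-cardinality
maxima break to the lexicographically smallest id-sorted set, so selection
is deterministic. A 64-node guard aborts cleanly instead of hanging;
realistic pools are far smaller.

## Promoter constructs

Geometry convention: "X bp downstream of Y" = exactly X bases strictly
between the last base of Y and the first base of the element; "directly
adjacent" = 0 bases. Under this convention the three specified distances
(UAS→5' site 36 bp, UAS→3' site 105 bp, TSS→3' site 10 bp, with a
27-bp site+PAM unit) are mutually consistent and imply a TSS 31 nt into the
38-nt smCMV core; `validate_layout` recomputes this offset and rejects
inconsistent layouts. The TSS position is derived from the distance
constraints, not independently known.

Orientation semantics: a binding-site unit is "pointing" in the 5'→3'
direction of the strand carrying PAM-then-protospacer. In the default
`outward` mode both protospacers point away from the TATA box and both PAMs
are smCMV-proximal — the 5' unit sits on the minus strand, the 3' unit on
the plus strand; `inward` is the base-wise reverse complement at identical
coordinates; `five_prime`/`three_prime` point both units the same way.
Orientation changes strand only, never positions, so the printed distances
hold in every mode.

The 4x UAS block ships as a synthetic placeholder (four copies of the 17-bp
Gal4 consensus); real designs should supply their own. Filler between fixed
elements comes from the seeded RNG and is re-drawn (cap 50) if it contains a
disallowed motif; junction-spanning motifs are not re-screened. Spacers
containing TTT raise a warning because they can create a spurious internal
PAM. GenBank output pins the LOCUS date so reruns are byte-identical.

## Synthetic fixtures

Planted genomes are i.i.d. uniform (or GC-biased) backgrounds with
PAM+protospacer variants inserted at non-overlapping positions; mismatch
positions are sampled uniformly (or pinned explicitly). Each emitted genome
is verified against the search itself and regenerated on collision (up to 20
attempts), so the expected hit list is exact by construction. Real genomes
differ in ways the fixtures deliberately ignore — repeat families, GC
isochores, chromatin — so passing tests demonstrate algorithmic
correctness of the search/score/selection machinery, not biological
off-target risk for any real host. Scaling note: the shipped suites use
genomes up to 100 kb and pools of ~20 candidates; all stages are linear in
genome length except the MIS step, which is exponential in pool size but
trivial at these scales.

## Reproducibility

Every stochastic component (annealing, fixtures, construct filler) takes an
explicit seed; stage seeds derive arithmetically from the run seed. Two runs
with the same config and seed produce byte-identical FASTA/TSV/GenBank
outputs, which the acceptance suite asserts via file comparison.
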