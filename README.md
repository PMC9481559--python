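# guideforge

Design of **mutually orthogonal Cas12a gRNA spacers** and their cognate
**repressible synthetic promoters** for CRISPRi circuits in mammalian cells.

Building multi-input synthetic gene circuits needs families of
repressor/promoter pairs that (a) do not bind the host genome, (b) repress
with similar strength, and (c) do not cross-react with one another.
`guideforge` screens candidate 23-nt spacers for catalytically dead LbCas12a
(PAM 5'-TTTN-3') through four computational stages and then drops the
surviving guides into a repressible promoter scaffold:

1. **Pool generation** — constrained simulated annealing produces random
   spacers with bounded direct/inverted repeats, no restriction-site or
   transcription-factor (PWM) motifs, limited k-mer sharing with host
   genomes, and a DNA melting temperature of 60 °C ± tolerance.  Each spacer
   is emitted as a full repeat-spacer (`TAATTTCTACTAAGTGTAGAT` + N23,
   transcribed to RNA).
2. **Off-target screen** — every PAM-anchored genomic locus within
   `max_mismatches` (default 7) of the spacer is enumerated on both strands.
   Each hit *h* is scored

   $$s_\text{hit} = \prod_{e\in\mathcal{M}}(1-W[e]) \times \frac{1}{\frac{22-\bar d}{22}\cdot 4+1} \times \frac{1}{n_{mm}^2}$$

   with $\mathcal{M}$ the mismatch-position set (position 1 PAM-proximal),
   $W$ a fixed 23-entry position weight vector, $\bar d$ the mean pairwise
   mismatch distance and $n_{mm}$ the mismatch count.  The aggregate guide
   score $S_\text{guide} = 100/(100+\sum_i s_\text{hit}(h_i))$ eliminates
   guides scoring below 0.8.
3. **Hybrid-energy screen** — the RNA:DNA free energy of the spacer bound to
   its cognate protospacer (nearest-neighbor model, 37 °C) must fall inside a
   user-specified window, equalising repression strengths.
4. **Orthogonality selection** — all-against-all Smith–Waterman scores,
   longest shared substrings and RNA:RNA duplex MFEs define an interaction
   graph (edge = potential crosstalk); the largest mutually orthogonal set is
   the **maximum independent set**, obtained as the maximum clique of the
   complement graph.

Selected guides are assembled into repressible promoters: a 4x UAS activator
block, two 23-bp binding sites with TTTN PAMs flanking the 38-nt super-minimal
CMV core (`TATATAAGCAGAGCTCGTTTAGTGAACCGTCAGATCGC`), with the printed
36/105/10-bp spacing and four site orientations (outward default).

All coordinates in outputs are 0-based, half-open, with an explicit strand
field.

## Worked example

No downloads needed — the fixtures module fabricates a host genome:

```python
from guideforge.fixtures import make_random_genome
from guideforge.io import write_fasta
write_fasta([make_random_genome(50000, rng_seed=5, genome_id="host")], "genome.fasta")
```

`config.yaml`:

```yaml
rng_seed: 42
genomes:
  - genome.fasta
generation:
  pool_size: 12
  screen_genomes: [genome.fasta]
hybrid:
  energy_range: [-30.0, -12.0]   # kcal/mol, required for the hybrid screen
```

```console
$ guideforge run --config config.yaml --out-dir out
pool=12 selected=7 (g1, g11, g2, g3, g5, g7, g9)
```

The run generated 12 constraint-satisfying spacers, none of which had any
genomic site within 7 mismatches of a TTTN PAM ($S_\text{guide}=1$), all
within the hybrid-energy window; the crosstalk graph had 12 edges (density
0.18, mostly RNA:RNA duplexes more stable than −15 kcal/mol) and its maximum
independent set contains 7 guides. `out/report.tsv` begins:

```
id  spacer                   tm_c     hybrid_dg_kcal_mol  offtarget_score
g1  AAACATTATAATACACTATCACT  60.34    -20.4254            1
g2  TTTTCTAATTCATATTTGAAGGA  61.3355  -17.766             1
g3  AATAACAAACAATATGTATTTGG  60.8599  -20.8842            1
```

(per-row Tm in °C, hybrid ΔG at 37 °C in kcal/mol, aggregate off-target
score).  `out/` also holds the off-target hit table/BED, crosstalk metric and
edge TSVs, the selected-guide FASTA and one annotated GenBank file per
promoter construct under `out/constructs/`.

Stages can be run individually (`guideforge generate|offtarget|hybrid|
crosstalk|select|construct`), each reading a FASTA pool; `--seed` overrides
the config seed.

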