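# lnaclamp

Design toolkit for **LNA-substituted fungal ITS primers** and
**host-blocking LNA clamping oligonucleotides**.

## The problem

Profiling plant-associated fungal communities by ITS metabarcoding is
routinely spoiled by the host: the primer-annealing regions flanking the
fungal ITS (the 3' end of the SSU and 5' end of the LSU rRNA genes) are
nearly identical in plants, so DNA extracted from roots, leaves or tubers
yields mostly host amplicons and the fungal community is underestimated.
`lnaclamp` implements the two coupled countermeasures:

1. **A fungal-specific degenerate forward primer with locked nucleic acid
   (LNA) bases.** From an alignment of target-group sequences the toolkit
   builds a degenerate consensus (IUPAC codes cover minor variants above a
   frequency threshold), finds the columns where the targets are near-fixed
   for a base that every host group lacks, and converts those bases to LNA.
   LNA's 2'-O,4'-C methylene bridge locks the ribose in the 3'-endo
   conformation, raising duplex stability and sharpening single-mismatch
   discrimination exactly at the diagnostic positions.
2. **Host-specific clamping oligonucleotides competing with the reverse
   primer.** For each host sequence type, a 20-25 nt oligo is designed
   complementary to the host template, overlapping the reverse primer's
   3'-terminal annealing bases by one or two positions, with LNA spread
   evenly over the host-specific positions and a 3' phosphate so the
   polymerase cannot extend it.  At a dedicated annealing step (hotter than
   the primers' functional ceiling) only the clamp hybridizes, occupying
   host templates cycle after cycle.

## The Tm model

Both designs hinge on melting temperatures.  The engine uses the unified
DNA/DNA nearest-neighbor model,

  Tm = ΔH° / (ΔS° + 0.368·(N−1)·ln[Na⁺]eq + R·ln(C_T/4)) − 273.15,

with ΔH°, ΔS° summed over base-pair stacks plus duplex-initiation terms.
Each stack adjacent to an LNA base additionally receives a sequence-dependent
(ΔΔH°, ΔΔS°) increment from a shipped, versioned parameter table
(`lnaclamp/data/*.tsv`).  Degenerate oligos are expanded over their IUPAC
variants (cap 256) and reported as median with min/max.  The increment table
and the default conditions (115 mM monovalent, 0.25 µM oligo) are the
package's calibrated parameter set; see `docs/methods.md`.

## Worked example

```
$ python examples/design_host_clamps.py
clamp for host type a (wheat)
  sequence (LNA uppercase): cttaAactcAgcggGtagtccCp
  bases 5'->3'            : CTTAAACTCAGCGGGTAGTCCC
  length / overlap        : 22 nt / 1 base(s) with the reverse primer 3' end
  LNA positions (1-based) : 5,10,15,22
  Tm                      : 68.2 C
  target cross-hits       : 0
...
```

The wheat-type clamp overlaps the reverse primer's 3'-terminal base (the
lowercase leading `c`), carries four LNA bases (uppercase) at the positions
where wheat-type plants differ from the fungal consensus, ends in a
phosphate (`p`), and melts at 68.2 °C — about 7 °C above the amplification
primers (59.4–61.3 °C for the degenerate LNA forward primer), which is what
lets a 68 °C cycle step load the clamp while the primers are inert.  Zero
target cross-hits means no fungal sequence in the alignment is perfectly
complementary to the clamp, so fungal amplification is not collaterally
blocked.

The same pipelines are scriptable from a shell:

```
$ lnaclamp fixtures --seed 7 --out-dir work/
$ lnaclamp design-primer work/forward.fasta --groups work/forward.groups.tsv
$ lnaclamp design-clamp  work/reverse.fasta --groups work/reverse.groups.tsv --anchor 26
$ lnaclamp tm CTYGGTCATTTAGAGGAASTAA --lna 5,20,22
$ lnaclamp protocol --clamp-tm 68.2 --primer-tm-max 61.3
```

## Layout

| Module | Role |
| --- | --- |
| `lnaclamp.alignio` | FASTA/Clustal IO, group sidecars, degapping, windows |
| `lnaclamp.profiling` | column profiles, coverage, discrimination, host typing |
| `lnaclamp.thermo` | LNA-aware nearest-neighbor Tm, clamp-step recommendation |
| `lnaclamp.primer_design` | degenerate consensus + LNA substitution planning |
| `lnaclamp.clamp_design` | clamp candidates, LNA distribution, screening |
| `lnaclamp.protocol` | thermal program, titration series, GC-clamp/DGGE primers |
| `lnaclamp.fixtures` | seeded synthetic alignments for every design stage |
| `lnaclamp.workflows` / `lnaclamp.cli` | end-to-end pipelines and the CLI |
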