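"""Predict oligo Tm values and emit the clamped-PCR program.

Computes the degenerate Tm range of the LNA forward primer and the reverse
primer's Tm, recommends the clamp-annealing temperature for the wheat-type
clamp, and prints the full thermal program and titration series.
"""

from lnaclamp import (
    FixtureSpec,
    Oligo,
    attach_gc_clamp,
    build_clamping_program,
    design_forward_primer,
    design_host_clamps,
    make_forward_fixture,
    make_reverse_fixture,
    tm_oligo,
)
from lnaclamp.fixtures import ITS4

forward = make_forward_fixture(FixtureSpec(seed=7))
primer = design_forward_primer(forward.alignment)
its4_tm = tm_oligo(Oligo("ITS4", ITS4))
print(f"forward LNA primer Tm range: {primer.tm.tm_min:.1f}-{primer.tm.tm_max:.1f} C")
print(f"reverse primer (ITS4) Tm   : {its4_tm.tm:.1f} C")

reverse = make_reverse_fixture(FixtureSpec(seed=7))
wheat = next(d for d in design_host_clamps(reverse.alignment, reverse.anchor_col).values()
             if "wheat" in d.host_type)
program = build_clamping_program((primer.tm, its4_tm), wheat.tm)
print(f"wheat clamp Tm             : {wheat.tm.tm:.1f} C")
print()
print(program.bench_sheet())
print()
dgge = attach_gc_clamp(primer.dna_primer)
print(f"nested DGGE forward primer ({len(dgge.full_sequence)} nt):")
print(dgge.full_sequence)
print("The 40-base GC-rich 5' tail keeps amplicons partially melted on a")
print("denaturing-gradient gel so same-length amplicons separate by sequence.")
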