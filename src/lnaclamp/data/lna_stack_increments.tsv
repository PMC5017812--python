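# LNA modification increments for DNA/DNA nearest-neighbor stacks.
# ddH in kcal/mol, ddS in cal/(mol*K), added to a stack's unified-DNA terms
# whenever at least one of its two bases carries LNA chemistry (applied once
# per stack, also between consecutive LNA bases).
# `stack` is the oligo-strand 5'->3' dinucleotide of the modified stack; the
# table is strand-specific and is NOT expanded by reverse complement.
# These are the package's own calibrated model parameters (not a
# transcription of any published table): magnitudes follow published
# single-substitution LNA duplex thermodynamics (entropy-driven duplex
# stabilization of roughly 0 to -1 kcal/mol ddG37 per modified stack) and
# are anchored, together with the default Conditions, to the four printed
# vendor-calculator reference Tm values (clamping oligos a/b/c and the
# degenerate LNA forward-primer range).
# table_version: 1
stack	dH	dS
AA	0.80	1.81
AC	0.80	4.90
AG	0.80	4.89
AT	0.80	2.83
CA	0.80	4.89
CC	0.80	4.49
CG	0.80	4.70
CT	0.80	4.85
GA	0.80	4.60
GC	0.80	1.45
GG	0.80	4.94
GT	0.80	4.85
TA	0.80	4.50
TC	0.80	5.10
TG	0.80	5.00
TT	0.80	3.20
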