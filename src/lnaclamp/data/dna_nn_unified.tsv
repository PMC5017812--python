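# Unified DNA/DNA nearest-neighbor parameters (SantaLucia 1998, PNAS 95:1460),
# 1 M NaCl reference state.  dH in kcal/mol, dS in cal/(mol*K).
# `stack` is the 5'->3' top-strand dinucleotide; the loader derives the six
# reverse-complement duplicates (TT, TG, AC, AG, TC, CC).
# init_AT / init_GC: duplex initiation with a terminal A:T / G:C pair,
# counted once per end.  sym: symmetry correction for self-complementary
# duplexes.
# table_version: 1
stack	dH	dS
AA	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
init_AT	2.3	4.1
init_GC	0.1	-2.8
sym	0.0	-1.4
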