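"""Design one blocking clamp per host plant type and screen it against fungi.

Builds the synthetic reverse-window alignment (17 host plants in three
sequence types plus 600 fungal rows), partitions hosts into identity types,
designs a 3'-phosphorylated LNA clamp per type overlapping the reverse
primer's 3' end, and screens each clamp for exact fungal complements.
"""

from lnaclamp import FixtureSpec, make_reverse_fixture, design_host_clamps

fixture = make_reverse_fixture(FixtureSpec(seed=7))
clamps = design_host_clamps(fixture.alignment, fixture.anchor_col)

for design in clamps.values():
    print(design.report())
    print()

print("Each clamp melts ~7-10 C above the amplification primers, so a cycle")
print("step at the clamp Tm lets it occupy host templates while the primers")
print("are still non-functional; the 3' phosphate (p) blocks extension.")
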