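"""Design the degenerate LNA forward primer from a labelled alignment.

Builds the synthetic forward-window alignment (600 fungal rows from three
phyla plus three host plants), derives the degenerate consensus over the
fungal rows, finds the fungus/plant discriminating positions, and converts
them to LNA.
"""

from lnaclamp import FixtureSpec, make_forward_fixture, design_forward_primer

fixture = make_forward_fixture(FixtureSpec(seed=7))
result = design_forward_primer(fixture.alignment)

print(result.report())
print()
print("The Y and S codes cover the C minor variants at columns 3 and 19;")
print("the uppercase (LNA) bases sit where fungi carry G/T/A but plants A/C/G,")
print("so a plant template pays both a mismatch and an LNA-sharpened penalty.")
print(f"Discriminating columns: {[s.col for s in result.discriminating]}")
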