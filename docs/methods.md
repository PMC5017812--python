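# Methods

## Scope and model

`lnaclamp` designs two oligonucleotide classes for suppressing host-plant
amplification in fungal ITS metabarcoding: a degenerate, LNA-substituted
forward primer specific to the fungal target groups, and 3'-phosphorylated
LNA clamping oligos that compete with the reverse primer on host templates.
Everything operates on a multiple sequence alignment with group labels
(`target:<phylum>`, `nontarget:<host>`); the toolkit consumes alignments
(CLUSTAL-style input is supported) and never performs alignment or database
retrieval itself.

Coordinates are 1-based, inclusive, and 5'→3' on the stored strand
throughout.  Gap removal is anchored to a designated reference row (a primer
row or chosen sequence): columns gapped in the anchor are dropped and a
column map back to the source coordinates is retained.  Whole-column gap
fraction is deliberately *not* the removal criterion — reported positions
must match primer-anchored counting ("the 5th base from the 5' end").

## Column statistics

Ambiguous residues contribute fractionally and equally to their constituent
bases (R adds ½ to A and ½ to G) rather than being dropped; this keeps the
effective depth of N-rich database columns stable and avoids biasing
consensus calls.  Gaps are excluded from the frequency denominator and
tracked separately.

A column is *discriminating* when one base reaches ≥ `target_purity` (default
0.95) in the targets and every non-target group is ≥ `nontarget_purity`
(default 0.95) for a different base.  The 0.95 defaults quantify "specific
base" conservatively while tolerating the few-percent sequencing noise real
database sets carry; both are configurable.

Primer coverage treats a sequence as matched when at most `max_mismatch`
positions fail IUPAC-set intersection (gaps never match).  The engine is
property-tested against a brute-force per-position matcher.

Percent identity for reporting database matches uses nearest-integer
rounding, half away from zero — the convention consistent with the worked
examples the tests pin (e.g. 204/218 → 94, not 93).

## Degenerate consensus and LNA planning

Per column the consensus emits the IUPAC code covering the modal base plus
every base at frequency ≥ `minor_freq_threshold` (default 0.05: a variant
present in ~5 % of targets costs coverage if ignored, while lower
frequencies are mostly noise; configurable).  A column demanding all four
bases emits N with a logged warning.

LNA goes on discriminating, non-degenerate positions (LNA-on-ambiguity-code
is rejected: the thermodynamic increments for a degenerate LNA stack are
undefined here), ranked by how many non-target groups the base mismatches,
then by 3'-proximity (a 3'-side mismatch is most disruptive to extension),
capped at `max_lna`.  A 3'-terminal LNA is permitted on primers.  The plan
never changes base letters and is idempotent.

## Tm model

Duplex Tm against the perfect DNA complement:

    Tm = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na+]eq + R·ln(CT/4)) − 273.15

with unified DNA/DNA nearest-neighbor ΔH/ΔS sums (1 M NaCl reference state,
initiation terms per terminal pair, symmetry correction and CT divisor 1 for
self-complementary duplexes), the entropic monovalent-salt correction, and
the von Ahsen square-root rule folding any divalent term into [Na+]eq.
DNA-only predictions are cross-checked in the tests against an independent
implementation of the same published parameter set to 1e-6 °C.

**LNA increments.** Every stack adjacent to at least one LNA base receives a
(ΔΔH, ΔΔS) increment keyed by the stack's oligo-strand dinucleotide, applied
once per stack even between consecutive LNA bases (consecutive-LNA effects
are known to be sub-additive).  The shipped table is the package's own
calibrated parameter set, not a transcription of a published table: the
magnitudes follow published single-substitution LNA thermodynamics
(entropy-driven stabilization of roughly 0 to −1 kcal/mol ΔΔG37 per
modified stack, pyrimidine contexts stabilizing more than purine contexts),
and the free entries were fitted once, by least squares, so that the model
at the default conditions reproduces four published reference values
produced by a vendor calculator whose model is undisclosed: the three
clamping-oligo Tm values (68/72/69 °C) and the degenerate LNA forward
primer's range (59–62 °C).  The default `Conditions` (115 mM monovalent,
0 divalent, 0.25 µM total oligo) are frozen as part of that calibration.
Agreement within ±2 °C of those anchors is the verification contract;
exact equality with any particular vendor tool is not claimed.  The
reverse primer's published *functional* annealing estimate (~60 °C, a
gel-intensity readout) is about 4 °C above this duplex-model prediction and
was deliberately not force-fitted.

Degenerate oligos are expanded over all IUPAC variants (hard cap 256, with
an explicit resolve-first error beyond it); the headline `tm` is the median
(robust to a single hot expansion), with min/max always surfaced.  Oligos
under 8 nt are rejected as outside nearest-neighbor validity.

**Clamp-step recommendation.** The clamp-annealing temperature is
max(highest primer tm_max + `primer_ceiling_offset`, clamp Tm rounded to the
nearest degree), infeasible if that exceeds clamp Tm + 1 °C or if the clamp
is not hotter than the primers.  The default offset of 4 °C reflects that
primers remain partially functional a few degrees above their predicted Tm.

## Clamp design

Candidates are enumerated over overlap v ∈ {1, 2} with the reverse primer's
3'-terminal annealing bases and length L ∈ [20, 25] (bracketing practical
clamp synthesis lengths).  The clamp is represented on the same annealing
sense as the reverse primer: written 5'→3' it is the reverse complement of
the stored-strand window `anchor−(L−v) … anchor+v−1`, so the overlap bases
are its 5' end and the 3' phosphate points into the extension side.

LNA is placed on **all** host-specific positions (host base conflicting with
a ≥ 0.95-pure target base), excluding the overlap bases, thinned to
`max_lna` by maximizing the minimal pairwise spacing ("equal distribution",
verified in tests by exhaustive enumeration).  An alternative rule — adding
LNA only until the Tm window is reached — was considered and rejected: it
pins every clamp to the lower edge of the Tm window, erasing the real
between-host Tm differences, and leaves host-specific positions unguarded;
full substitution maximizes host discrimination, which is the clamp's job.
Designs with fewer than two host-specific positions are refused.

Among candidates whose Tm lies within `tm_target ± tm_tolerance` (defaults
70 ± 2 °C: high enough that the amplification primers are non-functional at
the clamp step, low enough that clamp hybridization stays efficient), the
winner maximizes, in order:

1. **host-specific position density** (LNA count / length) — padding a clamp
   with fungus-matching bases makes it a better fungal clamp, which is
   exactly the cross-reactivity one is trying to avoid;
2. **overlap depth** — a deeper overlap occludes the primer's 3' terminus
   more directly, the competitive mechanism of clamping;
3. closeness of Tm to the target; 4. shortness.

Infeasible runs raise an error listing the best near-misses.

Cross-reactivity screening counts target records whose (gap-stripped)
window over the clamp's columns is exactly complementary to the clamp in
either orientation.  This full-length, zero-mismatch criterion stands in
for a live database identity search; partial-identity screening is out of
scope.  Non-zero counts are reported as warnings, not failures — a handful
of perfectly matching targets among hundreds is acceptable collateral.

## Protocol emission

The clamped-PCR program inserts the clamp-annealing step between
denaturation and primer annealing in each of 40 cycles (94 °C 3 min; ×40:
94 °C 1 min, clamp step 1 min, 54 °C 1 min, 72 °C 2 min; 72 °C 10 min),
with 0.8 µM primers and a clamp titration of 0/0.5/1/2/3/4 µM (optionally
6/8 µM) — the effective clamp concentration is an empirical property of the
sample's host/fungus DNA ratio.  Only the clamp-step temperature is
computed; everything else is an overridable default.  Programs serialize
losslessly to YAML and TSV.  For DGGE, `attach_gc_clamp` records the
40-base GC-rich 5' extension on the forward primer and the nested pairing
with the internal reverse primer is emitted as a note (round-1 product
diluted 10³–10⁴-fold).  Ramp rates and lid temperatures are not modelled.

## Synthetic fixtures

The generators reproduce the *structure* of the two design alignments, not
their scale: 200 rows per target phylum by default (the real sets run to
thousands; extra rows only tighten frequencies already controlled exactly),
with per-row substitution noise at 2 % — enough to exercise the purity
thresholds, low enough not to create spurious degeneracies.

* Forward window (22 columns): fungal rows follow the canonical forward
  annealing sequence with a C minor variant at columns 3 and 19 (35 % of
  the first phylum's rows, assigned by exact count so empirical frequencies
  track the spec within sampling noise); plant rows differ exactly at
  columns 5/20/22 (G/T/A vs A/C/G).
* Reverse window (48 columns, anchor at column 26): three host sequence
  types whose windows are exactly complementary to the three reference
  clamps, 17 representative plants distributed over the types, the shared
  reverse-primer annealing region, and fungal rows differing from every
  host at ≥ 3 clamp-window positions (4–5 host-specific positions per
  type).  The extension-side flank is fungal-identical A/T-rich sequence —
  a design choice reflecting that the ITS2-side flank carries no
  plant-specific signal — and an optional planted fungal row identical to
  the wheat window exercises the cross-reactivity screen.
* An optional "protozoa-like" outgroup (default off) provides
  coverage-contrast material.

What passing tests on these fixtures do **not** show: performance on real
database alignments with indels inside the windows, ITS length variation
(~400–900 bp), chimeras, or phylogenetically structured variation; the
fixtures make the minor-variant and discrimination structure exact rather
than estimated.  Wet-lab outcomes (gel intensities, DGGE patterns, live
database hit counts) are out of scope entirely.

## Numerical and degenerate-input choices

* Expansion cap 256 with an explicit error; median as headline Tm.
* `spread_positions` ties break by larger total spread, then
  lexicographically smallest set — deterministic under re-runs.
* Host identity types are labelled a, b, c… in order of first appearance.
* Same config + same seed ⇒ byte-identical CLI reports; runs log the seed
  and a hash of the effective configuration.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`.

## Known limitations

* The LNA increment table is calibrated to four anchor values; absolute
  accuracy outside 20–25-mers at moderate salt is unverified (mismatch and
  Mg²⁺-dependent corrections beyond the square-root rule, hairpin/dimer
  structure, and duplex-hybrid ΔTm prediction are non-goals).
* Exact-match screening misses near-complementary targets.
* Clamp enumeration assumes a gapless host window over the candidate span.
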