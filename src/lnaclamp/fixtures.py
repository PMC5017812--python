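"""Seeded synthetic alignments with the structure of the two design figures.

The real designs were made on database alignments (thousands of fungal SSU/
LSU flanks plus representative host plants).  These generators produce
reduced-scale alignments with the same *statistical* structure -- the
consensus, the minor-variant columns that earn degeneracy codes, the
fungus/plant discriminating positions, and the three host sequence types
complementary to the printed clamping oligos -- so every design stage is
testable without downloads.

Forward fixture (ITS1F window, 22 columns): fungal rows follow the ITS1F
annealing region with a C minor variant at columns 3 and 19 (the columns
degenerated to Y and S) and fixed G/T/A at columns 5/20/22, where plant rows
carry A/C/G.

Reverse fixture (ITS4-competition window): three host plant types whose
stored-strand windows are exactly complementary to the printed clamping
oligos a/b/c, the reverse-primer annealing region shared by all rows, and
fungal rows differing from every host type at >= 3 positions inside the
clamp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np

from .alignio import Alignment, SequenceRecord
from .errors import ValidationError
from .oligo import normalize_residues, reverse_complement

# Published primer and clamp sequences the fixtures are organized around.
ITS1F = "CTTGGTCATTTAGAGGAAGTAA"
ITS4 = "TCCTCCGCTTATTGATATGC"
CLAMP_A = "CTTAAACTCAGCGGGTAGTCCC"  # wheat type
CLAMP_B = "CTTAAACTCAGCGGGTAGCCCC"  # soybean type
CLAMP_C = "GCTTAAACTCAGCGGGTAATCCC"  # potato type (two-base overlap)

PHYLA = ("Ascomycota", "Basidiomycota", "Glomeromycota")

#: Representative plants per reverse-window sequence type.
HOST_TYPE_MEMBERS = {
    "wheat": ("wheat", "rice", "maize", "melon", "carrot"),
    "soybean": ("soybean", "spinach", "peanut", "banana"),
    "potato": (
        "potato",
        "thale_cress",
        "tomato",
        "sweet_potato",
        "coffee",
        "orange",
        "cotton",
        "jute",
    ),
}

# Forward window: plant rows differ from fungi exactly at the three
# discriminating positions 5 (G->A), 20 (T->C) and 22 (A->G).
_FWD_PLANT = "CTTGATCATTTAGAGGAAGCAG"

# Reverse window geometry: 4-column extension-side flank, the 22-column
# wheat-clamp window, the reverse-primer annealing region, 3-column tail.
_REV_FLANK_LEFT = "TATA"
_REV_FLANK_RIGHT = "ATT"
REVERSE_ANCHOR = len(_REV_FLANK_LEFT) + len(CLAMP_A)  # 3' terminus of ITS4

# Stored-strand columns where the fungal consensus departs from every host
# (complementary to clamp-a positions 22/15/10/5), and the bases there.
_FUNGAL_SPECIFIC = {5: "A", 12: "T", 17: "G", 22: "C"}


def _reverse_host_row(clamp: str, overlap: int) -> str:
    """Stored-strand host window complementary to a printed clamp."""
    core = reverse_complement(clamp)
    its4_rc = reverse_complement(ITS4)
    lead = REVERSE_ANCHOR - (len(clamp) - overlap) - 1
    row = _REV_FLANK_LEFT[:lead] + core + its4_rc[overlap:] + _REV_FLANK_RIGHT
    assert len(_REV_FLANK_LEFT) == lead, "clamp window must start at column 5"
    assert core[-overlap:] == its4_rc[:overlap], "clamp/primer overlap mismatch"
    return row


def _default_host_rows() -> dict[str, str]:
    return {
        "wheat": _reverse_host_row(CLAMP_A, 1),
        "soybean": _reverse_host_row(CLAMP_B, 1),
        "potato": _reverse_host_row(CLAMP_C, 2),
    }


def _fungal_reverse_consensus() -> str:
    row = list(_default_host_rows()["wheat"])
    for col, base in _FUNGAL_SPECIFIC.items():
        row[col - 1] = base
    return "".join(row)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic alignment generators (seed fixes everything).

    ``minor_variant_freqs`` maps a forward-window column to the minor base
    and its within-Ascomycota frequency; minor-base carriers are assigned by
    exact count (round(freq * n)) so empirical frequencies track the spec
    tightly, then per-base substitution noise is overlaid at ``noise_rate``.
    """

    seed: int = 7
    n_per_phylum: tuple[int, int, int] = (200, 200, 200)
    minor_variant_freqs: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: {3: ("C", 0.35), 19: ("C", 0.35)}
    )
    host_types: Mapping[str, str] | None = None
    n_outgroup: int = 0
    window_lengths: tuple[int, int] = (len(ITS1F), len(_reverse_host_row(CLAMP_A, 1)))
    noise_rate: float = 0.02
    planted_match: bool = False

    def __post_init__(self) -> None:
        if len(self.n_per_phylum) != len(PHYLA) or any(n < 1 for n in self.n_per_phylum):
            raise ValidationError("n_per_phylum must give a positive count per phylum")
        for col, (base, freq) in self.minor_variant_freqs.items():
            if base not in "ACGT" or not 0.0 < freq < 1.0:
                raise ValidationError(
                    f"minor variant at column {col}: base must be plain and "
                    "frequency in (0, 1)"
                )
            if not 1 <= col <= self.window_lengths[0]:
                raise ValidationError(f"minor-variant column {col} outside the window")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValidationError("noise_rate must lie in [0, 0.5)")
        if self.n_outgroup < 0:
            raise ValidationError("n_outgroup may not be negative")
        if self.host_types is not None:
            for label, seq in self.host_types.items():
                normalize_residues(seq, where=f"host type {label!r}")


class Fixture(NamedTuple):
    alignment: Alignment
    group_map: dict[str, str]
    anchor_col: int | None = None


def _noise(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(chars)) < rate
    for i in np.nonzero(hit)[0]:
        current = chars[i].decode()
        chars[i] = rng.choice([b for b in "ACGT" if b != current]).encode()
    return b"".join(chars).decode()


def make_forward_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Fungal + plant alignment over the forward-primer window."""
    rng = np.random.default_rng(spec.seed)
    width = spec.window_lengths[0]
    consensus = ITS1F[:width]
    records: list[SequenceRecord] = []

    for phylum, n in zip(PHYLA, spec.n_per_phylum):
        rows = [list(consensus) for _ in range(n)]
        if phylum == "Ascomycota":
            for col, (base, freq) in spec.minor_variant_freqs.items():
                k = round(freq * n)
                for i in rng.permutation(n)[:k]:
                    rows[i][col - 1] = base
        for i, row in enumerate(rows, start=1):
            seq = _noise(rng, "".join(row), spec.noise_rate)
            records.append(
                SequenceRecord(
                    id=f"{phylum[:4]}_{i:04d}", residues=seq, group=f"target:{phylum}"
                )
            )

    for plant in ("wheat", "soybean", "potato"):
        records.append(
            SequenceRecord(id=plant, residues=_FWD_PLANT[:width], group=f"nontarget:{plant}")
        )

    if spec.n_outgroup:
        out = list(consensus)
        out[8] = "C" if out[8] != "C" else "A"
        out[13] = "T" if out[13] != "T" else "G"
        for i in range(1, spec.n_outgroup + 1):
            seq = _noise(rng, "".join(out), spec.noise_rate)
            records.append(
                SequenceRecord(id=f"Prot_{i:04d}", residues=seq, group="outgroup:protozoa")
            )

    aln = Alignment(tuple(records))
    return Fixture(aln, {r.id: r.group for r in records}, None)


def make_reverse_fixture(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Host-type + fungal alignment over the reverse (clamp) window.

    The returned ``anchor_col`` is the stored-strand column facing the
    reverse primer's 3' terminus (the overlap pivot for clamp design).
    """
    rng = np.random.default_rng(spec.seed + 1)
    hosts = dict(spec.host_types) if spec.host_types is not None else _default_host_rows()
    widths = {len(s) for s in hosts.values()}
    if len(widths) != 1:
        raise ValidationError("host type windows must share one length")
    width = widths.pop()

    records: list[SequenceRecord] = []
    for type_label, seq in hosts.items():
        members = HOST_TYPE_MEMBERS.get(type_label, (type_label,))
        for plant in members:
            records.append(
                SequenceRecord(id=plant, residues=seq, group=f"nontarget:{plant}")
            )

    consensus = _fungal_reverse_consensus()
    if len(consensus) != width:
        raise ValidationError(
            "custom host windows must match the built-in fungal window length"
        )
    for phylum, n in zip(PHYLA, spec.n_per_phylum):
        for i in range(1, n + 1):
            seq = _noise(rng, consensus, spec.noise_rate)
            records.append(
                SequenceRecord(
                    id=f"{phylum[:4]}_{i:04d}", residues=seq, group=f"target:{phylum}"
                )
            )

    if spec.planted_match:
        records.append(
            SequenceRecord(
                id="Asco_planted",
                residues=_default_host_rows()["wheat"],
                group="target:Ascomycota",
            )
        )

    aln = Alignment(tuple(records))
    return Fixture(aln, {r.id: r.group for r in records}, REVERSE_ANCHOR)
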