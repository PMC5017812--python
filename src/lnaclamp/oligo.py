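"""Oligonucleotide model: IUPAC alphabet helpers and the `Oligo` container.

An `Oligo` is a 5'->3' base string carrying a parallel per-position chemistry
vector (plain DNA or locked nucleic acid, LNA) plus optional end
modifications: a 3' phosphate (turning the oligo into a non-extendable PCR
clamp) and a 5' extension such as a GC clamp for DGGE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .errors import ValidationError

#: IUPAC one-letter code -> set of plain bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: frozenset of bases -> IUPAC code.
SETS_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

GAP = "-"
ALPHABET = frozenset(IUPAC_SETS) | {GAP}

DNA = "DNA"
LNA = "LNA"


def normalize_residues(raw: str, *, where: str = "sequence") -> str:
    """Uppercase, map RNA U to T, and validate against the IUPAC DNA alphabet.

    Any character outside {A,C,G,T, degenerate codes, '-'} is an error, not
    silently masked.
    """
    s = raw.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValidationError(
            f"invalid residue(s) {sorted(bad)} in {where}; "
            "expected IUPAC DNA letters or '-'"
        )
    return s


def iupac_code(bases: set[str] | frozenset[str]) -> str:
    """IUPAC one-letter code covering exactly the given set of plain bases."""
    try:
        return SETS_TO_IUPAC[frozenset(bases)]
    except KeyError:
        raise ValidationError(f"no IUPAC code for base set {sorted(bases)}") from None


def complement(seq: str) -> str:
    """Base-wise complement (IUPAC-aware, gaps preserved)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return complement(seq)[::-1]


def bases_compatible(a: str, b: str) -> bool:
    """True if the IUPAC sets of the two letters intersect (gap never matches)."""
    if a == GAP or b == GAP:
        return False
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def degeneracy(seq: str) -> int:
    """Product of per-position IUPAC set sizes."""
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def expand_degenerate(seq: str, cap: int = 256) -> list[str]:
    """All plain-base expansions of a degenerate sequence, in lexical order.

    Raises ValidationError if the expansion count exceeds `cap` -- resolve the
    degeneracy first (e.g. design with fewer ambiguity codes).
    """
    n = degeneracy(seq)
    if n > cap:
        raise ValidationError(
            f"degenerate expansion of {seq!r} has {n} variants (cap {cap}); "
            "resolve ambiguity codes first"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return ["".join(p) for p in itertools.product(*pools)]


@dataclass(frozen=True)
class Oligo:
    """A 5'->3' oligonucleotide with per-position chemistry.

    Parameters
    ----------
    name : short identifier, e.g. ``"ITS1F KU LNA"``.
    bases : IUPAC base string, 5'->3', no gaps.
    chemistry : tuple of ``"DNA"``/``"LNA"``, one entry per base. LNA is never
        allowed on a degenerate position because the nearest-neighbor
        increments for degenerate LNA stacks are undefined here.
    three_prime_mod : ``"none"`` or ``"phosphate"`` (a 3' phosphate blocks
        polymerase extension, the defining feature of a clamping oligo).
    five_prime_extension : extra 5' DNA bases (e.g. a 40-base GC clamp), or "".
    """

    name: str
    bases: str
    chemistry: tuple[str, ...] = ()
    three_prime_mod: str = "none"
    five_prime_extension: str = ""

    def __post_init__(self) -> None:
        bases = normalize_residues(self.bases, where=f"oligo {self.name!r}")
        if GAP in bases:
            raise ValidationError(f"oligo {self.name!r} may not contain gaps")
        object.__setattr__(self, "bases", bases)
        chem = self.chemistry or tuple(DNA for _ in bases)
        if len(chem) != len(bases):
            raise ValidationError(
                f"oligo {self.name!r}: chemistry length {len(chem)} != "
                f"sequence length {len(bases)}"
            )
        if any(c not in (DNA, LNA) for c in chem):
            raise ValidationError(f"oligo {self.name!r}: chemistry entries must be DNA|LNA")
        for pos, (b, c) in enumerate(zip(bases, chem), start=1):
            if c == LNA and len(IUPAC_SETS[b]) > 1:
                raise ValidationError(
                    f"oligo {self.name!r}: LNA at degenerate position {pos} ({b})"
                )
        object.__setattr__(self, "chemistry", tuple(chem))
        if self.three_prime_mod not in ("none", "phosphate"):
            raise ValidationError(f"unknown 3' modification {self.three_prime_mod!r}")
        if self.five_prime_extension:
            ext = normalize_residues(self.five_prime_extension, where="5' extension")
            object.__setattr__(self, "five_prime_extension", ext)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def lna_positions(self) -> tuple[int, ...]:
        """1-based positions (5'->3') carrying LNA chemistry."""
        return tuple(i for i, c in enumerate(self.chemistry, start=1) if c == LNA)

    @property
    def full_sequence(self) -> str:
        """5' extension concatenated with the core bases."""
        return self.five_prime_extension + self.bases

    @property
    def is_degenerate(self) -> bool:
        return any(len(IUPAC_SETS[b]) > 1 for b in self.bases)

    def with_lna(self, positions: set[int] | tuple[int, ...], name: str | None = None) -> "Oligo":
        """Copy of this oligo with LNA chemistry at the given 1-based positions."""
        chem = tuple(
            LNA if i in set(positions) else c
            for i, c in enumerate(self.chemistry, start=1)
        )
        return replace(self, chemistry=chem, name=name or self.name)

    def expansions(self, cap: int = 256) -> list["Oligo"]:
        """Plain-base expansions, each inheriting chemistry and modifications."""
        return [
            replace(self, bases=s, name=f"{self.name}[{i}]")
            for i, s in enumerate(expand_degenerate(self.bases, cap=cap), start=1)
        ]

    def annotated(self) -> str:
        """Human-readable string: LNA positions uppercase, DNA lowercase.

        Note this inverts FASTA softmasking conventions on purpose: the rare,
        important residues (LNA) are the loud ones.  A 3' phosphate is shown
        as a trailing ``p``.
        """
        s = "".join(
            b.upper() if c == LNA else b.lower()
            for b, c in zip(self.bases, self.chemistry)
        )
        if self.three_prime_mod == "phosphate":
            s += "p"
        if self.five_prime_extension:
            s = self.five_prime_extension.lower() + s
        return s
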