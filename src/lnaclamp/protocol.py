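"""Clamped-PCR protocol emission: thermal program, titration plan, DGGE primers.

PCR clamping adds one extra annealing step per cycle, hotter than the primer
annealing step, in which only the high-Tm clamp hybridizes to host templates;
the effective clamp concentration is then found empirically by titration.
For community fingerprinting by DGGE, the forward primer is re-synthesized
with a 40-base GC-rich 5' extension and used in a nested second round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

from .errors import ValidationError
from .oligo import Oligo
from .thermo import TmEstimate, recommend_clamp_annealing

#: 40-base GC clamp carried by the DGGE forward primer.
GC_CLAMP = "CGCCCGCCGCGCGCGGCGGGCGGGGCGGGGGCACGGGGGG"

#: Nested (DGGE) reverse primer ITS2, 5'->3'.
ITS2_PRIMER = "GCTGCGTTCTTCATCGATGC"

DEFAULT_TITRATION_UM = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
EXTENDED_TITRATION_UM = (6.0, 8.0)


@dataclass(frozen=True)
class ProgramStep:
    label: str
    temperature_c: float
    duration_s: int
    cycled: bool


@dataclass(frozen=True)
class ProtocolSpec:
    """A thermal program plus the reagent concentrations to titrate."""

    steps: tuple[ProgramStep, ...]
    cycles: int
    primer_concentration_uM: float = 0.8
    clamp_concentrations_uM: tuple[float, ...] = DEFAULT_TITRATION_UM
    notes: str = ""

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValidationError("cycle count must be >= 1")
        flags = [s.cycled for s in self.steps]
        if True not in flags:
            raise ValidationError("program must contain a cycled block")
        first, last = flags.index(True), len(flags) - 1 - flags[::-1].index(True)
        if not all(flags[first : last + 1]):
            raise ValidationError("cycled steps must form one contiguous block")
        for s in self.steps:
            if not 4.0 <= s.temperature_c <= 99.0:
                raise ValidationError(f"step {s.label!r}: temperature out of range [4, 99]")
            if s.duration_s <= 0:
                raise ValidationError(f"step {s.label!r}: duration must be positive")

    def to_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "primer_concentration_uM": self.primer_concentration_uM,
            "clamp_concentrations_uM": list(self.clamp_concentrations_uM),
            "steps": [
                {
                    "label": s.label,
                    "temperature_c": s.temperature_c,
                    "duration_s": s.duration_s,
                    "cycled": s.cycled,
                }
                for s in self.steps
            ],
            "notes": self.notes,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolSpec":
        d = yaml.safe_load(text)
        return cls(
            steps=tuple(
                ProgramStep(s["label"], s["temperature_c"], s["duration_s"], s["cycled"])
                for s in d["steps"]
            ),
            cycles=d["cycles"],
            primer_concentration_uM=d["primer_concentration_uM"],
            clamp_concentrations_uM=tuple(d["clamp_concentrations_uM"]),
            notes=d.get("notes", ""),
        )

    def to_tsv(self) -> str:
        lines = ["label\ttemperature_c\tduration_s\tcycled"]
        for s in self.steps:
            lines.append(f"{s.label}\t{s.temperature_c:g}\t{s.duration_s}\t{int(s.cycled)}")
        return "\n".join(lines) + "\n"

    def bench_sheet(self) -> str:
        out = [
            "Clamped-PCR bench sheet",
            f"  primers: {self.primer_concentration_uM} uM each (final)",
            "  clamp titration (uM): "
            + ", ".join(f"{c:g}" for c in self.clamp_concentrations_uM),
            f"  cycles: {self.cycles}",
            "  program:",
        ]
        for s in self.steps:
            tag = f"  x{self.cycles}" if s.cycled else ""
            out.append(
                f"    {s.label:<18} {s.temperature_c:>5.1f} C  {s.duration_s:>4d} s{tag}"
            )
        if self.notes:
            out.append("  notes: " + self.notes)
        return "\n".join(out)


def build_clamping_program(
    primer_pair_tms: tuple[TmEstimate, TmEstimate],
    clamp_tm: TmEstimate,
    cycles: int = 40,
    primer_anneal_c: float = 54.0,
    primer_ceiling_offset: float = 4.0,
    extended_titration: bool = False,
) -> ProtocolSpec:
    """Thermal program with the clamp-annealing step inserted per cycle.

    The clamp step temperature is the `thermo.recommend_clamp_annealing`
    recommendation; every other temperature, duration and concentration is
    the standard clamped-PCR default and overridable.  The extended
    titration adds 6.0 and 8.0 uM for stubborn (host-DNA-rich) samples.
    """
    if cycles < 1:
        raise ValidationError("cycle count must be >= 1")
    clamp_step_c = recommend_clamp_annealing(
        primer_pair_tms, clamp_tm, primer_ceiling_offset
    )
    if clamp_step_c <= primer_anneal_c:
        raise ValidationError(
            "clamp-annealing temperature must exceed the primer-annealing step"
        )
    titration = DEFAULT_TITRATION_UM + (EXTENDED_TITRATION_UM if extended_titration else ())
    steps = (
        ProgramStep("initial denaturation", 94.0, 180, False),
        ProgramStep("denaturation", 94.0, 60, True),
        ProgramStep("clamp annealing", float(clamp_step_c), 60, True),
        ProgramStep("primer annealing", primer_anneal_c, 60, True),
        ProgramStep("extension", 72.0, 120, True),
        ProgramStep("final extension", 72.0, 600, False),
    )
    return ProtocolSpec(
        steps=steps,
        cycles=cycles,
        clamp_concentrations_uM=titration,
        notes=(
            "Nested second round for DGGE: dilute round-1 product 10^3- to "
            "10^4-fold, then amplify with the GC-clamped forward primer and "
            "the nested reverse primer (ITS2)."
        ),
    )


def attach_gc_clamp(primer: Oligo) -> Oligo:
    """Attach the 40-base GC clamp as the primer's 5' extension (for DGGE).

    The extension is plain DNA; the primer must not already carry one.
    """
    if primer.five_prime_extension:
        raise ValidationError(
            f"primer {primer.name!r} already carries a 5' extension"
        )
    return replace(
        primer,
        five_prime_extension=GC_CLAMP,
        name=f"{primer.name} + GC clamp",
    )
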