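"""Nearest-neighbor melting-temperature prediction for DNA and LNA oligos.

The duplex Tm of an oligonucleotide against its perfect DNA complement is
computed from summed nearest-neighbor enthalpy/entropy terms (unified DNA
parameters, 1 M NaCl reference) with duplex-initiation terms, an entropic
monovalent-salt correction, and -- for locked-nucleic-acid (LNA) positions --
per-stack modification increments: every base stack adjacent to at least one
LNA base receives a sequence-dependent (ddH, ddS) increment, applied once per
stack even between two consecutive LNA bases.

Degenerate oligos are expanded over their IUPAC variants (capped); the
headline ``tm`` is the median over expansions, with min/max always surfaced.

The LNA increment table shipped with the package is the package's own
calibrated parameter set: magnitudes follow published single-substitution
LNA thermodynamics (entropy-driven stabilization, pyrimidine-rich contexts
stabilizing more than purine-rich ones) and are anchored, together with the
default buffer conditions, to the four vendor-calculator melting temperatures
printed for the reference clamp and primer designs.  See ``docs/methods.md``.
"""

from __future__ import annotations

import functools
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources

from .errors import DesignInfeasibleError, ValidationError
from .oligo import DNA, LNA, Oligo, reverse_complement

R_GAS = 1.987  # cal/(mol*K)
EXPANSION_CAP = 256
MIN_LENGTH = 8

_PARAMETER_SETS = {
    "v1": ("dna_nn_unified.tsv", "lna_stack_increments.tsv"),
}


def _read_table(filename: str) -> dict[str, tuple[float, float]]:
    text = resources.files("lnaclamp.data").joinpath(filename).read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    return table


@functools.lru_cache(maxsize=None)
def _load_parameter_set(name: str) -> tuple[dict, dict]:
    try:
        dna_file, lna_file = _PARAMETER_SETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown parameter set {name!r}; available: {sorted(_PARAMETER_SETS)}"
        ) from None
    dna = _read_table(dna_file)
    # Derive reverse-complement duplicate stacks (duplex symmetry).
    for stack in list(dna):
        if stack.startswith(("init", "sym")):
            continue
        rc = reverse_complement(stack)
        dna.setdefault(rc, dna[stack])
    lna = _read_table(lna_file)
    return dna, lna


@dataclass(frozen=True)
class Conditions:
    """Buffer and strand-concentration assumptions for a Tm prediction.

    Defaults (115 mM monovalent cation, no divalent term, 0.25 uM total
    oligonucleotide) are the package's frozen calibration point for the
    shipped ``v1`` parameter set.
    """

    monovalent_mM: float = 115.0
    divalent_mM: float = 0.0
    oligo_concentration_M: float = 0.25e-6
    parameter_set: str = "v1"

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.oligo_concentration_M <= 0:
            raise ValidationError("cation and oligo concentrations must be positive")
        if self.divalent_mM < 0:
            raise ValidationError("divalent concentration may not be negative")
        _load_parameter_set(self.parameter_set)  # fail fast on unknown sets

    @property
    def monovalent_equivalent_M(self) -> float:
        """Monovalent-equivalent cation concentration (von Ahsen square-root
        rule for the divalent contribution), in mol/L."""
        eq_mM = self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)
        return eq_mM / 1000.0


DEFAULT_CONDITIONS = Conditions()


@dataclass(frozen=True)
class TmEstimate:
    """Predicted melting temperature with its degenerate-expansion range."""

    tm: float
    tm_min: float
    tm_max: float
    n_expansions: int
    conditions: Conditions

    def __post_init__(self) -> None:
        if not self.tm_min <= self.tm <= self.tm_max:
            raise ValidationError("tm must lie within [tm_min, tm_max]")
        if self.n_expansions == 1 and self.tm_min != self.tm_max:
            raise ValidationError("a single expansion cannot have a Tm range")


def nn_sums(
    bases: str,
    chemistry: tuple[str, ...] | None = None,
    parameter_set: str = "v1",
) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/mol/K) for a plain-base oligo vs its
    complement, including initiation and LNA stack increments.

    Exposed separately so an independent brute-force summation can be checked
    against it.
    """
    dna, lna = _load_parameter_set(parameter_set)
    n = len(bases)
    chem = chemistry or tuple(DNA for _ in bases)
    dh = ds = 0.0
    for end in (bases[0], bases[-1]):
        key = "init_AT" if end in "AT" else "init_GC"
        dh += dna[key][0]
        ds += dna[key][1]
    if bases == reverse_complement(bases):
        dh += dna["sym"][0]
        ds += dna["sym"][1]
    for i in range(n - 1):
        stack = bases[i : i + 2]
        dh += dna[stack][0]
        ds += dna[stack][1]
        if chem[i] == LNA or chem[i + 1] == LNA:
            dh += lna[stack][0]
            ds += lna[stack][1]
    return dh, ds


def _tm_single(bases: str, chem: tuple[str, ...], cond: Conditions) -> float:
    dh, ds = nn_sums(bases, chem, cond.parameter_set)
    n = len(bases)
    ds_salt = ds + 0.368 * (n - 1) * math.log(cond.monovalent_equivalent_M)
    # Non-self-complementary duplex with equal strand concentrations: CT/4.
    divisor = 1.0 if bases == reverse_complement(bases) else 4.0
    ct = cond.oligo_concentration_M / divisor
    return 1000.0 * dh / (ds_salt + R_GAS * math.log(ct)) - 273.15


def tm_oligo(oligo: Oligo, conditions: Conditions = DEFAULT_CONDITIONS) -> TmEstimate:
    """Tm estimate for a (possibly degenerate, possibly LNA-bearing) oligo.

    Degenerate oligos are expanded over all IUPAC variants (cap 256) and the
    median is reported as the headline ``tm`` with min/max alongside.  Oligos
    shorter than 8 nt are outside the model's validity and rejected.
    """
    if len(oligo) < MIN_LENGTH:
        raise ValidationError(
            f"oligo {oligo.name!r} has {len(oligo)} nt; nearest-neighbor Tm "
            f"prediction requires >= {MIN_LENGTH}"
        )
    tms = [
        _tm_single(exp.bases, exp.chemistry, conditions)
        for exp in oligo.expansions(cap=EXPANSION_CAP)
    ]
    return TmEstimate(
        tm=float(statistics.median(tms)),
        tm_min=min(tms),
        tm_max=max(tms),
        n_expansions=len(tms),
        conditions=conditions,
    )


def recommend_clamp_annealing(
    primer_tms: tuple[TmEstimate, TmEstimate],
    clamp_tm: TmEstimate,
    primer_ceiling_offset: float = 4.0,
) -> int:
    """Annealing temperature (deg C, integer) for the clamp-hybridization step.

    The clamp step must sit above the temperature at which the amplification
    primers still function (their highest predicted Tm plus an empirical
    functional-ceiling offset) yet close enough to the clamp's own Tm that the
    clamp hybridizes efficiently: the recommendation is the larger of the two,
    and a recommendation exceeding the clamp Tm by more than 1 deg C is an
    infeasible design.
    """
    max_primer = max(t.tm_max for t in primer_tms)
    if clamp_tm.tm <= max_primer:
        raise DesignInfeasibleError(
            f"clamp Tm {clamp_tm.tm:.1f} not above primer Tm {max_primer:.1f}: "
            "the clamp cannot outcompete the primer"
        )
    ceiling = max_primer + primer_ceiling_offset
    recommendation = max(ceiling, round(clamp_tm.tm))
    if recommendation > clamp_tm.tm + 1.0:
        raise DesignInfeasibleError(
            f"required clamp-step temperature {recommendation:.0f} exceeds the "
            f"clamp Tm {clamp_tm.tm:.1f} by more than 1 deg C: the primers are "
            "too hot for this clamp"
        )
    return int(round(recommendation))
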