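"""Degenerate target-specific primer construction and LNA substitution planning.

The forward-primer pathway: build a degenerate consensus over the target
(fungal) column profiles -- each column's IUPAC code covers the modal base
plus every minor base above a frequency threshold -- then convert the bases
that discriminate targets from every non-target (host plant) group into LNA,
which sharpens mismatch discrimination exactly at the diagnostic positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .oligo import DNA, IUPAC_SETS, LNA, Oligo, iupac_code
from .profiling import ColumnProfile, DiscriminatingSite

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    """Tunable thresholds for primer and clamp design.

    minor_freq_threshold : minimum within-target frequency for a minor base
        to earn a degeneracy code in the consensus (default 5%).
    target_purity / nontarget_purity : frequency a base must reach to call a
        column "specific" for the target / a non-target group (default 0.95).
    max_lna : cap on LNA substitutions per oligo.
    lna_min_spacing : minimum column gap preferred between LNA bases.
    tm_target / tm_tolerance : clamp melting-temperature window (deg C).
    overlap_range : allowed clamp/reverse-primer overlaps (bases).
    """

    minor_freq_threshold: float = 0.05
    target_purity: float = 0.95
    nontarget_purity: float = 0.95
    max_lna: int = 6
    lna_min_spacing: int = 2
    tm_target: float = 70.0
    tm_tolerance: float = 2.0
    overlap_range: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        for name in ("minor_freq_threshold", "target_purity", "nontarget_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.max_lna < 1:
            raise ValidationError("max_lna must be >= 1")
        if self.tm_tolerance < 0:
            raise ValidationError("tm_tolerance must be >= 0")
        if not set(self.overlap_range) <= {1, 2}:
            raise ValidationError("overlap_range entries must be 1 or 2")


DEFAULT_CONFIG = DesignConfig()


def degenerate_consensus(
    target_profiles: Sequence[ColumnProfile],
    minor_freq_threshold: float = DEFAULT_CONFIG.minor_freq_threshold,
    name: str = "consensus",
) -> Oligo:
    """DNA-only degenerate consensus over target column profiles.

    Per column the IUPAC code covers the modal base plus every base at or
    above `minor_freq_threshold`.  A column demanding all four bases emits N
    with a design warning (logged, not raised).
    """
    if not target_profiles:
        raise ValidationError("no profiles to build a consensus from")
    letters = []
    for p in target_profiles:
        if p.modal_freq == 0.0:
            raise ValidationError(f"column {p.col} has no contributing bases")
        chosen = p.bases_at_least(minor_freq_threshold)
        if len(chosen) == 4:
            log.warning("column %d requires all four bases; emitting N", p.col)
        letters.append(iupac_code(chosen))
    return Oligo(name=name, bases="".join(letters))


def plan_lna(
    primer: Oligo,
    discriminating: Iterable[DiscriminatingSite | int],
    config: DesignConfig = DEFAULT_CONFIG,
    name: str | None = None,
) -> Oligo:
    """Mark target-discriminating, non-degenerate primer positions as LNA.

    Positions are ranked by non-target mismatch strength (how many non-target
    groups the target base mismatches) and then by 3'-proximity, and at most
    ``config.max_lna`` are converted.  Degenerate positions are skipped with
    a warning -- LNA chemistry on an ambiguity code is not meaningful here.
    A 3'-terminal LNA is permitted.  Base letters are never altered, and the
    operation is idempotent.
    """
    if any(c == LNA for c in primer.chemistry):
        pass  # replanning an already-marked primer is allowed (idempotence)
    sites: list[tuple[int, int]] = []  # (position, strength)
    for d in discriminating:
        if isinstance(d, DiscriminatingSite):
            pos, strength = d.col, len(d.nontarget_bases)
        else:
            pos, strength = int(d), 1
        if not 1 <= pos <= len(primer):
            raise ValidationError(
                f"discriminating position {pos} outside primer of length {len(primer)}"
            )
        if len(IUPAC_SETS[primer.bases[pos - 1]]) > 1:
            log.warning(
                "position %d is degenerate (%s); skipping LNA there",
                pos,
                primer.bases[pos - 1],
            )
            continue
        sites.append((pos, strength))
    if not sites:
        log.warning("no eligible LNA positions; returning primer unchanged")
        return primer
    ranked = sorted(sites, key=lambda ps: (-ps[1], -ps[0]))
    chosen = {pos for pos, _ in ranked[: config.max_lna]}
    return primer.with_lna(chosen, name=name or primer.name)
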