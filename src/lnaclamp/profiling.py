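"""Column composition profiles, primer coverage and discrimination calls.

These are the alignment statistics that drive primer and clamp design:
per-column base frequencies (with fractional handling of IUPAC ambiguity),
primer coverage under a mismatch allowance, positions that discriminate a
target group from every non-target group, grouping of host sequences into
identical window types, and the percent-identity convention used when
reporting database matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .alignio import Alignment, SequenceRecord, extract_window
from .errors import EmptySelectionError, ValidationError
from .oligo import GAP, IUPAC_SETS, Oligo, bases_compatible

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ColumnProfile:
    """Base frequencies in one alignment column.

    ``freqs`` sums to 1 over the contributing (non-gap) rows; an ambiguous
    input base contributes fractionally and equally to each of its
    constituent bases (R adds 1/2 to A and 1/2 to G), so columns rich in Ns
    do not lose effective depth.  ``gap_fraction`` is computed over all rows
    and gaps are excluded from the frequency denominator.
    """

    col: int
    freqs: Mapping[str, float]
    gap_fraction: float
    n_effective: int

    @property
    def modal_base(self) -> str:
        return max(BASES, key=lambda b: (self.freqs.get(b, 0.0), b))

    @property
    def modal_freq(self) -> float:
        return self.freqs.get(self.modal_base, 0.0)

    def bases_at_least(self, threshold: float) -> set[str]:
        """Bases at or above a frequency threshold (always includes the mode)."""
        chosen = {b for b in BASES if self.freqs.get(b, 0.0) >= threshold}
        chosen.add(self.modal_base)
        return chosen


class DiscriminatingSite(NamedTuple):
    """A column separating targets from every non-target group."""

    col: int
    target_base: str
    nontarget_bases: frozenset[str]


class Mismatch(NamedTuple):
    record_id: str
    col: int
    primer_base: str
    sequence_base: str


@dataclass(frozen=True)
class CoverageReport:
    """Per-group primer coverage: (matched, total, fraction) plus mismatches."""

    primer_name: str
    per_group: Mapping[str, tuple[int, int, float]]
    mismatches: tuple[Mismatch, ...]
    max_mismatch: int

    @property
    def overall(self) -> tuple[int, int, float]:
        matched = sum(m for m, _t, _f in self.per_group.values())
        total = sum(t for _m, t, _f in self.per_group.values())
        return matched, total, matched / total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "matched": m, "total": t, "fraction": f}
            for g, (m, t, f) in sorted(self.per_group.items())
        ]
        m, t, f = self.overall
        rows.append({"group": "overall", "matched": m, "total": t, "fraction": f})
        return pd.DataFrame(rows)


def column_profiles(aln: Alignment, group_filter: str = "all") -> list[ColumnProfile]:
    """One `ColumnProfile` per column, over rows matching `group_filter`.

    `group_filter` is a group label prefix (``"target"`` selects every
    ``target:*`` group) or ``"all"``.
    """
    sub = aln.select(group_filter)
    profiles = []
    for col in range(1, sub.n_cols + 1):
        counts = dict.fromkeys(BASES, 0.0)
        n_gap = 0
        n_eff = 0
        for rec in sub.records:
            ch = rec.residues[col - 1]
            if ch == GAP:
                n_gap += 1
                continue
            constituents = IUPAC_SETS[ch]
            w = 1.0 / len(constituents)
            for b in constituents:
                counts[b] += w
            n_eff += 1
        total = sum(counts.values())
        freqs = {b: (counts[b] / total if total else 0.0) for b in BASES}
        profiles.append(
            ColumnProfile(
                col=col,
                freqs=freqs,
                gap_fraction=n_gap / len(sub.records),
                n_effective=n_eff,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Long-format (col, base, freq) table of a profile sequence."""
    rows = [
        {"col": p.col, "base": b, "freq": p.freqs.get(b, 0.0)}
        for p in profiles
        for b in BASES
    ]
    return pd.DataFrame(rows)


def coverage(
    primer: Oligo,
    seqs: Alignment | Iterable[SequenceRecord],
    max_mismatch: int = 0,
) -> CoverageReport:
    """Fraction of sequences the primer matches at its annealing window.

    Sequences are assumed to already be aligned to the primer (column i of
    each row faces primer position i).  A row is covered when at most
    `max_mismatch` positions fail IUPAC compatibility: a degenerate primer
    base matches any of its constituent bases, a degenerate sequence base
    matches if the two IUPAC sets intersect, and a gap never matches.
    """
    records = seqs.records if isinstance(seqs, Alignment) else tuple(seqs)
    if not records:
        raise EmptySelectionError("empty sequence set")
    n = len(primer)
    for rec in records:
        if len(rec) < n:
            raise ValidationError(
                f"record {rec.id!r} window ({len(rec)}) shorter than primer ({n})"
            )
    per_group: dict[str, list[int]] = {}
    mismatches: list[Mismatch] = []
    for rec in records:
        mm = []
        for i in range(n):
            if not bases_compatible(primer.bases[i], rec.residues[i]):
                mm.append(Mismatch(rec.id, i + 1, primer.bases[i], rec.residues[i]))
        matched = len(mm) <= max_mismatch
        stats = per_group.setdefault(rec.group, [0, 0])
        stats[0] += int(matched)
        stats[1] += 1
        if not matched:
            mismatches.extend(mm)
    frozen = {
        g: (m, t, m / t) for g, (m, t) in per_group.items()
    }
    return CoverageReport(
        primer_name=primer.name,
        per_group=frozen,
        mismatches=tuple(mismatches),
        max_mismatch=max_mismatch,
    )


def discriminating_positions(
    target_profiles: Sequence[ColumnProfile],
    nontarget_profiles: Mapping[str, Sequence[ColumnProfile]],
    target_purity: float = 0.95,
    nontarget_purity: float = 0.95,
) -> list[DiscriminatingSite]:
    """Columns where targets are near-fixed for a base every non-target lacks.

    A column qualifies when one base reaches frequency >= `target_purity`
    in the target profiles and, in every non-target group, the modal base
    differs from it with frequency >= `nontarget_purity`.  Output is sorted
    by column.
    """
    target_cols = [p.col for p in target_profiles]
    for group, profs in nontarget_profiles.items():
        if [p.col for p in profs] != target_cols:
            raise ValidationError(
                f"non-target group {group!r} covers different columns than targets"
            )
    sites = []
    for idx, tp in enumerate(target_profiles):
        if tp.modal_freq < target_purity:
            continue
        t_base = tp.modal_base
        nt_bases = set()
        ok = True
        for profs in nontarget_profiles.values():
            np_ = profs[idx]
            if np_.modal_base == t_base or np_.modal_freq < nontarget_purity:
                ok = False
                break
            nt_bases.add(np_.modal_base)
        if ok and nontarget_profiles:
            sites.append(DiscriminatingSite(tp.col, t_base, frozenset(nt_bases)))
    return sorted(sites)


def sites_to_frame(sites: Sequence[DiscriminatingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "col": s.col,
                "target_base": s.target_base,
                "nontarget_bases": ",".join(sorted(s.nontarget_bases)),
            }
            for s in sites
        ]
    )


def group_by_identity(
    aln: Alignment, window: tuple[int, int] | None = None
) -> dict[str, tuple[str, ...]]:
    """Partition record ids by identical (gap-stripped) window sequences.

    Types are labelled ``a``, ``b``, ``c``, ... in order of first appearance,
    continuing ``z1``, ``z2``, ... past 26 types.
    """
    sub = extract_window(aln, *window) if window is not None else aln
    types: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in sub.records:
        key = rec.ungapped
        if not key:
            raise ValidationError(f"record {rec.id!r} is empty in the window")
        if key not in types:
            types[key] = []
            order.append(key)
        types[key].append(rec.id)
    labels = {}
    for i, key in enumerate(order):
        label = chr(ord("a") + i) if i < 26 else f"z{i - 25}"
        labels[label] = tuple(types[key])
    return labels


def identity_percent(matches: int, aligned_length: int) -> int:
    """Integer percent identity, rounded half away from zero.

    This is the convention used when reporting database-match similarities
    (e.g. 204 matches over 218 aligned columns -> 94%).
    """
    if aligned_length <= 0:
        raise ZeroDivisionError("aligned_length must be positive")
    if not 0 <= matches <= aligned_length:
        raise ValidationError("matches must lie in [0, aligned_length]")
    value = 100 * matches / aligned_length
    import math

    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))
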