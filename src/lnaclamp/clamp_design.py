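"""Host-blocking LNA clamp design against the reverse-primer annealing site.

A clamping oligonucleotide competes with the reverse primer on host-plant
templates: it overlaps the primer's 3'-terminal annealing bases by one or two
positions, extends toward the extension side, carries LNA chemistry at the
positions where the host differs from the fungal targets (spread as evenly
as possible), and is 3'-phosphorylated so the polymerase cannot extend it.

Orientation convention: the stored alignment strand is the one the forward
primer reads 5'->3'.  The reverse primer and the clamp both anneal to that
stored strand, so both are written 5'->3' as the reverse complement of a
stored-strand window; the reverse primer's 3' terminus faces the anchor
column and its annealing window extends to higher columns, while the clamp
covers columns ``anchor-(L-v) .. anchor+v-1`` for length L and overlap v
(the overlap bases are therefore the clamp's 5' end).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .alignio import Alignment, SequenceRecord
from .errors import (
    DesignInfeasibleError,
    InsufficientSpecificityError,
    ValidationError,
)
from .oligo import GAP, IUPAC_SETS, Oligo, reverse_complement
from .primer_design import DEFAULT_CONFIG, DesignConfig
from .profiling import ColumnProfile
from .thermo import DEFAULT_CONDITIONS, Conditions, TmEstimate, tm_oligo

LENGTH_RANGE = (20, 25)  # brackets the printed 22/23-mer clamping oligos


@dataclass(frozen=True)
class ScreenResult:
    """Exact-complement cross-reactivity screen against target sequences."""

    n_target_hits: int
    hit_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_target_hits != len(self.hit_ids):
            raise ValidationError("n_target_hits must equal len(hit_ids)")


@dataclass(frozen=True)
class ClampDesign:
    """An accepted clamping oligo plus its design geometry and screening."""

    oligo: Oligo
    host_type: str
    overlap_length: int
    overlap_columns: tuple[int, ...]
    window_columns: tuple[int, int]  # stored-strand columns covered, inclusive
    lna_positions: tuple[int, ...]  # 1-based, 5'->3' on the clamp
    tm: TmEstimate
    screen: ScreenResult | None = None

    def __post_init__(self) -> None:
        if self.overlap_length not in (1, 2):
            raise ValidationError("overlap_length must be 1 or 2")
        if self.oligo.three_prime_mod != "phosphate":
            raise ValidationError("a clamp must carry a 3' phosphate")
        if any(p <= self.overlap_length for p in self.lna_positions):
            raise ValidationError("LNA is not allowed on primer-overlap bases")

    def report(self) -> str:
        lines = [
            f"clamp for host type {self.host_type}",
            f"  sequence (LNA uppercase): {self.oligo.annotated()}",
            f"  bases 5'->3'            : {self.oligo.bases}",
            f"  length / overlap        : {len(self.oligo)} nt / {self.overlap_length} base(s) with the reverse primer 3' end",
            f"  LNA positions (1-based) : {','.join(map(str, self.lna_positions))}",
            f"  Tm                      : {self.tm.tm:.1f} C",
        ]
        if self.screen is not None:
            lines.append(
                f"  target cross-hits       : {self.screen.n_target_hits}"
                + (f" ({', '.join(self.screen.hit_ids)})" if self.screen.hit_ids else "")
            )
        return "\n".join(lines)


def spread_positions(positions: Sequence[int], k: int) -> tuple[int, ...]:
    """Choose k positions maximizing the minimal pairwise distance.

    Exhaustive over combinations (candidate windows are <= 25 nt so this is
    tiny).  Ties broken by larger total spread, then lexicographically.
    """
    positions = sorted(positions)
    if k >= len(positions):
        return tuple(positions)
    if k <= 0:
        raise ValidationError("k must be positive")

    def score(combo: tuple[int, ...]) -> tuple:
        gaps = [b - a for a, b in zip(combo, combo[1:])]
        return (min(gaps) if gaps else 0, sum(gaps), tuple(-p for p in combo))

    return max(itertools.combinations(positions, k), key=score)


def _host_sequence(host_window: Alignment, cols: range) -> str:
    """The (identical) host row content over `cols`; error if rows disagree."""
    seqs = {r.residues[cols.start - 1 : cols.stop - 1] for r in host_window.records}
    if len(seqs) != 1:
        raise ValidationError(
            "host rows are not identical over the clamp window; group host "
            "sequences into identity types first (profiling.group_by_identity)"
        )
    return next(iter(seqs))


def host_specific_columns(
    host_window: Alignment,
    target_profiles: Sequence[ColumnProfile],
    cols: Iterable[int],
    target_purity: float,
) -> set[int]:
    """Stored-strand columns where the host base conflicts with a near-fixed
    target base (the columns eligible for LNA on a clamp)."""
    by_col = {p.col: p for p in target_profiles}
    specific = set()
    host = host_window.records[0].residues
    for col in cols:
        base = host[col - 1]
        if base == GAP or len(IUPAC_SETS[base]) > 1:
            continue
        prof = by_col.get(col)
        if prof is None:
            continue
        if prof.modal_freq >= target_purity and prof.modal_base != base:
            specific.add(col)
    return specific


def enumerate_candidates(
    host_window: Alignment,
    reverse_primer_anchor: int,
    target_profiles: Sequence[ColumnProfile],
    config: DesignConfig = DEFAULT_CONFIG,
    conditions: Conditions = DEFAULT_CONDITIONS,
    host_type: str = "host",
) -> list[dict]:
    """All (overlap, length) clamp candidates with their status.

    Each entry records the candidate geometry, sequence, LNA plan, Tm and a
    status: ``ok`` (within the Tm window), ``tm_out_of_window`` or
    ``insufficient_specificity``.
    """
    n_cols = host_window.n_cols
    anchor = reverse_primer_anchor
    if not 1 <= anchor <= n_cols:
        raise ValidationError(f"anchor column {anchor} outside alignment (1..{n_cols})")
    min_len, max_len = LENGTH_RANGE
    if anchor - (max_len - 1) < 1:
        raise ValidationError(
            f"window too short: need >= {max_len} columns on the extension side "
            f"of the anchor (anchor={anchor})"
        )
    host = host_window.records[0].residues
    out: list[dict] = []
    for v in sorted(config.overlap_range):
        for length in range(min_len, max_len + 1):
            left = anchor - (length - v)
            right = anchor + v - 1
            if left < 1 or right > n_cols:
                continue
            span = host[left - 1 : right]
            if GAP in span or any(len(IUPAC_SETS[b]) > 1 for b in span):
                continue  # clamp sequence must be plain host bases
            _host_sequence(host_window, range(left, right + 1))  # identity check
            bases = reverse_complement(span)
            # clamp position p (1-based, 5'->3') faces column right - (p-1)
            specific_cols = host_specific_columns(
                host_window, target_profiles, range(left, right + 1), config.target_purity
            )
            specific_pos = sorted(
                right - c + 1 for c in specific_cols if (right - c + 1) > v
            )
            entry = {
                "host_type": host_type,
                "overlap": v,
                "length": length,
                "window": (left, right),
                "bases": bases,
                "n_specific": len(specific_pos),
            }
            if len(specific_pos) < 2:
                entry.update(status="insufficient_specificity", tm=None, lna=())
                out.append(entry)
                continue
            lna = spread_positions(specific_pos, config.max_lna)
            oligo = Oligo(
                name=f"clamp_{host_type}_v{v}_L{length}",
                bases=bases,
                three_prime_mod="phosphate",
            ).with_lna(set(lna))
            est = tm_oligo(oligo, conditions)
            feasible = abs(est.tm - config.tm_target) <= config.tm_tolerance
            entry.update(
                status="ok" if feasible else "tm_out_of_window",
                tm=est,
                lna=tuple(lna),
                density=len(lna) / length,
                oligo=oligo,
            )
            out.append(entry)
    return out


def candidates_to_frame(candidates: list[dict]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "host_type": c["host_type"],
                "overlap": c["overlap"],
                "length": c["length"],
                "bases": c["bases"],
                "lna_positions": ",".join(map(str, c.get("lna", ()))),
                "tm": round(c["tm"].tm, 2) if c.get("tm") else None,
                "status": c["status"],
            }
        )
    return pd.DataFrame(rows)


def design_clamp(
    host_window: Alignment,
    reverse_primer_anchor: int,
    target_profiles: Sequence[ColumnProfile],
    config: DesignConfig = DEFAULT_CONFIG,
    conditions: Conditions = DEFAULT_CONDITIONS,
    host_type: str = "host",
) -> ClampDesign:
    """Design the clamping oligo for one host sequence type.

    Candidates are enumerated over overlap and length; LNA goes on every
    host-specific non-overlap position (thinned to ``config.max_lna`` by the
    equal-distribution rule).  Among candidates inside the Tm window the
    winner maximizes host-specific position density (a clamp padded with
    fungus-matching bases would clamp fungi too), then overlap depth (a
    deeper overlap occludes the primer's 3' terminus more directly), then
    closeness of Tm to the target, then shortness.
    """
    candidates = enumerate_candidates(
        host_window, reverse_primer_anchor, target_profiles, config, conditions, host_type
    )
    feasible = [c for c in candidates if c["status"] == "ok"]
    if not feasible:
        with_tm = [c for c in candidates if c.get("tm") is not None]
        if not with_tm:
            raise InsufficientSpecificityError(
                f"host type {host_type!r}: fewer than 2 host-specific positions "
                "in every candidate window"
            )
        near = sorted(with_tm, key=lambda c: abs(c["tm"].tm - config.tm_target))[:3]
        misses = "; ".join(
            f"overlap {c['overlap']} length {c['length']} Tm {c['tm'].tm:.1f}"
            for c in near
        )
        raise DesignInfeasibleError(
            f"host type {host_type!r}: no clamp within "
            f"{config.tm_target}+/-{config.tm_tolerance} C; best near-misses: {misses}"
        )
    best = min(
        feasible,
        key=lambda c: (
            -c["density"],
            -c["overlap"],
            abs(c["tm"].tm - config.tm_target),
            c["length"],
        ),
    )
    left, right = best["window"]
    v = best["overlap"]
    return ClampDesign(
        oligo=replace(best["oligo"], name=f"clamp_{host_type}"),
        host_type=host_type,
        overlap_length=v,
        overlap_columns=tuple(range(reverse_primer_anchor, reverse_primer_anchor + v)),
        window_columns=(left, right),
        lna_positions=best["lna"],
        tm=best["tm"],
    )


def screen_cross_reactivity(
    clamp: ClampDesign,
    target_seqs: Alignment | Iterable[SequenceRecord],
) -> ScreenResult:
    """Count target records exactly complementary to the clamp.

    A record hits when its (gap-stripped) stored-strand window over the
    clamp's columns equals the clamp's reverse complement -- i.e. the clamp
    would hybridize the record perfectly -- or, checking the opposite
    orientation, equals the clamp sequence itself.  Non-zero counts mean the
    clamp would also block those targets; they are reported, not fatal.
    """
    records = target_seqs.records if isinstance(target_seqs, Alignment) else tuple(target_seqs)
    left, right = clamp.window_columns
    want_fwd = reverse_complement(clamp.oligo.bases)
    want_rev = clamp.oligo.bases
    hits = []
    for rec in records:
        if len(rec) < right:
            continue
        window = rec.residues[left - 1 : right].replace(GAP, "")
        if window == want_fwd or window == want_rev:
            hits.append(rec.id)
    return ScreenResult(n_target_hits=len(hits), hit_ids=tuple(hits))
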