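"""Reading, writing and slicing of sequence alignments.

Alignments come from standard FASTA or Clustal files (parsed with Biopython)
and carry an optional sidecar group map -- a two-column tab-separated file
assigning each record id to a group label such as ``target:Ascomycota`` or
``nontarget:wheat``.  Column coordinates are 1-based, inclusive, and always
refer to the stored strand read 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO as _BioAlignIO
from Bio import SeqIO as _BioSeqIO

from .errors import EmptySelectionError, FormatError, ValidationError
from .oligo import GAP, normalize_residues

UNKNOWN_GROUP = "unknown"


@dataclass(frozen=True)
class SequenceRecord:
    """One gapped IUPAC DNA row with a group label."""

    id: str
    residues: str
    group: str = UNKNOWN_GROUP

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, where=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length rows.

    ``column_map`` (optional) maps this alignment's 1-based columns back to
    the 1-based columns of the alignment it was derived from (by `degap` or
    `extract_window`), for traceability of reported positions.
    """

    records: tuple[SequenceRecord, ...]
    column_map: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment must contain at least one record")
        records = tuple(self.records)
        n = len(records[0])
        if n < 1:
            raise ValidationError("alignment must have at least one column")
        for rec in records:
            if len(rec) != n:
                raise ValidationError(
                    f"record {rec.id!r} has length {len(rec)}, expected {n}: "
                    "not a valid alignment"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record id(s): {dup}")
        object.__setattr__(self, "records", records)
        if self.column_map is not None and len(self.column_map) != n:
            raise ValidationError("column_map length must equal the column count")

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(f"record {record_id!r} not in alignment")

    def column(self, col: int) -> str:
        """Residues of 1-based column `col`, top to bottom."""
        self._check_col(col)
        return "".join(r.residues[col - 1] for r in self.records)

    def select(self, group_prefix: str) -> "Alignment":
        """Sub-alignment of rows whose group starts with `group_prefix`.

        The prefix ``"all"`` selects every row.
        """
        if group_prefix == "all":
            return self
        kept = tuple(r for r in self.records if r.group.startswith(group_prefix))
        if not kept:
            raise EmptySelectionError(f"no records with group matching {group_prefix!r}")
        return Alignment(kept, column_map=self.column_map)

    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group)
        return tuple(seen)

    def _check_col(self, col: int) -> None:
        if not 1 <= col <= self.n_cols:
            raise ValidationError(
                f"column {col} out of range 1..{self.n_cols}"
            )


# ---------------------------------------------------------------------------
# IO


def read_group_map(path: str | Path) -> dict[str, str]:
    """Parse a two-column (id <TAB> group) sidecar file."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 'id<TAB>group'")
        seq_id, group = parts
        if seq_id in mapping:
            raise ValidationError(f"{path}: duplicate id {seq_id!r} in group map")
        mapping[seq_id] = group
    return mapping


def write_group_map(aln: Alignment | Iterable[SequenceRecord], path: str | Path) -> None:
    records = aln.records if isinstance(aln, Alignment) else tuple(aln)
    Path(path).write_text("".join(f"{r.id}\t{r.group}\n" for r in records))


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    group_map: dict[str, str] | str | Path | None = None,
    aligned: bool = True,
) -> Alignment | list[SequenceRecord]:
    """Read a FASTA or Clustal file into an `Alignment` (or plain record list).

    Residues are normalized to uppercase with U->T.  Group labels come from
    `group_map` (a dict or a sidecar file path); absent ids default to
    ``unknown``.  With ``aligned=True`` (default) unequal row lengths are a
    validation error.
    """
    if format not in ("fasta", "clustal"):
        raise FormatError(f"unsupported format {format!r}; expected fasta or clustal")
    if group_map is not None and not isinstance(group_map, dict):
        group_map = read_group_map(group_map)
    groups = group_map or {}

    try:
        if format == "clustal":
            seqs = list(_BioAlignIO.read(str(path), "clustal"))
        else:
            seqs = list(_BioSeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not seqs:
        raise FormatError(f"{path}: no sequences found (format {format})")

    records = []
    for s in seqs:
        try:
            rec = SequenceRecord(
                id=s.id, residues=str(s.seq), group=groups.get(s.id, UNKNOWN_GROUP)
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records.append(rec)

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate record id(s): {dup}")
    if not aligned:
        return records
    return Alignment(tuple(records))


def write_fasta(aln: Alignment | Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (residues exactly as stored)."""
    records = aln.records if isinstance(aln, Alignment) else tuple(aln)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Column operations


def degap(aln: Alignment, anchor_id: str) -> Alignment:
    """Keep exactly the columns where the anchor row has a residue.

    Mirrors organizing an alignment around a primer row: columns that are
    gaps in the designated anchor (a primer row or reference sequence) are
    discarded.  The returned alignment's ``column_map`` gives, for each new
    1-based column, the original column index.
    """
    try:
        anchor = aln.get(anchor_id)
    except KeyError:
        raise KeyError(f"anchor {anchor_id!r} not present in alignment") from None
    keep = [i + 1 for i, ch in enumerate(anchor.residues) if ch != GAP]
    if not keep:
        raise ValidationError(f"anchor {anchor_id!r} is all gaps: empty alignment")
    records = tuple(
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[c - 1] for c in keep),
            group=r.group,
        )
        for r in aln.records
    )
    parent = aln.column_map or tuple(range(1, aln.n_cols + 1))
    return Alignment(records, column_map=tuple(parent[c - 1] for c in keep))


def extract_window(aln: Alignment, start: int, end: int) -> Alignment:
    """Sub-alignment of columns [start, end], 1-based and inclusive."""
    if not (1 <= start <= end <= aln.n_cols):
        raise ValidationError(
            f"window [{start}, {end}] out of range for {aln.n_cols} columns"
        )
    records = tuple(
        SequenceRecord(id=r.id, residues=r.residues[start - 1 : end], group=r.group)
        for r in aln.records
    )
    parent = aln.column_map or tuple(range(1, aln.n_cols + 1))
    return Alignment(records, column_map=parent[start - 1 : end])
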