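"""Alignment IO, residue normalization and column-coordinate operations."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lnaclamp.alignio import (
    Alignment,
    SequenceRecord,
    degap,
    extract_window,
    read_group_map,
    read_sequences,
    write_fasta,
)
from lnaclamp.errors import FormatError, ValidationError


def _aln(*rows, ids=None, groups=None):
    ids = ids or [f"s{i}" for i in range(1, len(rows) + 1)]
    groups = groups or ["unknown"] * len(rows)
    return Alignment(
        tuple(SequenceRecord(i, r, g) for i, r, g in zip(ids, rows, groups))
    )


class TestReading:
    def test_fasta_parse_and_normalization(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a\nacgu-ACGT\n>b\nACGTNACGT\n>c\nacgtacgtr\n")
        aln = read_sequences(path, "fasta")
        assert aln.n_cols == 9 and len(aln) == 3
        assert aln.get("a").residues == "ACGT-ACGT"  # uppercase, U->T
        assert aln.get("c").residues.endswith("R")

    def test_sidecar_group_map(self, tmp_path):
        (tmp_path / "in.fasta").write_text(">a\nACGT\n>b\nACGT\n")
        (tmp_path / "g.tsv").write_text("a\ttarget:Ascomycota\n")
        aln = read_sequences(tmp_path / "in.fasta", "fasta", group_map=tmp_path / "g.tsv")
        assert aln.get("a").group == "target:Ascomycota"
        assert aln.get("b").group == "unknown"

    def test_clustal_parse(self, tmp_path):
        text = (
            "CLUSTAL W (1.7) multiple sequence alignment\n\n"
            "s1    ACGTACGT\n"
            "s2    ACGTACGA\n"
        )
        path = tmp_path / "in.aln"
        path.write_text(text)
        aln = read_sequences(path, "clustal")
        assert aln.ids == ("s1", "s2") and aln.n_cols == 8

    def test_unparsable_file_is_format_error(self, tmp_path):
        path = tmp_path / "bad.aln"
        path.write_text("this is not clustal\n")
        with pytest.raises(FormatError):
            read_sequences(path, "clustal")

    def test_invalid_residue_is_error_not_masked(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a\nACXT\n")
        with pytest.raises(FormatError, match="X"):
            read_sequences(path, "fasta")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_sequences(path, "fasta")

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(ValidationError):
            read_sequences(path, "fasta")
        records = read_sequences(path, "fasta", aligned=False)
        assert [len(r) for r in records] == [4, 3]


class TestDegap:
    def test_anchor_defines_kept_columns(self):
        aln = _aln("AC-GT", "AAAAA")
        out = degap(aln, "s1")
        assert out.n_cols == 4
        assert out.column_map == (1, 2, 4, 5)
        assert out.get("s2").residues == "AAAA"

    def test_gapless_anchor_is_identity(self):
        aln = _aln("ACGT", "TTTT")
        out = degap(aln, "s1")
        assert [r.residues for r in out] == [r.residues for r in aln]

    def test_all_gap_anchor_rejected(self):
        aln = _aln("----", "ACGT")
        with pytest.raises(ValidationError, match="all gaps"):
            degap(aln, "s1")

    def test_missing_anchor(self):
        with pytest.raises(KeyError):
            degap(_aln("ACGT"), "nope")


class TestExtractWindow:
    def test_identity_and_single_column(self):
        aln = _aln("ACGTT")
        assert extract_window(aln, 1, 5).get("s1").residues == "ACGTT"
        assert extract_window(aln, 3, 3).get("s1").residues == "G"

    @pytest.mark.parametrize("start,end", [(5, 2), (0, 3), (1, 6)])
    def test_bad_bounds(self, start, end):
        with pytest.raises(ValidationError):
            extract_window(_aln("ACGTT"), start, end)


@st.composite
def alignments(draw):
    n_rows = draw(st.integers(2, 5))
    n_cols = draw(st.integers(2, 12))
    rows = [
        "".join(draw(st.sampled_from("ACGT-")) for _ in range(n_cols))
        for _ in range(n_rows)
    ]
    # ensure the anchor row keeps at least one column
    if set(rows[0]) == {"-"}:
        rows[0] = "A" + rows[0][1:]
    return _aln(*rows)


@given(alignments())
def test_fasta_round_trip_is_byte_identical(tmp_path_factory, aln):
    path = tmp_path_factory.mktemp("rt") / "x.fasta"
    write_fasta(aln, path)
    back = read_sequences(path, "fasta")
    assert [r.residues for r in back] == [r.residues for r in aln]
    assert back.ids == aln.ids


@given(alignments(), st.data())
def test_degap_commutes_with_window_on_mapped_coordinates(aln, data):
    degapped = degap(aln, "s1")
    start = data.draw(st.integers(1, degapped.n_cols))
    end = data.draw(st.integers(start, degapped.n_cols))
    via_degap = extract_window(degapped, start, end)
    # extracting the mapped original columns then degapping agrees
    lo, hi = degapped.column_map[start - 1], degapped.column_map[end - 1]
    via_window = degap(extract_window(aln, lo, hi), "s1")
    assert [r.residues for r in via_degap] == [r.residues for r in via_window]
    assert via_degap.column_map == via_window.column_map
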