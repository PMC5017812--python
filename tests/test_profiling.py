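"""Column profiles, coverage vs a brute-force matcher, discrimination calls."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lnaclamp.alignio import Alignment, SequenceRecord
from lnaclamp.errors import EmptySelectionError, ValidationError
from lnaclamp.oligo import IUPAC_SETS, Oligo
from lnaclamp.profiling import (
    column_profiles,
    coverage,
    discriminating_positions,
    group_by_identity,
    identity_percent,
)


def _aln(rows, groups=None):
    groups = groups or ["unknown"] * len(rows)
    return Alignment(
        tuple(
            SequenceRecord(f"s{i}", r, g)
            for i, (r, g) in enumerate(zip(rows, groups), start=1)
        )
    )


class TestColumnProfiles:
    def test_pure_column(self):
        (p,) = column_profiles(_aln(["A", "A", "A", "A"]))
        assert p.freqs["A"] == 1.0 and p.gap_fraction == 0.0

    def test_gap_excluded_from_frequency_denominator(self):
        (p,) = column_profiles(_aln(["T", "T", "C", "-"]))
        assert p.freqs["T"] == pytest.approx(2 / 3)
        assert p.freqs["C"] == pytest.approx(1 / 3)
        assert p.gap_fraction == 0.25
        assert p.n_effective == 3

    def test_ambiguity_contributes_fractionally(self):
        (p,) = column_profiles(_aln(["R", "G"]))
        assert p.freqs["A"] == pytest.approx(0.25)
        assert p.freqs["G"] == pytest.approx(0.75)

    def test_frequencies_sum_to_one(self):
        for p in column_profiles(_aln(["ANRT", "C-ST", "GYWT"])):
            assert sum(p.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_selection(self):
        with pytest.raises(EmptySelectionError):
            column_profiles(_aln(["A"]), "target")


def brute_force_covered(primer: str, row: str, max_mismatch: int) -> bool:
    """Independent oracle: per-position IUPAC set intersection."""
    mismatches = 0
    for p, s in zip(primer, row):
        ok = p != "-" and s != "-" and bool(IUPAC_SETS[p] & IUPAC_SETS[s])
        mismatches += 0 if ok else 1
    return mismatches <= max_mismatch


class TestCoverage:
    def test_identical_rows_fully_covered(self):
        aln = _aln(["ACGT"] * 3, groups=["g1", "g1", "g2"])
        rep = coverage(Oligo("p", "ACGT"), aln)
        assert rep.per_group["g1"] == (2, 2, 1.0)
        assert rep.overall[2] == 1.0

    def test_degenerate_primer_partial_coverage(self):
        rep = coverage(Oligo("p", "AYG"), _aln(["ACG", "ATG", "AAG"]))
        assert rep.overall == (2, 3, pytest.approx(2 / 3))

    def test_all_n_primer_covers_everything(self):
        rep = coverage(Oligo("p", "NNNN"), _aln(["ACGT", "RYSW", "TTTT"]))
        assert rep.overall[2] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(EmptySelectionError):
            coverage(Oligo("p", "ACGT"), [])

    def test_mismatch_list_reports_positions(self):
        rep = coverage(Oligo("p", "ACGT"), _aln(["ACGA"]))
        assert rep.mismatches[0].col == 4
        assert rep.mismatches[0].sequence_base == "A"

    @given(
        primer=st.text(alphabet="ACGTRYSWKMN", min_size=8, max_size=8),
        rows=st.lists(
            st.text(alphabet="ACGTN-", min_size=8, max_size=8), min_size=1, max_size=20
        ),
        allowance=st.integers(0, 8),
    )
    def test_matches_brute_force_oracle(self, primer, rows, allowance):
        rep = coverage(Oligo("p", primer), _aln(rows), max_mismatch=allowance)
        expected = sum(brute_force_covered(primer, r, allowance) for r in rows)
        assert rep.overall[0] == expected

    @given(
        primer=st.text(alphabet="ACGT", min_size=8, max_size=8),
        rows=st.lists(
            st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=1, max_size=10
        ),
    )
    def test_coverage_monotone_in_allowance(self, primer, rows):
        aln = _aln(rows)
        oligo = Oligo("p", primer)
        fracs = [
            coverage(oligo, aln, max_mismatch=k).overall[2]
            for k in range(len(primer) + 1)
        ]
        assert fracs[-1] == 1.0
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestDiscriminatingPositions:
    @staticmethod
    def _profiles(target_rows, nontarget_rows_by_group):
        tp = column_profiles(_aln(target_rows))
        ntp = {g: column_profiles(_aln(rows)) for g, rows in nontarget_rows_by_group.items()}
        return tp, ntp

    def test_fixed_difference_is_reported(self):
        tp, ntp = self._profiles(["G", "G"], {"plant": ["A", "A"]})
        (site,) = discriminating_positions(tp, ntp)
        assert (site.col, site.target_base, set(site.nontarget_bases)) == (1, "G", {"A"})

    def test_mixed_target_column_excluded(self):
        tp, ntp = self._profiles(["A", "G"], {"plant": ["C", "C"]})
        assert discriminating_positions(tp, ntp, target_purity=0.95) == []

    def test_stricter_purity_is_subset(self):
        tp, ntp = self._profiles(
            ["GAT", "GAT", "GAT", "GCT"], {"plant": ["ATA", "ATA"]}
        )
        strict = discriminating_positions(tp, ntp, 1.0, 1.0)
        loose = discriminating_positions(tp, ntp, 0.7, 0.7)
        assert set(s.col for s in strict) <= set(s.col for s in loose)

    def test_mismatched_columns_rejected(self):
        tp, _ = self._profiles(["GG"], {})
        _, ntp = self._profiles(["G"], {"plant": ["A"]})
        with pytest.raises(ValidationError):
            discriminating_positions(tp, ntp)

    def test_forward_fixture_reports_exactly_5_20_22(self, forward_fixture):
        aln = forward_fixture.alignment
        tp = column_profiles(aln, "target")
        ntp = {g: column_profiles(aln, g) for g in aln.groups() if g.startswith("nontarget")}
        sites = discriminating_positions(tp, ntp)
        assert [s.col for s in sites] == [5, 20, 22]
        assert [s.target_base for s in sites] == ["G", "T", "A"]
        assert [sorted(s.nontarget_bases) for s in sites] == [["A"], ["C"], ["G"]]


class TestGroupByIdentity:
    def test_identical_windows_share_a_type(self):
        aln = _aln(["AACC", "AACC", "AACC"], groups=["x", "y", "z"])
        types = group_by_identity(aln, window=(1, 4))
        assert types == {"a": ("s1", "s2", "s3")}

    def test_distinct_rows_get_singletons_in_order(self):
        types = group_by_identity(_aln(["AA", "CC", "GG"]))
        assert list(types) == ["a", "b", "c"]
        assert types["b"] == ("s2",)

    def test_gap_stripped_comparison(self):
        types = group_by_identity(_aln(["A-C", "AC-"]))
        assert len(types) == 1

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            group_by_identity(_aln(["ACGT"]), window=(3, 2))


class TestIdentityPercent:
    @pytest.mark.parametrize(
        "matches,length,expected",
        [(191, 192, 99), (204, 218, 94), (0, 100, 0), (248, 248, 100), (1, 200, 1)],
    )
    def test_rounding_half_away_from_zero(self, matches, length, expected):
        assert identity_percent(matches, length) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ZeroDivisionError):
            identity_percent(0, 0)

    def test_matches_exceeding_length_rejected(self):
        with pytest.raises(ValidationError):
            identity_percent(5, 4)
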