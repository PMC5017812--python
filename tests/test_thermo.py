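"""LNA-aware nearest-neighbor Tm model: oracles, symmetries, monotonicity."""

import csv
import math
from importlib import resources

import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given
from hypothesis import strategies as st

from lnaclamp.errors import DesignInfeasibleError, ValidationError
from lnaclamp.oligo import Oligo, reverse_complement
from lnaclamp.thermo import (
    Conditions,
    TmEstimate,
    nn_sums,
    recommend_clamp_annealing,
    tm_oligo,
)


def _load_tsv(name):
    text = resources.files("lnaclamp.data").joinpath(name).read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith(("#", "stack\t"))
    ]
    return {k: (float(h), float(s)) for k, h, s in rows}


def naive_nn_sums(bases, lna_positions):
    """Independent re-summation straight from the shipped tables."""
    dna = _load_tsv("dna_nn_unified.tsv")
    for stack in list(dna):
        if not stack.startswith(("init", "sym")):
            dna.setdefault(reverse_complement(stack), dna[stack])
    lna = _load_tsv("lna_stack_increments.tsv")
    dh = ds = 0.0
    for end in (bases[0], bases[-1]):
        key = "init_AT" if end in "AT" else "init_GC"
        dh, ds = dh + dna[key][0], ds + dna[key][1]
    if bases == reverse_complement(bases):
        dh, ds = dh + dna["sym"][0], ds + dna["sym"][1]
    for i in range(len(bases) - 1):
        st_ = bases[i : i + 2]
        dh, ds = dh + dna[st_][0], ds + dna[st_][1]
        if (i + 1) in lna_positions or (i + 2) in lna_positions:
            dh, ds = dh + lna[st_][0], ds + lna[st_][1]
    return dh, ds


class TestEngineOracles:
    @given(
        bases=st.text(alphabet="ACGT", min_size=8, max_size=12),
        lna=st.sets(st.integers(1, 8), max_size=4),
    )
    def test_nn_sums_match_independent_loop(self, bases, lna):
        oligo = Oligo("x", bases).with_lna(lna)
        got = nn_sums(oligo.bases, oligo.chemistry)
        want = naive_nn_sums(bases, lna)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)

    @pytest.mark.parametrize(
        "seq",
        [
            "CTTAAACTCAGCGGGTAGTCCC",
            "TCCTCCGCTTATTGATATGC",
            "CTTGGTCATTTAGAGGAAGTAA",
            "ATATATATATAA",
        ],
    )
    def test_dna_only_matches_biopython_santalucia(self, seq):
        cond = Conditions(monovalent_mM=115.0, oligo_concentration_M=0.25e-6)
        mine = tm_oligo(Oligo("x", seq), cond).tm
        # same model: unified NN table + 0.368*(N-1)*ln[Na+] entropy correction
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=115, dnac1=125, dnac2=125, saltcorr=5)
        assert mine == pytest.approx(ref, abs=1e-6)

    def test_self_complementary_duplex_matches_biopython(self):
        # palindromes get the symmetry entropy term and CT (not CT/4)
        cond = Conditions(monovalent_mM=115.0, oligo_concentration_M=0.25e-6)
        mine = tm_oligo(Oligo("x", "ATATATATATAT"), cond).tm
        ref = mt.Tm_NN(
            "ATATATATATAT", nn_table=mt.DNA_NN3, Na=115,
            dnac1=250, dnac2=0, selfcomp=True, saltcorr=5,
        )
        assert mine == pytest.approx(ref, abs=1e-6)


class TestModelProperties:
    def test_tm_increases_with_salt(self):
        seq = Oligo("x", "CTTGGTCATTTAGAGGAAGTAA")
        tms = [
            tm_oligo(seq, Conditions(monovalent_mM=na)).tm
            for na in (25, 50, 115, 300, 600)
        ]
        assert all(a < b for a, b in zip(tms, tms[1:]))

    def test_tm_increases_with_length_fixed_composition(self):
        tms = [
            tm_oligo(Oligo("x", "ACGT" * k)).tm
            for k in range(2, 7)
        ]
        assert all(a < b for a, b in zip(tms, tms[1:]))

    @given(st.text(alphabet="ACGT", min_size=8, max_size=16))
    def test_reverse_complement_symmetry(self, seq):
        assert tm_oligo(Oligo("x", seq)).tm == pytest.approx(
            tm_oligo(Oligo("x", reverse_complement(seq))).tm, abs=1e-9
        )

    def test_lna_raises_tm(self):
        dna = Oligo("p", "CTTGGTCATTTAGAGGAAGTAA")
        lna = dna.with_lna({5, 20, 22})
        assert tm_oligo(lna).tm > tm_oligo(dna).tm


class TestDegenerateExpansion:
    def test_non_degenerate_has_point_estimate(self):
        est = tm_oligo(Oligo("x", "ACGTACGTAC"))
        assert est.n_expansions == 1
        assert est.tm_min == est.tm == est.tm_max

    def test_expansion_count_and_range(self):
        est = tm_oligo(Oligo("x", "CTYGGTCATTTAGAGGAASTAA"))
        assert est.n_expansions == 4
        assert est.tm_min <= est.tm <= est.tm_max
        assert est.tm_max > est.tm_min

    def test_expansion_cap_overflow(self):
        with pytest.raises(ValidationError, match="cap"):
            tm_oligo(Oligo("x", "NNNNNNNNNN"))  # 4^10 expansions

    def test_short_oligo_rejected(self):
        with pytest.raises(ValidationError, match=">= 8"):
            tm_oligo(Oligo("x", "ACGT"))


def _est(tm, tm_min=None, tm_max=None):
    return TmEstimate(
        tm=tm,
        tm_min=tm_min if tm_min is not None else tm,
        tm_max=tm_max if tm_max is not None else tm,
        n_expansions=1 if tm_min is None else 4,
        conditions=Conditions(),
    )


class TestClampAnnealingRecommendation:
    def test_clamp_tm_dominates_when_primers_cool(self):
        rec = recommend_clamp_annealing((_est(60, 59, 62), _est(60)), _est(70), 4)
        assert rec == 70

    def test_hot_primers_make_design_infeasible(self):
        with pytest.raises(DesignInfeasibleError):
            recommend_clamp_annealing((_est(66, 64, 68), _est(60)), _est(70), 4)

    def test_clamp_cooler_than_primers_rejected(self):
        with pytest.raises(DesignInfeasibleError):
            recommend_clamp_annealing((_est(62), _est(60)), _est(60), 4)
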