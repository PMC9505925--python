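"""Cohort statistics: length shares, splice sites, BP calls, composition,
unique-sequence tallies and lariat geometry."""
import pytest
from hypothesis import given, strategies as st

from tinyintron.genome_io import IntronRecord
from tinyintron.intron_features import (
    BPCall,
    LengthDistribution,
    bp_position_distribution,
    build_pfm,
    call_branchpoint,
    classify_lengths,
    composition,
    lariat_geometry,
    tally_unique_introns,
    terminal_dinucleotides,
)

REPRESENTATIVE = "GUAAUUUUUAUAUAG"  # the most abundant 15-nt tiny intron


def _rec(seq, flank5="", flank3=""):
    return IntronRecord("g", "c", 1, len(seq), "+", seq, flank5=flank5, flank3=flank3)


class TestLengthDistribution:
    @pytest.mark.parametrize(
        "counts, shares",
        [
            ({15: 8173, 16: 633}, {15: 92.81, 16: 7.19}),
            ({15: 3, 16: 1}, {15: 75.00, 16: 25.00}),
            ({15: 1}, {15: 100.00}),
        ],
    )
    def test_shares_from_counts(self, counts, shares):
        assert LengthDistribution.from_counts(counts).shares == shares

    def test_classify_over_records(self):
        dist = classify_lengths([_rec("GU" + "A" * 11 + "AG"), _rec("GU" + "A" * 12 + "AG")])
        assert dist.counts == {15: 1, 16: 1}

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            classify_lengths([])

    @given(st.lists(st.integers(8, 20), min_size=1, max_size=200))
    def test_shares_sum_to_100(self, lengths):
        dist = classify_lengths(["A" * n for n in lengths])
        assert abs(sum(dist.shares.values()) - 100.0) <= 0.05


class TestTerminalDinucleotides:
    @pytest.mark.parametrize(
        "seqs, frac",
        [
            ([REPRESENTATIVE], 1.0),
            (["AUAAUUUUUAUAUAC"], 0.0),
            ([REPRESENTATIVE, "GUAAAG", "AUUUAC", "CUUUAG"], 0.5),
        ],
    )
    def test_gu_ag_fraction(self, seqs, frac):
        assert terminal_dinucleotides(seqs).gu_ag_fraction == frac

    def test_too_short_excluded_with_warning(self, caplog):
        res = terminal_dinucleotides(["GUA", REPRESENTATIVE])
        assert res.n_excluded == 1 and res.n_used == 1


class TestPFM:
    def test_identical_sequences_are_fully_informative(self):
        pfm = build_pfm([_rec("GUAG"), _rec("GUAG")], length_class=4, flank=0)
        assert (pfm.info_content == 2.0).all()
        assert pfm.freqs.loc["I1", "G"] == 1.0
        assert pfm.freqs.sum(axis=1).sub(1.0).abs().max() < 1e-9

    def test_half_half_column_is_one_bit(self):
        pfm = build_pfm([_rec("AG"), _rec("UG")], length_class=2, flank=0)
        assert pfm.info_content["I1"] == pytest.approx(1.0)

    def test_entropy_by_hand(self):
        # first column A,A,U,G: freqs .5/.25/.25, info = 2 - 1.5 = 0.5 bits
        pfm = build_pfm([_rec(s) for s in ("AAAA", "AAAA", "UAAA", "GAAA")],
                        length_class=4, flank=0)
        assert pfm.freqs.loc["I1", "A"] == 0.5
        assert pfm.freqs.loc["I1", "U"] == 0.25
        assert pfm.info_content["I1"] == pytest.approx(0.5)

    def test_flank_columns_and_n_exclusion(self):
        pfm = build_pfm([_rec("GUAG", flank5="CC", flank3="A")], length_class=4, flank=2)
        assert list(pfm.freqs.index) == ["5'E-2", "5'E-1", "I1", "I2", "I3", "I4",
                                         "3'E+1", "3'E+2"]
        # missing flank position padded with N and excluded from counts
        assert pfm.n_per_column["3'E+2"] == 0 and pfm.info_content["3'E+2"] == 0.0

    def test_missing_class_is_error(self):
        with pytest.raises(ValueError):
            build_pfm([_rec("GUAG")], length_class=15)


class TestBranchpointCall:
    def test_canonical_position(self):
        call = call_branchpoint(REPRESENTATIVE)
        assert call.position == 10 and call.canonical

    def test_canonical_wins_over_neighbour(self):
        call = call_branchpoint("GUAAUUUUAAUUUAG")  # A at 9 and 10
        assert call.position == 10 and call.canonical

    def test_no_adenosine_is_no_call(self):
        call = call_branchpoint("GUUUUUUUUUUUUAG")
        assert not call.is_call

    def test_fallback_prefers_3prime_on_tie(self):
        # A at 9 and 11, nothing at 10: ties break toward 3'
        call = call_branchpoint("GUUUUUUUAUAUUAG")
        assert call.position == 11 and not call.canonical

    def test_window_zero_disables_fallback(self):
        seq = "GUAAUUUUAUUUUAG"  # A at 9, not at 10
        assert call_branchpoint(seq).position == 9
        assert not call_branchpoint(seq, window=(0, 0)).is_call


class TestBPDistribution:
    def test_printed_cohort_arithmetic(self):
        calls = [10] * 8005 + [11] * 442 + [9] * 168 + [12] * 191
        dist = bp_position_distribution(calls, total=8806)
        assert dist[10] == (8005, 90.90)
        assert dist[11] == (442, 5.02)
        assert dist[9] == (168, 1.91)
        assert dist[12] == (191, 2.17)

    def test_single_call(self):
        assert bp_position_distribution([10], total=1)[10] == (1, 100.00)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            bp_position_distribution([10], total=0)


class TestComposition:
    @pytest.mark.parametrize(
        "seq, au", [(REPRESENTATIVE, 86.67), ("GGGG", 0.0), ("AUAU", 100.0)]
    )
    def test_au_content(self, seq, au):
        res = composition([seq])
        assert res.au_pooled_percent == au == res.au_mean_percent

    def test_all_n_is_error(self):
        with pytest.raises(ValueError):
            composition(["NNNN"])

    def test_n_introns_excluded(self):
        res = composition(["AUAU", "NNNN"])
        assert res.n_used == 1 and res.n_excluded == 1


class TestUniqueTally:
    def test_class_denominator_share(self):
        filler = "GUAAAAAAAAUAUAG"
        seqs = [REPRESENTATIVE] * 127 + [filler] * (8173 - 127)
        tally = tally_unique_introns(seqs, denominator="class")
        assert (REPRESENTATIVE, 127, 1.55) in tally

    def test_all_identical(self):
        assert tally_unique_introns(["AUAU"] * 5) == [("AUAU", 5, 100.00)]

    def test_tie_breaks_lexicographically(self):
        tally = tally_unique_introns(["CCCC", "AAAA"])
        assert [s for s, _, _ in tally] == ["AAAA", "CCCC"]


class TestLariat:
    def test_15nt_gives_10nt_loop_5nt_tail(self):
        lm = lariat_geometry(REPRESENTATIVE, BPCall(10, True, (4, 12)))
        assert (lm.loop_length, lm.tail_length, lm.branch_nt) == (10, 5, "A")

    def test_16nt_gives_11nt_loop_5nt_tail(self):
        seq = "GUAAUUUUUUAUAUAG"
        call = call_branchpoint(seq)
        lm = lariat_geometry(seq, call)
        assert (lm.loop_length, lm.tail_length) == (11, 5)

    def test_terminal_bp_is_degenerate(self):
        lm = lariat_geometry("GUUUUUUUUUUUUUA", BPCall(15, False, (4, 12)))
        assert lm.tail_length == 0 and lm.degenerate

    def test_no_call_is_error(self):
        with pytest.raises(ValueError):
            lariat_geometry(REPRESENTATIVE, BPCall(None, False, (4, 12)))

    @given(st.text(alphabet="ACGU", min_size=8, max_size=20))
    def test_loop_plus_tail_equals_length(self, seq):
        call = call_branchpoint(seq)
        if call.is_call:
            lm = lariat_geometry(seq, call)
            assert lm.loop_length + lm.tail_length == len(seq)
            assert lm.branch_nt == "A"
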