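"""FASTA/GFF3 parsing and strand-aware intron extraction."""
import logging

import pytest
from hypothesis import given, strategies as st

from tinyintron.genome_io import (
    GeneRecord,
    extract_introns,
    parse_fasta,
    parse_gff,
    read_introns_tsv,
    write_intron_outputs,
)
from tinyintron._util import reverse_complement_dna

# plus-strand intron at 31..45, minus-strand intron at 66..80 (whose
# plus-strand slice CTATATAAAAATTAC reverse-complements to the canonical
# GU...AG intron)
_CHROM = "A" * 30 + "GTAAGTTTTTATAAG" + "A" * 20 + "CTATATAAAAATTAC" + "A" * 40


@pytest.fixture
def genome(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">ctg1\n" + _CHROM + "\n")
    return parse_fasta(p)


def test_parse_fasta_linewrap_and_casefold(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">s1\nac\ngt\n")
    assert parse_fasta(p).records == {"s1": "ACGT"}


def test_parse_fasta_duplicate_id_is_error(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">s1\nACGT\n>s1\nGGGG\n")
    with pytest.raises(ValueError, match="duplicate"):
        parse_fasta(p)


def test_parse_fasta_empty_is_error(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text("")
    with pytest.raises(ValueError):
        parse_fasta(p)


_GFF = """##gff-version 3
ctg1\tt\tgene\t1\t100\t.\t+\t.\tID=geneA
ctg1\tt\texon\t1\t40\t.\t+\t.\tID=geneA.e1;Parent=geneA
ctg1\tt\texon\t56\t100\t.\t+\t.\tID=geneA.e2;Parent=geneA
ctg1\tt\tintron\t41\t55\t.\t+\t.\tID=geneA.i1;Parent=geneA
ctg1\tt\tgene\t120\t160\t.\t-\t.\tID=geneB
ctg1\tt\tgene\t200\t300\t.\t+\t.\tID=geneC
ctg1\tt\tmRNA\t200\t300\t.\t+\t.\tID=geneC.t1;Parent=geneC
ctg1\tt\tintron\t240\t254\t.\t+\t.\tID=geneC.t1.i1;Parent=geneC.t1
ctg1\tt\tintron\t400\t414\t.\t+\t.\tID=orphan;Parent=nosuchgene
"""


def test_parse_gff_explicit_introns(tmp_path, caplog):
    p = tmp_path / "a.gff3"
    p.write_text(_GFF)
    with caplog.at_level(logging.WARNING):
        genes = {g.gene_id: g for g in parse_gff(p, mode="explicit-introns")}
    assert genes["geneA"].intron_intervals == ((41, 55),)
    # parent resolved through the mRNA level
    assert genes["geneC"].intron_intervals == ((240, 254),)
    # gene with no exon/intron rows is retained, intron-less
    assert genes["geneB"].intron_intervals == ()
    assert "orphan" in caplog.text


def test_parse_gff_exon_gaps(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(_GFF)
    genes = {g.gene_id: g for g in parse_gff(p, mode="exon-gaps")}
    # gap between exons 1..40 and 56..100 is the intron 41..55
    assert genes["geneA"].intron_intervals == ((41, 55),)


def test_parse_gff_modes_agree_where_both_annotated(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(_GFF)
    explicit = {g.gene_id: g.intron_intervals for g in parse_gff(p, "explicit-introns")}
    gaps = {g.gene_id: g.intron_intervals for g in parse_gff(p, "exon-gaps")}
    assert explicit["geneA"] == gaps["geneA"]


def test_parse_gff_malformed_coordinates(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nctg1\tt\tgene\t50\t10\t.\t+\t.\tID=g\n")
    with pytest.raises(ValueError, match="start > end"):
        parse_gff(p)


def test_extract_plus_strand_t_to_u(genome):
    gene = GeneRecord("gp", "ctg1", 25, 60, "+", ((31, 45),))
    (rec,) = extract_introns(genome, [gene], flank=2)
    assert rec.sequence == "GUAAGUUUUUAUAAG"
    assert rec.length == 15 == len(rec.sequence)


def test_extract_minus_strand_reverse_complement(genome):
    gene = GeneRecord("gm", "ctg1", 60, 90, "-", ((66, 80),))
    (rec,) = extract_introns(genome, [gene], flank=2)
    assert rec.sequence == "GUAAUUUUUAUAUAG"
    assert (rec.start, rec.end) == (66, 80)  # genomic coords stay plus-strand


def test_extract_flank_truncated_at_sequence_start(genome):
    gene = GeneRecord("gt", "ctg1", 1, 20, "+", ((1, 15),))
    (rec,) = extract_introns(genome, [gene], flank=4)
    assert rec.flank5 == "" and rec.flank5_truncated
    assert len(rec.flank3) == 4 and not rec.flank3_truncated


def test_extract_out_of_bounds_names_gene():
    genome = {"c": "ACGTACGT"}
    # gene annotated past the end of its sequence
    gene = GeneRecord("badgene", "c", 1, 20, "+", ((5, 20),))
    with pytest.raises(ValueError, match="badgene"):
        extract_introns(genome, [gene])


def test_write_then_reread_round_trip(genome, tmp_path):
    genes = [
        GeneRecord("gp", "ctg1", 25, 60, "+", ((31, 45),)),
        GeneRecord("gm", "ctg1", 60, 90, "-", ((66, 80),)),
    ]
    introns = extract_introns(genome, genes, flank=3)
    paths = write_intron_outputs(introns, tmp_path / "out")
    fasta_seqs = [
        line.strip() for line in paths["fasta"].read_text().splitlines()
        if not line.startswith(">")
    ]
    assert fasta_seqs == [it.sequence for it in introns]
    assert read_introns_tsv(paths["tsv"]) == introns


def test_write_empty_outputs(tmp_path):
    paths = write_intron_outputs([], tmp_path / "out")
    assert paths["fasta"].read_text() == ""
    assert paths["tsv"].read_text().startswith("gene_id\t")
    assert read_introns_tsv(paths["tsv"]) == []


@given(
    seq=st.text(alphabet="ACGT", min_size=30, max_size=60),
    lo=st.integers(5, 10),
    length=st.integers(8, 16),
)
def test_strand_mirror_property(seq, lo, length):
    """Extracting from a genome and from its reverse complement (mirrored
    coordinates, flipped strand) yields the same transcript-oriented RNA."""
    hi = lo + length - 1
    n = len(seq)
    fwd_gene = GeneRecord("g", "c", 1, n, "+", ((lo, hi),))
    rev_gene = GeneRecord("g", "c", 1, n, "-", ((n - hi + 1, n - lo + 1),))
    (fwd,) = extract_introns({"c": seq}, [fwd_gene], flank=3)
    (rev,) = extract_introns({"c": reverse_complement_dna(seq)}, [rev_gene], flank=3)
    assert fwd.sequence == rev.sequence
    assert fwd.flank5 == rev.flank5 and fwd.flank3 == rev.flank3


def test_simulator_round_trip_both_modes(small_sim, small_sim_paths):
    """Every planted intron is recovered exactly, from both annotation modes."""
    genome = parse_fasta(small_sim_paths["fasta"])
    truth_by_coord = {
        (t.seq_id, t.start, t.end, t.strand): t.sequence for t in small_sim.truth.introns
    }
    for mode in ("explicit-introns", "exon-gaps"):
        genes = parse_gff(small_sim_paths["gff"], mode=mode)
        introns = extract_introns(genome, genes)
        got = {(i.seq_id, i.start, i.end, i.strand): i.sequence for i in introns}
        assert got == truth_by_coord
    strands = {t.strand for t in small_sim.truth.introns}
    assert strands == {"+", "-"}
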