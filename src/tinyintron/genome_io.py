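"""Genome FASTA / GFF3 input and strand-aware intron extraction.

Coordinates are 1-based inclusive on the plus strand externally (the GFF3
convention); slicing is done 0-based half-open internally, with the
conversion confined to this module.  Extracted introns are reported
5'->3' in transcript orientation on the RNA alphabet (T folded to U);
minus-strand records are reverse-complemented but keep their plus-strand
genomic start/end.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from ._util import dna_to_rna, reverse_complement_dna

logger = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")

PARSE_MODES = ("explicit-introns", "exon-gaps")


class GenomeSequenceSet(Mapping[str, str]):
    """Uppercase DNA sequences keyed by unique sequence id."""

    def __init__(self, records: dict[str, str]):
        for sid, seq in records.items():
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
        self.records = dict(records)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its (possibly empty) ordered intron intervals.

    start/end and all intervals are 1-based inclusive genomic coordinates
    on the plus strand, regardless of the gene's own strand.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    intron_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for lo, hi in self.intron_intervals:
            if lo > hi:
                raise ValueError(f"gene {self.gene_id}: intron start > end")
            if not (self.start <= lo and hi <= self.end):
                raise ValueError(f"gene {self.gene_id}: intron outside gene body")
            if prev_end is not None and lo <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping/unsorted introns")
            prev_end = hi

    @property
    def gene_length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_introns(self) -> int:
        return len(self.intron_intervals)


@dataclass(frozen=True)
class IntronRecord:
    """One extracted intron, 5'->3' in transcript orientation, RNA alphabet."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    flank5: str = ""
    flank3: str = ""
    flank5_truncated: bool = False
    flank3_truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def parse_fasta(path: str | Path) -> GenomeSequenceSet:
    """Load a multi-record FASTA, fold to uppercase, map odd symbols to N."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _DNA_OK:
            bad = sorted(set(seq) - _DNA_OK)
            logger.warning("sequence %s: mapping non-ACGTN symbols %s to N", rec.id, bad)
            seq = "".join(c if c in _DNA_OK else "N" for c in seq)
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequenceSet(records)


def _check_gff_coords(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: malformed coordinates start > end")


def parse_gff(path: str | Path, mode: str = "explicit-introns") -> list[GeneRecord]:
    """Read gene models from GFF3.

    mode="explicit-introns": intron features (type 'intron') are attached to
    their gene via the Parent chain; an intron whose parent gene cannot be
    resolved is skipped with a warning.
    mode="exon-gaps": introns are the gaps between consecutive exons of the
    same gene.
    Genes with zero introns are retained.
    """
    if mode not in PARSE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {PARSE_MODES}")
    _check_gff_coords(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    introns_by_gene: dict[str, list[tuple[int, int]]] = {}
    if mode == "explicit-introns":
        for feat in db.features_of_type("intron"):
            parents = list(db.parents(feat, featuretype="gene"))
            if not parents:
                logger.warning(
                    "intron %s at %s:%d-%d has no resolvable gene parent; skipped",
                    feat.id, feat.seqid, feat.start, feat.end,
                )
                continue
            introns_by_gene.setdefault(parents[0].id, []).append((feat.start, feat.end))
    else:
        for gene in db.features_of_type("gene"):
            exons = sorted(
                db.children(gene, featuretype="exon"), key=lambda f: f.start
            )
            gaps = []
            for prev, nxt in zip(exons, exons[1:]):
                if nxt.start > prev.end + 1:
                    gaps.append((prev.end + 1, nxt.start - 1))
            if gaps:
                introns_by_gene[gene.id] = gaps

    genes: list[GeneRecord] = []
    for gene in db.features_of_type("gene"):
        ivs = sorted(introns_by_gene.get(gene.id, []))
        kept = []
        for lo, hi in ivs:
            if gene.start <= lo <= hi <= gene.end:
                kept.append((lo, hi))
            else:
                logger.warning(
                    "gene %s: intron %d-%d outside gene body; skipped", gene.id, lo, hi
                )
        genes.append(
            GeneRecord(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                intron_intervals=tuple(kept),
            )
        )
    return genes


def _slice(seq: str, start: int, end: int) -> str:
    """1-based inclusive genomic slice."""
    return seq[start - 1 : end]


def extract_introns(
    genome: GenomeSequenceSet | Mapping[str, str],
    genes: Iterable[GeneRecord],
    flank: int = 6,
) -> list[IntronRecord]:
    """Extract every intron interval as an RNA-alphabet transcript-oriented record.

    Flanking exonic context of width `flank` is taken from the adjacent
    genomic sequence (transcript orientation) and truncated, with a flag,
    at sequence ends.
    """
    out: list[IntronRecord] = []
    for gene in genes:
        if gene.seq_id not in genome:
            raise KeyError(f"gene {gene.gene_id}: sequence {gene.seq_id!r} not in genome")
        chrom = genome[gene.seq_id]
        n = len(chrom)
        for lo, hi in gene.intron_intervals:
            if not (1 <= lo <= hi <= n):
                raise ValueError(
                    f"gene {gene.gene_id}: intron {lo}-{hi} out of bounds of "
                    f"{gene.seq_id} (length {n})"
                )
            body = _slice(chrom, lo, hi)
            up_lo = max(1, lo - flank)
            up = _slice(chrom, up_lo, lo - 1)
            down_hi = min(n, hi + flank)
            down = _slice(chrom, hi + 1, down_hi)
            if gene.strand == "+":
                seq, f5, f3 = body, up, down
                f5_trunc = len(up) < flank
                f3_trunc = len(down) < flank
            else:
                seq = reverse_complement_dna(body)
                f5 = reverse_complement_dna(down)
                f3 = reverse_complement_dna(up)
                f5_trunc = len(down) < flank
                f3_trunc = len(up) < flank
            out.append(
                IntronRecord(
                    gene_id=gene.gene_id,
                    seq_id=gene.seq_id,
                    start=lo,
                    end=hi,
                    strand=gene.strand,
                    sequence=dna_to_rna(seq),
                    flank5=dna_to_rna(f5),
                    flank3=dna_to_rna(f3),
                    flank5_truncated=f5_trunc,
                    flank3_truncated=f3_trunc,
                )
            )
    return out


_TSV_COLUMNS = [
    "gene_id", "seq_id", "start", "end", "strand", "length", "sequence",
    "flank5", "flank3", "flank5_truncated", "flank3_truncated",
]


def write_intron_outputs(introns: Iterable[IntronRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write introns.fasta (RNA) and introns.tsv into out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    introns = list(introns)
    fasta = out_dir / "introns.fasta"
    with open(fasta, "w", newline="\n") as fh:
        for it in introns:
            fh.write(f">{it.gene_id}|{it.seq_id}|{it.start}-{it.end}|{it.strand}\n")
            fh.write(it.sequence + "\n")
    tsv = out_dir / "introns.tsv"
    df = pd.DataFrame(
        [
            {
                "gene_id": it.gene_id, "seq_id": it.seq_id, "start": it.start,
                "end": it.end, "strand": it.strand, "length": it.length,
                "sequence": it.sequence, "flank5": it.flank5, "flank3": it.flank3,
                "flank5_truncated": it.flank5_truncated,
                "flank3_truncated": it.flank3_truncated,
            }
            for it in introns
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
    return {"fasta": fasta, "tsv": tsv}


def read_introns_tsv(path: str | Path) -> list[IntronRecord]:
    """Re-load IntronRecords from an introns.tsv written by write_intron_outputs."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"flank5": str, "flank3": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            IntronRecord(
                gene_id=str(row.gene_id), seq_id=str(row.seq_id),
                start=int(row.start), end=int(row.end), strand=str(row.strand),
                sequence=str(row.sequence), flank5=str(row.flank5),
                flank3=str(row.flank3),
                flank5_truncated=bool(row.flank5_truncated),
                flank3_truncated=bool(row.flank3_truncated),
            )
        )
    return out
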