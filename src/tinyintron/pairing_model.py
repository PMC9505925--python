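"""snRNA-intron base-pairing model of the spliceosomal active site.

Before the first transesterification the intron is clamped by three RNA
duplexes: the 5' splice-site region pairs with the U1 snRNA 5' motif
(during early recognition) and with the U6 ACAGAGA box (in the activated
spliceosome), and the branchpoint region pairs with the U2 GUAGUA motif
forming the branch helix, from which the branchpoint adenosine (BP-A)
bulges out unpaired.  This module scores those antiparallel duplexes with a
small pair-type taxonomy: Watson-Crick A-U / G-C, the G-U wobble, and the
non-canonical U.U pair (treated as a genuine, weaker pair, as it commonly
is in non-coding RNA duplexes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .genome_io import IntronRecord
from .intron_features import BPCall

logger = logging.getLogger(__name__)


class PairType(Enum):
    WC = "WC"
    WOBBLE = "WOBBLE"
    NONCANONICAL_UU = "NONCANONICAL_UU"
    NONE = "NONE"


#: diagram glyphs: | Watson-Crick, : wobble, . . -> bullet for U.U
GLYPH = {
    PairType.WC: "|",
    PairType.WOBBLE: ":",
    PairType.NONCANONICAL_UU: "•",
    PairType.NONE: " ",
}

DEFAULT_WEIGHTS: dict[PairType, float] = {
    PairType.WC: 2.0,
    PairType.WOBBLE: 1.0,
    PairType.NONCANONICAL_UU: 1.0,
    PairType.NONE: 0.0,
}

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_type(b1: str, b2: str) -> PairType:
    """Classify a base pair; symmetric in its arguments."""
    b1, b2 = b1.upper(), b2.upper()
    if b1 not in "ACGU" or b2 not in "ACGU":
        logger.warning("non-RNA base in pair (%s, %s); treated as unpaired", b1, b2)
        return PairType.NONE
    if (b1, b2) in _WC:
        return PairType.WC
    if (b1, b2) in _WOBBLE:
        return PairType.WOBBLE
    if b1 == "U" and b2 == "U":
        return PairType.NONCANONICAL_UU
    return PairType.NONE


@dataclass(frozen=True)
class SnrnaMotif:
    name: str
    sequence: str  # 5'->3' uppercase RNA

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGU"):
            raise ValueError(f"motif {self.name}: not an RNA sequence")


#: built-in registry of the conserved snRNA recognition motifs
MOTIFS: dict[str, SnrnaMotif] = {
    "U1_5p": SnrnaMotif("U1_5p", "ACUUACCU"),
    "U2_BP": SnrnaMotif("U2_BP", "GUAGUA"),
    "U6_ACAGAGA": SnrnaMotif("U6_ACAGAGA", "ACAGAGA"),
}


@dataclass(frozen=True)
class DuplexAlignment:
    """An antiparallel region/motif duplex at one offset.

    `pairs` holds (region_pos, motif_pos, PairType) with 1-based positions in
    the original region and motif; region positions increase while motif
    positions decrease (antiparallel, monotone).  The bulged position, if
    any, participates in no pair.  `region_origin` gives the coordinate of
    region position 1 in the caller's frame (e.g. intron coordinates), for
    rendering only.
    """

    region: str
    motif: SnrnaMotif
    offset: int
    pairs: tuple[tuple[int, int, PairType], ...]
    bulge: int | None
    score: float
    region_origin: int = 1

    @property
    def n_paired(self) -> int:
        return sum(1 for _, _, t in self.pairs if t is not PairType.NONE)

    def longest_run(self) -> int:
        run = best = 0
        for _, _, t in self.pairs:
            run = run + 1 if t is not PairType.NONE else 0
            best = max(best, run)
        return best


def _score_offset(
    region_eff: str,
    eff_to_orig: Sequence[int],
    motif: SnrnaMotif,
    offset: int,
    weights: Mapping[PairType, float],
) -> tuple[float, tuple[tuple[int, int, PairType], ...]]:
    m = len(motif.sequence)
    pairs = []
    score = 0.0
    for i_eff, orig_pos in enumerate(eff_to_orig):
        j = i_eff - offset  # index into the reversed motif
        if 0 <= j < m:
            motif_pos = m - j  # 1-based position in the motif, 5'->3'
            t = pair_type(region_eff[i_eff], motif.sequence[motif_pos - 1])
            pairs.append((orig_pos, motif_pos, t))
            score += weights.get(t, 0.0)
    return score, tuple(pairs)


def duplex_align(
    region: str,
    motif: SnrnaMotif | str,
    weights: Mapping[PairType, float] | None = None,
    bulge_at: int | None = None,
    region_origin: int = 1,
) -> DuplexAlignment:
    """Best antiparallel duplex between `region` and `motif`.

    All offsets of the reversed motif along the region are scored
    exhaustively; the optional single bulge at 1-based region position
    `bulge_at` (the BP-A) is excluded from pairing and the motif is read
    through contiguously across it.  Ties break toward the smallest offset,
    then the longest contiguous paired run.
    """
    if len(region) < 2:
        raise ValueError("region must be at least 2 nt")
    if isinstance(motif, str):
        motif = SnrnaMotif("ad-hoc", motif)
    weights = dict(DEFAULT_WEIGHTS) if weights is None else dict(weights)
    if any(w < 0 for w in weights.values()):
        raise ValueError("pair weights must be non-negative")
    weights[PairType.NONE] = 0.0

    if bulge_at is not None and not (1 <= bulge_at <= len(region)):
        raise ValueError(f"bulge position {bulge_at} outside region of length {len(region)}")
    eff_to_orig = [p for p in range(1, len(region) + 1) if p != bulge_at]
    region_eff = "".join(region[p - 1] for p in eff_to_orig)

    m = len(motif.sequence)
    best: tuple[tuple[float, int, int], int] | None = None  # (key, offset)
    best_pairs: tuple = ()
    best_score = 0.0
    for offset in range(-(m - 1), len(region_eff)):
        score, pairs = _score_offset(region_eff, eff_to_orig, motif, offset, weights)
        key = (score, -offset, _run_length(pairs))
        if best is None or key > best[0]:
            best = (key, offset)
            best_pairs, best_score = pairs, score
    assert best is not None
    return DuplexAlignment(
        region=region, motif=motif, offset=best[1], pairs=best_pairs,
        bulge=bulge_at, score=best_score, region_origin=region_origin,
    )


def _run_length(pairs: Sequence[tuple[int, int, PairType]]) -> int:
    run = best = 0
    for _, _, t in pairs:
        run = run + 1 if t is not PairType.NONE else 0
        best = max(best, run)
    return best


def branch_helix(
    intron: IntronRecord | str,
    bp: BPCall,
    motif: SnrnaMotif | None = None,
    window: tuple[int, int] = (4, 2),
    weights: Mapping[PairType, float] | None = None,
) -> DuplexAlignment:
    """Branch-helix duplex: the branch region (default b-4 .. b+2, clipped to
    the intron) paired with the U2 GUAGUA motif, with the BP-A bulged out."""
    if not bp.is_call:
        raise ValueError("branch helix requires a BP call")
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    b = bp.position
    assert b is not None
    motif = motif or MOTIFS["U2_BP"]
    lo = max(1, b - window[0])
    hi = min(len(seq), b + window[1])
    region = seq[lo - 1 : hi]
    return duplex_align(
        region, motif, weights=weights, bulge_at=b - lo + 1, region_origin=lo
    )


@dataclass(frozen=True)
class PairingNetwork:
    """Per-motif best alignments for one intron plus a text diagram."""

    intron_sequence: str
    bp: BPCall
    alignments: dict[str, DuplexAlignment]
    notes: tuple[str, ...] = ()

    def render(self) -> str:
        lines = [f"RNA interaction network for intron 5'-{self.intron_sequence}-3'"]
        if self.bp.is_call:
            lines.append(f"BP-A at intron position {self.bp.position} "
                         f"({'canonical' if self.bp.canonical else 'non-canonical'})")
        for name in sorted(self.alignments):
            lines.append("")
            lines.extend(_render_alignment(name, self.alignments[name]))
        for note in self.notes:
            lines.append("")
            lines.append(note)
        return "\n".join(lines) + "\n"


def _render_alignment(name: str, aln: DuplexAlignment) -> list[str]:
    n = len(aln.region)
    glyph_cols = {p - 1: GLYPH[t] for p, _, t in aln.pairs}
    motif_cols = {p - 1: aln.motif.sequence[mp - 1] for p, mp, _ in aln.pairs}
    if aln.bulge is not None:
        glyph_cols[aln.bulge - 1] = " "
        motif_cols[aln.bulge - 1] = "-"  # gap: motif reads through the bulge
    glyphs = "".join(glyph_cols.get(i, " ") for i in range(n))
    motif_row = "".join(motif_cols.get(i, " ") for i in range(n))
    start = aln.region_origin
    header = f"{name}: score={aln.score:g} offset={aln.offset:+d}"
    if aln.bulge is not None:
        header += f" bulged position {start + aln.bulge - 1} (BP-A)"
    return [
        header,
        f"  region 5'-{aln.region}-3'  (positions {start}..{start + n - 1})",
        f"            {glyphs}",
        f"  motif  3'-{motif_row}-5'  ({aln.motif.name} {aln.motif.sequence} read 3'->5')",
    ]


def network_report(
    intron: IntronRecord | str,
    bp: BPCall,
    weights: Mapping[PairType, float] | None = None,
    ss5_intron_width: int = 6,
    ss5_exon_width: int = 3,
) -> PairingNetwork:
    """Best alignments for U1_5p and U6_ACAGAGA over the 5' splice-site
    region (last `ss5_exon_width` exonic nt, when available, plus the first
    `ss5_intron_width` intron nt) and the bulged branch helix with U2_BP."""
    if isinstance(intron, IntronRecord):
        seq = intron.sequence
        exon5 = intron.flank5[-ss5_exon_width:] if ss5_exon_width else ""
    else:
        seq, exon5 = str(intron), ""
    if not bp.is_call:
        raise ValueError("network report requires a BP call")
    ss5_region = exon5 + seq[:ss5_intron_width]
    ss5_origin = 1 - len(exon5)  # exonic positions get coordinates <= 0
    alignments = {
        "U1_5p": duplex_align(ss5_region, MOTIFS["U1_5p"], weights=weights,
                              region_origin=ss5_origin),
        "U6_ACAGAGA": duplex_align(ss5_region, MOTIFS["U6_ACAGAGA"], weights=weights,
                                   region_origin=ss5_origin),
        "U2_BP": branch_helix(seq, bp, weights=weights),
    }
    notes = (
        "U5 loop1 holds the 5' exon at the active site; no species-specific "
        "loop sequence is registered, so this contact is noted without a score.",
    )
    return PairingNetwork(
        intron_sequence=seq, bp=bp, alignments=alignments, notes=notes
    )
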