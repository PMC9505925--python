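"""Per-intron and cohort statistics for tiny-intron genomes.

Covers the descriptive statistics a tiny-intron survey reports: intron
length classes, splice-site position frequency matrices, branchpoint
adenosine (BP-A) calls, base composition, unique-sequence tallies, and the
geometry of the excised lariat (a circular loop closed at the BP-A plus a
linear 3' tail).

Conventions: intron positions are 1-based from the 5' end of the intron.
For an intron of length L the canonical BP-A sits at position L-5, i.e. the
10th position of a 15-nt intron and the 11th of a 16-nt intron, leaving a
5-nt 3' tail after branching.  Percentages are half-up rounded to two
decimals.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import RNA_BASES, percent
from .genome_io import IntronRecord

logger = logging.getLogger(__name__)

#: default BP search-window half-widths (lo, hi) around the canonical L-5;
#: (7, 2) spans the full admissible window [4, L-3] for 15/16-nt introns.
DEFAULT_BP_WINDOW = (7, 2)


def _seq_of(intron: IntronRecord | str) -> str:
    return intron.sequence if isinstance(intron, IntronRecord) else str(intron)


@dataclass(frozen=True)
class LengthDistribution:
    counts: dict[int, int]
    shares: dict[int, float]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "LengthDistribution":
        total = sum(counts.values())
        if total == 0:
            raise ValueError("length distribution over zero introns")
        shares = {length: percent(c, total) for length, c in sorted(counts.items())}
        return cls(counts=dict(sorted(counts.items())), shares=shares, total=total)


def classify_lengths(introns: Sequence[IntronRecord | str]) -> LengthDistribution:
    if not introns:
        raise ValueError("no introns to classify")
    return LengthDistribution.from_counts(Counter(len(_seq_of(i)) for i in introns))


@dataclass(frozen=True)
class TerminalDinucleotides:
    pairs: dict[tuple[str, str], int]
    gu_ag_fraction: float
    n_used: int
    n_excluded: int


def terminal_dinucleotides(introns: Sequence[IntronRecord | str]) -> TerminalDinucleotides:
    """Tally (5' dinucleotide, 3' dinucleotide) pairs and the GU...AG fraction."""
    pairs: Counter[tuple[str, str]] = Counter()
    excluded = 0
    for it in introns:
        seq = _seq_of(it)
        if len(seq) < 4:
            logger.warning("intron shorter than 4 nt excluded from terminal tally")
            excluded += 1
            continue
        pairs[(seq[:2], seq[-2:])] += 1
    n = sum(pairs.values())
    if n == 0:
        raise ValueError("no introns of length >= 4")
    gu_ag = pairs.get(("GU", "AG"), 0) / n
    return TerminalDinucleotides(dict(pairs), gu_ag, n, excluded)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base frequencies and information content.

    `freqs` rows are labelled 5'E-k (5' exonic flank), I1..IL (intron), and
    3'E+k (3' exonic flank); columns A/C/G/U.  `info_content` is
    2 - H(column) in bits; columns with no informative (non-N) base get
    frequency 0 and info 0.
    """

    freqs: pd.DataFrame
    info_content: pd.Series
    n: int
    n_per_column: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.freqs.copy()
        out["info"] = self.info_content
        out["n"] = self.n_per_column
        return out


def build_pfm(
    introns: Sequence[IntronRecord],
    length_class: int,
    flank: int = 6,
) -> PositionFrequencyMatrix:
    """Frequency matrix over flank5 + intron + flank3 for one length class.

    Sequences containing N (and truncated flank positions, padded with N)
    are excluded column-wise from the counts.
    """
    members = [it for it in introns if it.length == length_class]
    if not members:
        raise ValueError(f"no introns of length {length_class}")
    if any(len(it.sequence) != length_class for it in members):
        raise ValueError("mixed lengths within one length class")

    labels = (
        [f"5'E-{k}" for k in range(flank, 0, -1)]
        + [f"I{k}" for k in range(1, length_class + 1)]
        + [f"3'E+{k}" for k in range(1, flank + 1)]
    )
    rows = []
    for it in members:
        f5 = it.flank5[-flank:].rjust(flank, "N") if flank else ""
        f3 = it.flank3[:flank].ljust(flank, "N") if flank else ""
        rows.append(f5 + it.sequence + f3)
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)

    counts = np.stack([(arr == b.encode()).sum(axis=0) for b in RNA_BASES], axis=1).astype(float)
    col_n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(col_n[:, None] > 0, counts / np.maximum(col_n, 1)[:, None], 0.0)
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.where(col_n > 0, 2.0 - entropy, 0.0)

    fdf = pd.DataFrame(freqs, index=labels, columns=list(RNA_BASES))
    return PositionFrequencyMatrix(
        freqs=fdf,
        info_content=pd.Series(info, index=labels, name="info"),
        n=len(members),
        n_per_column=pd.Series(col_n.astype(int), index=labels, name="n"),
    )


@dataclass(frozen=True)
class BPCall:
    """A branchpoint adenosine call; position is 1-based within the intron."""

    position: int | None
    canonical: bool
    window_used: tuple[int, int]

    @property
    def is_call(self) -> bool:
        return self.position is not None


def call_branchpoint(
    intron: IntronRecord | str,
    window: tuple[int, int] = DEFAULT_BP_WINDOW,
) -> BPCall:
    """Locate the BP-A: canonical position L-5 if it is an A, else the
    nearest A within [max(4, L-5-lo), min(L-3, L-5+hi)] with ties broken
    toward the 3' end, else a no-call.

    `window=(0, 0)` restricts the search to the canonical position only
    (no fallback).
    """
    seq = _seq_of(intron)
    L = len(seq)
    if L < 8:
        raise ValueError(f"intron too short for a BP call (L={L} < 8)")
    lo_off, hi_off = window
    canonical_pos = L - 5
    lo = max(4, canonical_pos - lo_off)
    hi = min(L - 3, canonical_pos + hi_off)
    if seq[canonical_pos - 1] == "A":
        return BPCall(canonical_pos, True, (lo, hi))
    best: int | None = None
    for p in range(lo, hi + 1):
        if seq[p - 1] != "A":
            continue
        if best is None:
            best = p
            continue
        d_new, d_old = abs(p - canonical_pos), abs(best - canonical_pos)
        if d_new < d_old or (d_new == d_old and p > best):
            best = p
    return BPCall(best, False, (lo, hi))


def bp_position_distribution(
    calls: Iterable[BPCall | int], total: int
) -> dict[int, tuple[int, float]]:
    """Counts and percentages of called BP positions.

    Percentages use the full-cohort denominator `total` (all introns, called
    or not), matching how BP-position shares are reported.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    positions = [
        c.position if isinstance(c, BPCall) else int(c)
        for c in calls
        if not (isinstance(c, BPCall) and not c.is_call)
    ]
    if len(positions) > total:
        raise ValueError("more calls than introns in the cohort")
    counts = Counter(positions)
    return {p: (c, percent(c, total)) for p, c in sorted(counts.items())}


@dataclass(frozen=True)
class CompositionSummary:
    per_intron: pd.DataFrame  # columns A/C/G/U fractions, one row per intron used
    au_pooled_percent: float  # A+U over all pooled bases
    au_mean_percent: float    # mean of per-intron A+U fractions
    n_used: int
    n_excluded: int


def composition(introns: Sequence[IntronRecord | str]) -> CompositionSummary:
    """Base composition; introns containing N are excluded (counted, logged)."""
    rows = []
    excluded = 0
    pooled = Counter()
    for it in introns:
        seq = _seq_of(it)
        if "N" in seq or not seq:
            excluded += 1
            continue
        c = Counter(seq)
        pooled.update(c)
        rows.append({b: c.get(b, 0) / len(seq) for b in RNA_BASES})
    if not rows:
        raise ValueError("no N-free introns for composition")
    if excluded:
        logger.warning("%d introns with N excluded from composition", excluded)
    df = pd.DataFrame(rows, columns=list(RNA_BASES))
    total = sum(pooled.values())
    au_pooled = percent(pooled.get("A", 0) + pooled.get("U", 0), total)
    au_mean = percent(float((df["A"] + df["U"]).mean()), 1.0)
    return CompositionSummary(df, au_pooled, au_mean, len(rows), excluded)


def tally_unique_introns(
    introns: Sequence[IntronRecord | str],
    denominator: str = "class",
) -> list[tuple[str, int, float]]:
    """Ranked unique sequences as (sequence, count, percent).

    denominator="class": each sequence's percent is over introns of the same
    length (how the most-abundant-sequence share is reported);
    "cohort": over all introns.  Descending by count, ties lexicographic.
    """
    if denominator not in ("class", "cohort"):
        raise ValueError("denominator must be 'class' or 'cohort'")
    seqs = [_seq_of(i) for i in introns]
    if not seqs:
        raise ValueError("no introns to tally")
    counts = Counter(seqs)
    class_sizes = Counter(len(s) for s in seqs)
    out = []
    for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        den = class_sizes[len(seq)] if denominator == "class" else len(seqs)
        out.append((seq, c, percent(c, den)))
    return out


@dataclass(frozen=True)
class LariatModel:
    """Geometry of the excised lariat: a circular loop of `loop_length` nt
    closed 2'-5' at the BP-A, plus a linear 3' tail of `tail_length` nt."""

    loop_length: int
    tail_length: int
    branch_nt: str
    degenerate: bool = False


def lariat_geometry(intron: IntronRecord | str, bp: BPCall) -> LariatModel:
    if not bp.is_call:
        raise ValueError("cannot derive lariat geometry from a no-call")
    seq = _seq_of(intron)
    L = len(seq)
    b = bp.position
    assert b is not None
    if not (1 <= b <= L):
        raise ValueError(f"BP position {b} outside intron of length {L}")
    tail = L - b
    if tail == 0:
        logger.warning("degenerate lariat: BP-A at the 3'-terminal position")
    return LariatModel(
        loop_length=b, tail_length=tail, branch_nt=seq[b - 1], degenerate=tail == 0
    )
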