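"""Gene-level statistics: intron-containing fraction, introns per gene,
gene-length comparison (two-tailed unpaired t-test) and 5' positional bias.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent
from .genome_io import GeneRecord


@dataclass(frozen=True)
class GeneCohortSummary:
    n_intronless: int
    n_introned: int
    percent_introned: float
    introns_per_gene: dict[int, int]

    @property
    def n_genes(self) -> int:
        return self.n_intronless + self.n_introned


def summarize_genes(genes: Sequence[GeneRecord]) -> GeneCohortSummary:
    if not genes:
        raise ValueError("no genes to summarize")
    hist = Counter(g.n_introns for g in genes)
    n_intronless = hist.get(0, 0)
    n_introned = len(genes) - n_intronless
    return GeneCohortSummary(
        n_intronless=n_intronless,
        n_introned=n_introned,
        percent_introned=percent(n_introned, len(genes)),
        introns_per_gene=dict(sorted(hist.items())),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    median_x: float
    median_y: float
    variant: str


def student_t_test(
    x: Iterable[float], y: Iterable[float], variant: str = "pooled"
) -> TTestResult:
    """Two-tailed unpaired t-test.

    variant="pooled" assumes equal variances (df = n1 + n2 - 2);
    variant="welch" uses the Welch-Satterthwaite approximation.
    Degenerate zero-variance samples follow the convention t=0, p=1 for
    equal means and t=+/-inf, p=0 otherwise.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")

    vx, vy = x.var(ddof=1), y.var(ddof=1)
    mx, my = x.mean(), y.mean()
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mx - my), 0.0
        df = float(len(x) + len(y) - 2)
    else:
        res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
        t, p = float(res.statistic), float(res.pvalue)
        if variant == "pooled":
            df = float(len(x) + len(y) - 2)
        else:
            n1, n2 = len(x), len(y)
            a, b = vx / n1, vy / n2
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    return TTestResult(
        t=t, df=df, p=p,
        mean_x=float(mx), mean_y=float(my),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        variant=variant,
    )


@dataclass(frozen=True)
class PositionalBias:
    """Transcript-oriented intron start ratios r = offset / gene_length.

    r = 0 means the intron starts at the first transcribed position; values
    below 0.5 on average indicate the 5' positional bias.
    """

    ratios: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    table: pd.DataFrame  # gene_id, intron_index, r

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())


def positional_bias(genes: Iterable[GeneRecord], bins: int = 20) -> PositionalBias:
    rows = []
    for g in genes:
        if g.gene_length == 0:
            raise ValueError(f"gene {g.gene_id} has zero length")
        intervals = list(g.intron_intervals)
        if g.strand == "-":
            # transcript order is right-to-left on the genome
            intervals = intervals[::-1]
        for idx, (lo, hi) in enumerate(intervals, start=1):
            if g.strand == "+":
                r = (lo - g.start) / g.gene_length
            else:
                r = (g.end - hi) / g.gene_length
            rows.append({"gene_id": g.gene_id, "intron_index": idx, "r": r})
    table = pd.DataFrame(rows, columns=["gene_id", "intron_index", "r"])
    ratios = table["r"].to_numpy(dtype=float) if len(table) else np.empty(0)
    counts, edges = np.histogram(ratios, bins=bins, range=(0.0, 1.0))
    return PositionalBias(ratios=ratios, bin_edges=edges, bin_counts=counts, table=table)
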