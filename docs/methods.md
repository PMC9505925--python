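# Methods

## Intron extraction

Coordinates follow GFF3: 1-based inclusive on the plus strand. Internally
slices are 0-based half-open; the conversion lives entirely in
`genome_io`. Introns are reported 5′→3′ in transcript orientation —
minus-strand intervals are reverse-complemented — and stored on the RNA
alphabet (T→U) at extraction time, because splice sites are conventionally
described as GU…AG on the RNA. Genomic start/end stay plus-strand so that
records remain joinable back to the annotation. Two annotation dialects
are supported: explicit `intron` features (parents resolved through the
Parent chain up to the `gene`, so intron→mRNA→gene works; unresolvable
parents are skipped with a warning) and intron inference from gaps between
consecutive exons of a gene. Sequences with symbols outside ACGTN are
folded to N; introns containing N are excluded from composition and
frequency-matrix statistics but still counted.

"Gene length" is the genomic span (end − start + 1). Annotation formats
guarantee genomic coordinates but not mRNA lengths, so span is the only
definition computable from a GFF alone; this is flagged because length
comparisons would shift slightly under an mRNA-based definition.

## Cohort statistics

Percentages are rounded half-up to two decimals, the convention used for
printed shares (Python's banker's rounding would disagree in ties).
Branchpoint-position shares use the full cohort of introns as the
denominator, including no-calls; unique-sequence shares use the length
class of the sequence as the denominator. Both choices reproduce the
printed arithmetic of published tiny-intron counts exactly (e.g.
8005/8806 → 90.90%, 127/8173 → 1.55%).

Position frequency matrices span the 5′ exonic flank, the intron and the
3′ exonic flank of one length class. Per column, frequencies are taken
over the non-N bases present (truncated flanks are padded with N and drop
out column-wise); information content is 2 − H in bits with 0·log 0 ≔ 0,
so an invariant column carries exactly 2 bits. Frequencies are the
primary representation; information content is carried alongside, since
logo conventions differ.

## Branchpoint calling

Tiny-intron annotations do not mark the branchpoint, and the branch
region shows no strong consensus, so the caller is deliberately
geometric: the BP-A is the adenosine at the canonical position L − 5 when
present (this alone reproduces the dominant 10th/11th-position modes of
15/16-nt cohorts); otherwise the nearest A inside the window
[max(4, L−5−lo), min(L−3, L−5+hi)] — default offsets (7, 2), i.e. the
full admissible window [4, L−3] — with ties broken toward 3′; otherwise a
no-call, which is a value, not an error. `window=(0, 0)` disables the
fallback, which is what the by-construction recovery analysis on
simulated data uses. Lariat geometry is then loop = b, tail = L − b,
with loop + tail = L conserved for every call; a BP-A at the terminal
position gives a degenerate 0-nt tail and is flagged.

## Gene-level statistics

The t-test is the two-tailed unpaired Student's test; the pooled variant
(df = n₁ + n₂ − 2) is the default and a Welch variant is available. The
statistic and p-value come from `scipy.stats.ttest_ind`; the test suite
checks both against the closed-form formulas to 1e-9. Zero-variance
degenerate inputs follow the convention t = 0, p = 1 for equal means and
t = ±∞, p = 0 otherwise. Medians are reported alongside means, since
skewed gene-length distributions are usually summarised by medians.

Positional bias is strand-aware: r = (intron start − gene start)/length
on plus genes and (gene end − intron end)/length on minus genes, so r = 0
always means the first transcribed position. The histogram bin count is
a parameter (default 20).

## Pairing model

Pair taxonomy: A-U and G-C are Watson–Crick, G-U is a wobble, U•U is a
non-canonical but genuine pair (common in non-coding RNA duplexes);
everything else is unpaired. Default weights WC = 2, wobble = 1,
U•U = 1: Watson–Crick pairs are stronger than the non-canonical
geometries, and both non-canonical types are admissible; no published
scoring scheme exists for this interaction, so the weights are a design
choice and configurable. Alignment is exhaustive over every antiparallel
offset of the motif along the region; there are no gaps and no internal
mismatch penalties — unpaired positions simply score 0 — except the
single bulge used for the branch helix: the BP-A is removed from the
pairing frame and the motif reads through it contiguously, which is how
the branch helix presents the bulged adenosine. Ties break toward the
smallest offset, then the longest contiguous paired run, making results
deterministic. The branch-region window that pairs with U2's GUAGUA is
not knowable from sequence alone; the default b−4…b+2 brackets the BP-A
with enough context for a 6-nt motif and is reported with every
alignment. U5 loop 1 contacts the 5′ exon, but no species-specific loop
sequence is registered, so the report notes the contact without scoring
it rather than inventing a sequence.

## Synthetic genomes

The generator emulates the marginal statistics of a tiny-intron ciliate
genome: per gene it draws strand, intron presence (default fraction
0.1814), a geometric intron count (p = 0.6, mode 1, capped at 8), intron
lengths from the {15: 0.9281, 16: 0.0719} mixture, and a log-normal gene
length (median 1230 nt for intron-containing genes, 939 nt for intronless
ones, σ = 0.45) so the gene-length comparison has a planted effect.
Sequence is i.i.d. with P(A) = P(T) = AU/2 and P(C) = P(G) = (1 − AU)/2
at AU = 0.7563, for exons, introns and intergenic spacers alike; splice
termini (GU…AG with probability 1.0) and the BP-A (canonical L−5 with
probability 0.96, else uniform over the admissible window) are overwritten
post hoc. Because five positions per intron are forced, the realised
whole-intron AU content is slightly below the knob (≈70.4% for 15-nt
introns); `expected_intron_au()` returns the implied value and the test
suite compares observed AU against it. Intron start offsets are drawn
from a Beta(1.5, 3) distribution over the eligible span, giving a mean
start ratio of ≈1/3 — a 5′ bias with a single tunable shape; placements
that collide are redrawn (up to 100 times, then evenly spaced, which is
rare and only affects multi-intron genes). All draws come from one
`numpy.random.default_rng(seed)` in a fixed per-gene order, so a fixed
config is byte-reproducible; the truth table carries a run id (hash of
the config) that `verify_truth` can check to prevent cross-run
comparisons.

What the simulator does not emulate: linkage between composition and
position, splice-site degeneracy beyond the termini, alternative
isoforms, annotation errors, or sequencing artefacts. Passing round-trip
and recovery tests therefore demonstrates correctness of the pipeline's
coordinate arithmetic, strand handling and calling logic — not robustness
to the noise of a real assembly.

## Problem sizes and determinism

The test suite runs the simulator at 2000 genes (≈600 introns, ≈2.6 Mb
of sequence, under a second to generate) for distributional checks and
300 genes for structural round trips; statistical assertions use
three-standard-error bands around the configured (or analytically
implied) values, with all seeds fixed. Analysis stages contain no
randomness at all, so reruns are bit-identical; the only stochastic
component is the simulator, which is seed-controlled.

## Known limitations

- The branchpoint caller is positional, not motif-based; in a genome
  whose BP-A does not sit near L − 5 it would need a different window.
- The pairing model scores duplexes combinatorially; it is not a
  thermodynamic folding model and does not predict snRNA–snRNA helices.
- Intron-containing vs intronless gene-length comparison uses genomic
  span (see above).
- The unique-sequence tally is exact and in-memory; it assumes cohorts of
  at most a few hundred thousand introns.
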