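# tinyintron

A toolkit for analysing genomes whose spliceosomal introns are tiny — on
the order of 15–16 nucleotides, as in the giant ciliate *Stentor
coeruleus*. At that size the excised lariat is a sharply bent loop of only
~10 nt, and the usual questions about splicing (where is the branchpoint?
how do the snRNAs grip such a short substrate?) can be asked of every
intron in the genome at once.

The package provides, as composable library modules and a `tinyintron`
command-line tool:

- **`genome_io`** — strand-aware intron extraction from a genome FASTA +
  GFF3 (explicit `intron` features, or gaps between exons), reported
  5′→3′ in transcript orientation on the RNA alphabet.
- **`intron_features`** — cohort statistics: length-class shares,
  terminal-dinucleotide (GU…AG) tallies, position frequency matrices with
  information content (2 − *H* bits), branchpoint-adenosine (BP-A) calls,
  AU content, unique-sequence rankings, and lariat geometry. For an
  intron of length *L* with BP-A at position *b*, the lariat is a circular
  loop of *b* nt plus a 3′ tail of *L − b* nt; the canonical BP-A sits at
  *b = L − 5* (the 10th position of a 15-nt intron, the 11th of a 16-nt
  one, always leaving a 5-nt tail).
- **`gene_features`** — intron-containing gene fraction, introns-per-gene
  histogram, gene-length comparison by two-tailed unpaired t-test (pooled
  or Welch), and the 5′ positional bias *r* = intron start offset /
  gene length in transcript orientation.
- **`pairing_model`** — the RNA–RNA interaction network of the
  spliceosomal active site: exhaustive antiparallel duplex alignment of
  intron regions against the conserved snRNA motifs (U1 `ACUUACCU`,
  U6 `ACAGAGA`, U2 `GUAGUA`), scoring Watson–Crick (A-U, G-C), wobble
  (G-U) and non-canonical U•U pairs, with the BP-A bulged out of the
  branch helix.
- **`synthetic_data`** — a seeded genome simulator that plants introns
  with configurable length mixture, GU…AG termini, BP-A placement, AU-rich
  composition and 5′-biased positioning, and emits FASTA + GFF3 + a truth
  table so the whole pipeline is testable offline.
- **`report`** — `run_all()` chains every stage and writes a merged
  `summary.json` plus a readable report.

## Worked example

Simulate a 300-gene genome and run the full pipeline:

```sh
tinyintron simulate --seed 42 --n-genes 300 --out simdemo
tinyintron run --fasta simdemo/genome.fasta --gff simdemo/annotation.gff3 --out simdemo/out
```

which prints (exact output for this seed):

```
Intron cohort: n=78
  15 nt: 96.15% (75/78)
  16 nt: 3.85% (3/78)
GU...AG introns: 100.00% of 78
Branchpoint adenosine positions (of 78 introns):
  position 10: 94.87% (74)
  position 11: 5.13% (4)
AU content: 71.36% pooled, 71.35% per-intron mean
...
Genes: 300 total, 18.0% intron-containing (54/300)
Gene length medians: 1308 nt (introned) vs 970 nt (intronless); t=3.8556, df=298, p=0.000141
Positional bias: mean 5′ ratio r = 0.3080 over 78 introns
```

Each line is a cohort statistic with its raw counts: 75 of the 78
extracted introns are 15 nt long; the BP-A was called at the canonical
10th/11th position for all of them; intron-containing genes are
significantly longer than intronless ones; and the mean start ratio below
0.5 shows the planted 5′ positional bias. The pairing model for a single
intron:

```sh
tinyintron pairing --seq GUAAUUUUUAUAUAG
```

```
U2_BP: score=8 offset=+1 bulged position 10 (BP-A)
  region 5'-UUUUAUA-3'  (positions 6..12)
             |•: ||
  motif  3'- AUG-AU-5'  (U2_BP GUAGUA read 3'->5')
```

The branch region pairs with U2's GUAGUA through Watson–Crick (`|`),
wobble (`:`) and U•U (`•`) pairs while the BP-A at position 10 bulges out
(the `-` gap), leaving a 10-nt loop and 5-nt tail after branching.

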