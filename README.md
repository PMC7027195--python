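# swingerscan

Detection and analysis of **swinger RNAs** — transcripts that match their
template genome only after a *systematic nucleotide exchange* is applied
uniformly along the read.

Sequencing projects routinely discard reads with no detectable homology to
the reference as artefacts. Some of those reads are not random noise: they
are exact images of the template under one of the 23 possible non-identity
bijections of the DNA alphabet (e.g. A↔T: every A read as T and vice versa;
or the directional cycle A→T→C→G→A). Such exchanges — 9 symmetric swaps and
14 asymmetric cycles — form a closed permutation group, so an "unknown" read
can be assigned a template, an exchange class and a strand by exhaustively
aligning its 23 transformed variants against the reference. `swingerscan`
implements that search and the downstream analyses used to characterise the
detected reads: per-class abundance/length statistics, regional (5′/mid/3′)
compartmentalization with exact sign tests, exon/intron classification, and
a codon-level conservation index. It targets anyone re-mining EST or read
archives for non-canonical transcription.

## The method in brief

For a read *s*, reference collection *R* and exchange *t* (a bijection of
{A,C,G,T}), the detector computes affine-gap Smith–Waterman alignments of
*t(s)* and *t(rc(s))* against every reference (match +2, mismatch −3, gap
open −5, extend −2), over *t* ∈ {identity} ∪ the 23 exchanges. The best
alignment passing the thresholds (≥ 40 columns, ≥ 75% identity, score ≥ 60)
classifies the read as *canonical* (identity), *swinger* (with its
detection transformation *t*, template locus and strand), or
*unidentified*. The transformation the polymerase performed on the template
is the inverse *t*⁻¹; hits on the reverse strand are re-expressed for the
forward orientation via the conjugation rc(t(s)) = (c∘t∘c)(rc(s)), where
c = A↔T+C↔G is the complement map.

Downstream, for k of n hits whose midpoints fall in the mid+3′ thirds of
their genes, the regional bias is tested with the exact one-tailed binomial
tail P(X ≥ k | n, p₀ = 2/3); class abundance is correlated with mean
aligned length (Pearson on log₁₀ abundance, p from the t transform on n−2
df) and with the conservation index — the fraction of the 64 codons whose
translation survives the exchange.

The package also ships transcriptions of the published tables of 347
swinger ESTs from a human cancer EST screen as loadable fixtures, so every
table-level statistic is reproducible offline.

## Worked example

```sh
python examples/03_tables_and_statistics.py
```

prints

```
records: 347 (223 symmetric, 124 asymmetric)
  A↔T: 219
  A→T→C→G→A: 124
  A↔C: 2
  G↔T: 1
  C↔T: 1
mitochondrial: 51 (ND2: 30), PABPC1: 33, non-coding: 17, uncharacterized: 2

log10(abundance) vs mean aligned length over 5 classes: r = 0.95, two-tailed P = 0.0118
→ more abundant exchange classes also align over longer stretches.

mid+3' regional bias, mitochondrial: 38/43 (one-tailed exact P = 0.00106)
mid+3' regional bias, nuclear:       33/33 (one-tailed exact P = 1.545e-06)
→ hits avoid the 5' third of their genes far beyond the 2/3 the null predicts.
```

Five detected exchange classes dominate the 347 records; the more abundant
a class, the longer its mean alignment (on the stated class means the
correlation is r = 0.96, P = 0.00945; the table-derived means shown here
give r = 0.95). The sign tests say that swinger hits sit overwhelmingly in
the downstream two thirds of their genes — the signature expected if the
exchange mode arises progressively during transcription.

The other examples cover the remaining capabilities: `01` the
transformation algebra, `02` detection on planted synthetic reads with a
truth-table evaluation, `04` gene thirds and exon/intron classification,
`05` the conservation–abundance analysis.

A thin CLI wraps the same functions:

```sh
swingerscan simulate --config sim.cfg --out-prefix sim
swingerscan detect --reads sim.reads.fasta --reference sim.ref.fasta --out hits.tsv
swingerscan summarize
```

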