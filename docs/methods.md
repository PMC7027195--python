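# Methods

## The detection problem

A *systematic nucleotide exchange* (swinger transformation) replaces every
occurrence of particular nucleotides by other particular nucleotides,
uniformly along a nucleic-acid sequence. Over the four-letter DNA alphabet
exactly 23 non-identity bijections exist: 9 symmetric involutions (6 single
swaps X↔Y and 3 double swaps X↔Y+Z↔W) and 14 directional cycles (8
three-cycles, 6 four-cycles). An RNA produced under such an exchange has no
detectable homology to its template under ordinary alignment, yet carries
its template's information exactly — applying the right bijection to the
read restores the homology. The detection method therefore aligns each
unexplained read, transformed under each of the 23 exchanges and in both
orientations, against the reference collection, and assigns the read to the
transformation, locus and strand of the best passing alignment.

Two conventions keep reports deterministic:

* **Inversion.** The *detection* transformation is the one applied to the
  read; the *transcription* transformation — the exchange the polymerase
  performed on the template — is its inverse. Symmetric exchanges are
  self-inverse; an asymmetric detection such as A→T→C→G→A implies
  transcription under A→G→C→T→A.
* **Strand canonicalization.** A hit on the reverse strand can be described
  equivalently as a different transformation on the forward strand; the two
  descriptions are linked by conjugation with the complement map c = A↔T+C↔G
  (rc(t(s)) = (c∘t∘c)(rc(s))). Every hit is expressed for the
  forward-oriented read, with the strand flag carrying the orientation.
  Ties between equivalent descriptions are broken by fewer moved bases, then
  canonical name, then strand; a tie between genuinely different
  transformations at the winning score is flagged ambiguous.

## Alignment engine

Alignments are affine-gap Smith–Waterman (Biopython's C `PairwiseAligner`),
with match +2, mismatch −3, gap open −5, gap extend −2 (a gap of length k
costs 5 + 2(k−1)). Because every exchange is a bijection, transforming query
and reference together never changes any alignment score; this invariance is
what lets a transformed-read search stand in for a transformed-database
search, and it is property-tested over all 23 exchanges.

Ties among co-optimal tracebacks are resolved by (smallest reference start,
smallest query start, shortest alignment), applied over a bounded prefix
(64) of the co-optimal enumeration — full enumeration can grow
combinatorially on low-complexity input while adding nothing in practice.

### Thresholds and significance

A hit must span ≥ 40 aligned columns at ≥ 75% identity (defaults chosen to
bracket the weakest hits this class of screen reports: alignments down to
41 nt and 75.4% identity), and must additionally reach an alignment score
of ≥ 60. The score floor is the significance filter: a seeded database
search (megablast-style) only ever reports alignments anchored on a long
exact word and below an e-value cutoff, whereas exhaustive Smith–Waterman
will happily return chance alignments that reach 75% identity over 40-odd
columns against multi-kilobase references. A floor of 60 — the score of a
perfect ~30 nt match — sits well above the chance-score regime at the
reference sizes this aligner is meant for (an extreme-value estimate for a
300 nt read against 1 Mb is ≈ 30) and well below any genuine hit class
(41 nt at 95% identity scores ≈ 72). E-values themselves are deliberately
not computed: Karlin–Altschul calibration of a custom aligner would not
match any database tool's numbers and adds no testable surface. For
database-scale runs, externally produced tabular hits (BLAST outfmt-6 plus
a transformation column) can be imported instead.

With `canonical_first` (default) the untransformed read is screened before
any transformation is tried, mirroring the two-pass design in which only
reads with no canonical homology enter the transformed search.

## Regional analysis

Genes are divided into three equal regions (5′, mid, 3′) along their own
reading direction; a hit belongs to the region containing its midpoint
⌊(start+end)/2⌋, with boundary positions at ⌊L/3⌋ and ⌊2L/3⌋ assigned to the
earlier region. The midpoint rule is a determinism choice — majority overlap
or fractional assignment would be equally defensible; midpoint keeps the
arithmetic integral and the partition exact. Thirds are computed on
transcript length when an exon structure is available, on genomic span
otherwise. Exon/intron structure is classified exhaustively as exonic
(fully covered by exons), intronic (inside the span, disjoint from exons),
spanning (both), or intergenic (outside the span).

The count k of hits in mid+3′ among n feeds an exact one-tailed binomial
sign test against p₀ = 2/3 (the two regions jointly cover two thirds of a
gene). The tail probability is evaluated in exact rational arithmetic and
converted to float once, so deep-tail values are correct to double
precision; on the published counts it gives P(38/43) = 1.061×10⁻³ and
P(33/33) = (2/3)³³ = 1.545×10⁻⁶. (A commonly printed rounding of the latter,
1.6×10⁻⁶, corresponds to evaluating 0.667³³; the exact value is the one
reported here.) The one-tailed form follows from the directional working
hypothesis — polymerase fatigue accumulating downstream of transcription
initiation predicts depletion of the 5′ region specifically.

## Correlations

Pearson coefficients carry p-values from the exact t transform
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.

* **Abundance vs length.** log₁₀ class abundance against mean aligned
  length over the classes with ≥ 1 read. The log scale is the default
  because abundances span orders of magnitude while mean lengths do not,
  and it is the scale on which the published statistic (r = 0.96, two-tailed
  P ≈ 0.0094 on the five detected classes) is reproduced; raw-scale
  correlation is available as an option (it gives r ≈ 0.91 on the same
  inputs). Note the running text and the tables disagree slightly on one
  class mean (G↔T: 152 vs 147 nt); computed on stated means the correlation
  is 0.960, on table-derived means 0.954.
* **Conservation vs abundance.** The conservation index of an exchange is
  the unweighted fraction of the 64 codons whose translation (standard
  nuclear code, stop as its own class) is unchanged when the exchange is
  applied to each codon base. This is the simplest defensible codon-level
  definition; published variants differ in weighting, so exact reproduction
  of any particular printed r is not promised — the tested contract is
  oracle equivalence of the index and a positive one-tailed correlation
  over all 23 classes (zero abundances included). The scorer is pluggable
  (any 64-codon table).

## Synthetic data

The generator emulates the EST regime the method targets: i.i.d. reference
sequences at 41% GC (human-like), reads of 100–600 nt (the defining EST
length range; in-suite runs use 100–300 nt to keep alignment cost
proportionate), each read a uniformly placed fragment that is optionally
reverse complemented (probability 0.5), transformed under a class drawn
from a configured distribution, then hit by per-base substitution noise
(always to a different base). The default class distribution is the
empirical 219:124:2:1:1 skew over five classes — one dominant symmetric,
one dominant asymmetric, most classes absent — without modelling its cause.
Truth records store the generative (template→read) exchange; a correct
detection is one whose transcription transformation matches the truth after
strand canonicalization.

What the simulation does *not* model: expression structure, chimeric
canonical/swinger reads, indel errors (substitution-only by default; an
aligner-stress indel option is out of scope), base-composition
heterogeneity, or repeats. Passing planted-read tests therefore demonstrates
correctness of the search and its conventions, not performance on real
genomes — in particular, repeat-rich references would lower unique
mappability in ways the i.i.d. simulation cannot show.

## Problem sizes and numerical choices

* Planted-recovery experiments use one 100 kb reference and 20 zero-noise
  reads of 100–300 nt — large enough that chance placement is negligible and
  every read is uniquely mappable, small enough for exhaustive DP search
  (each read is scored against 46 transform×strand variants).
* Noise-tracking experiments use 10 kb references, 8 reads per noise level
  at 2% and 5% substitution; the check is that mean percent identity sits
  within a 4σ binomial band of 100·(1−rate).
* The brute-force detection oracle (every transformation × orientation ×
  offset, ungapped) is compared on ≤200 nt references and ~48 nt reads,
  only where its optimum is unique.
* Degenerate inputs: empty sequences, empty reference sets and invalid
  characters are rejected with positions named; reads whose best alignment
  fails a threshold report which threshold; sequences sharing no base have
  no alignment at all.
* IUPAC ambiguity codes are transformed by mapping base *sets* (the image
  of an ambiguity code is the code of the image set), so transformation
  commutes with ambiguity semantics and N is always fixed; U is read as T;
  soft-masking case is not preserved.

## Packaged tables

The three packaged TSVs transcribe the published per-EST tables (347 rows:
241 + 87 + 19). The loader normalises minus-orientation coordinates
(5′ > 3′ becomes start ≤ end with strand −), canonicalises transformation
names, keeps e-values as verbatim text, recovers a handful of coordinates
mangled upstream into European-decimal scientific notation (kept verbatim
alongside the parsed value), and validates the headline tallies
(219/124/2/1/1 by class, 223 symmetric) — any transcription drift fails
loudly. Per-gene counts report what the tables contain; the source text's
own prose totals disagree with its tables in places (e.g. ND1 row count)
and no reconciliation is attempted.

## Known limitations

* The exhaustive aligner is quadratic; genome-scale screens must go through
  the external tabular-hit import path.
* The score floor substitutes for, but does not reproduce, e-value
  statistics; borderline hits near the floor have no significance estimate.
* Chimeric reads (part canonical, part transformed) are neither simulated
  nor segmented.
* The conservation index is unweighted; codon-usage- or
  substitution-weighted variants would change the correlation's magnitude
  (not, on these inputs, its sign).
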