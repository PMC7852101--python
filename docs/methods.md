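# Methods

## Problem and scope

Mature miRNAs are rarely sequenced as a single canonical species. Small-RNA-seq
libraries contain *isomiRs*: variants of the canonical mature that are trimmed
or extended at the 5′ and/or 3′ end, carry internal substitutions (genomic SNPs
or A-to-I editing, which sequencers read as an A→G transition in transcript
orientation), carry untemplated 3′ additions ("tails", typically uridylation or
adenylation), or combine several of these deviations at once ("fuzzy"
isomiRs). `isomirkit` detects, classifies and quantifies all of these from
aligned reads (SAM) plus a genome (FASTA) and a miRBase-dialect miRNA
annotation (GFF3), and ships a ground-truth read simulator used to validate the
classifier. Alignment itself, novel-precursor *prediction*, differential
expression and target analysis are out of scope: the package consumes a SAM
file, post-processes externally produced novel candidates, and exports the
count table that DE tools take as input.

## Classification model

A read is compared against every annotated mature miRNA of every precursor its
alignment overlaps, on the same strand.

**End offsets.** For each end the shift between the read boundary and the
canonical mature boundary is measured in transcript orientation (on the minus
strand, genomic left is transcript 3′). A read qualifies for a mature only if
*both* end shifts are at most `max_shift` = 5 nt; the cap applies to each end
independently, matching the identifier, whose four offset fields each hold
0–5. A shift toward the inside of the mature is a trimming (`trim5`/`trim3`),
outward a templated extension (`ext5`/`ext3`); an end is one or the other,
never both.

**Mismatch routing.** Reads are routed by their mismatch pattern against the
genome: 0 mismatches → pure offset isomiR; a single internal mismatch →
candidate internal variant; 1–3 mismatches forming a contiguous run at the
transcript 3′ terminus → untemplated tail (the tail is stripped before end
offsets are measured, so a trimmed-plus-tailed read reports its true
trimming); any other 2–3-mismatch pattern, or more than 3 mismatches, is
discarded. Routing a *single* terminal mismatch to the tailing path is a
deliberate design choice: a 1-nt tail and a substitution at the very last
position are observationally identical, and treating the terminal mismatch as
a tail keeps 1–3 nt tails in one consistent class. The cost is that a genuine
SNP at the read's final position would be reported as a 1-nt tail; internal
positions are unaffected. Soft-clipped bases are tolerated only at the
transcript 3′ terminus and only up to 3 nt (they are re-attached and treated
as candidate tail bases); any other clipping discards the read.

**Variant confirmation.** Internal mismatches are not reported per read;
they are confirmed jointly through a pileup with the four caller cutoffs:
observations require mapping quality ≥ 20 and base quality ≥ 20; a bona fide
variant requires site depth ≥ 10 (quality-gated, counted after the MQ/BQ
filter) and ≥ 3 reads supporting the same alternate allele. Sites failing
these thresholds are still reported as class `ALT` when ≥ 1000 reads support
the alternate; otherwise the read keeps its offsets but its variant fields
stay `NA` — this reproduces the deliberate false-negative behaviour of a
stringent caller at low depth. Confirmed variants are classified with the
precedence *known catalogue → editing → novel SNP*: a (chrom, pos, ref, alt)
present in the optional VCF catalogue is `dbSNP`; otherwise a
transcript-orientation A→G in animal mode is `A_to_I_editing` (a genomic T→C
on a minus-strand mature); anything else is `novel_SNP`. Plant references
carry no catalogue and never emit editing calls. Pileups are built per
sample, so ALT support and depth are interpretable within a replicate.

**Ambiguity.** A read (or multi-mapping read group, up to 5 hits) compatible
with matures of two or more distinct precursors is `ambiguous` and kept out
of the primary count table; hits falling outside any precursor lose to an
in-precursor hit. Within a single precursor, the mature with the smaller
total shift wins; an exact tie is ambiguous. Status conservation holds by
construction: assigned + ambiguous + unassigned + discarded = input reads.

**ncRNA filtering.** Before classification, each read is attributed to
exactly one ncRNA class by coordinate overlap with the precedence rRNA >
miRNA > tRNA > snoRNA > SRP_RNA > lncRNA > other (or `unannotated`); rRNA
reads are removed, everything else proceeds.

## The 11-field identifier

Every assigned read maps to the key

```
sequence _ mature _ trim5 _ ext5 _ trim3 _ ext3 _ varPos _ varCount _ varClass _ tailFlag _ tailSeq
```

with `NA` placeholders for absent variant/tail fields and `T`/`F` for the tail
flag; a canonical read is `<seq>_<mir>_0_0_0_0_NA_0_NA_F_NA`. The field order
(trim5, ext5, trim3, ext3) follows the published example of a 5′ variant
starting one nucleotide after its canonical form, encoded `1_0_0_1`. Variant
classes are encoded with underscore-free tokens (`dbSNP`, `editing`,
`newSNP`, `ALT`) so the field count is always exactly 11;
`decode(encode(x)) = x` is enforced by tests on 10,000 random identifiers.
The variant fields hold the 1-based transcript position of the confirmed
variant within the read, the number of internal variants (0 or 1, since only
single-mismatch reads enter the variant path), and the class. Ambiguous
count-table rows cannot name a unique mature, so they are keyed by the read
sequence plus the sorted candidate mature ids.

## The simulator

The simulator emulates the benchmark conditions, not a sequencer. It builds
hairpin precursors of 70 nt on alternating strands of one synthetic
chromosome (spacers of 50 nt), each with a 5p and a 3p mature of 22 nt (16 nt
supported) starting/ending 9 nt inside the hairpin ends. Reads are placed at
their true coordinates — the *correctly mapped* regime, which isolates the
classifier from aligner error. Consequences of that choice: the published
mapper-induced false-positive rate (a few percent for canonical miRNAs,
caused by short-read mismapping against a real genome) is *not* reproduced
here and is documented as mapper-dependent; in this regime the classifier is
expected to be exact, and the benchmark asserts exactly that.

Per-end offsets are drawn with magnitude uniform on 0–5 (trim vs extension
equiprobable), the package default where no distribution is prescribed.
Read counts are calibrated analytically so the *expected* mean per-base
coverage over mature regions equals `mature_depth` (default 10,000×) given
the offset distribution — trimming shortens the overlap of a read with its
mature, so the count per mature is `depth·L/(L − 2·E[trim])`. Hairpin
background reads (default mean depth 1000× over non-mature hairpin
positions, calibrated the same way) are drawn only from start positions that
do **not** satisfy the ±5 nt both-end rule for either mature: a background
read inside that window would be, by the algorithm's own definition, a
legitimate isomiR of the mature, and its truth label would be ill-defined.
Their correct call is therefore `unassigned`.

After placement, a fraction of mature-derived reads (default 0.10) receives
one internal substitution and a disjoint fraction (default 0.10) a 1–3 nt 3′
tail whose bases are resampled until they differ from the templated
downstream genome base. Substitution positions are uniform over non-terminal
read positions whose genomic site lies strictly inside the mature body: this
is the *adequate-depth* regime, in which every variant site carries the full
mature depth and enough alternate support to clear the `-d10 -a3` caller
thresholds. Placing substitutions in rarely covered extension or edge
positions instead starves sites below the 3-read support cutoff and
reproduces the stringent-caller false-negative regime — that behaviour is
exercised deliberately in tests by lowering the simulated depth. The default
injected fractions are in the range of tailing/editing burdens reported in
isomiR surveys, and at 10,000× give each (site, allele) combination an
expected support far above the cutoff. An optional uniform per-base error
rate exists for robustness experiments and is off by default, since the
benchmark injects variants post-mapping rather than modelling sequencing
error.

One integer seed drives everything; the RNG is stream-split per stage
(reference / reads / injection) so each stage is independently reproducible,
and a fixed seed yields byte-identical FASTA/GFF/SAM/truth outputs.

What passing the benchmark does and does not show: it validates offset
arithmetic, strand handling, routing, tail stripping, threshold logic and
identifier bookkeeping end to end; it does not probe aligner mismapping,
sequencing-error robustness, adapter artefacts, or annotation errors of real
references.

## Scoring

A read assigned to its miRNA of origin is a TP, one assigned to another
miRNA an FP, one left unassigned (or ambiguous/discarded) an FN;
sensitivity = TP/(TP+FN) and specificity = TP/(TP+FP) — the latter is
precision under the usual naming, and the implementation computes exactly
the stated formula. Background reads count as FP if assigned and are
otherwise excluded from the assignment-level tally. `type_accuracy`
additionally requires the complete isomiR signature — offset quadruple,
confirmed variant (position and alleles) and tail sequence — to match truth,
with background reads correct only when unassigned; this is the quantity
reported as the headline accuracy. Per-type sensitivity/specificity tables
treat a right-origin/wrong-type call as a type-level miss.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere (SAM/GFF native); BED input is
  converted on read. Transcript sequences use RNA alphabet; genome slices DNA.
* Novel-candidate merging uses *reciprocal* overlap with the shorter interval
  as denominator (the threshold's denominator is not prescribed; this is the
  stricter, symmetric choice and is configurable). Resolution is greedy
  best-coverage-first with id tie-break, which is idempotent,
  order-independent and deterministic.
* Empty inputs are non-errors where the result is well-defined (empty SAM →
  empty tables and an empty summary; zero simulated reads → NA metrics with a
  warning); all-zero count matrices are errors for proportion summaries.
* Undefined ratios (0/0 sensitivity) are reported as missing, never as 0.
* Simulator geometry validation requires the two matures plus a ≥ 2 nt loop
  to fit the hairpin (`2·L + 2·margin + 2 ≤ P`).
* Default problem sizes: the benchmark and the reproduction script use
  5 precursors (10 matures, ≈130,000 reads) at the stated 10,000×/1000×
  depths, which runs in well under a minute; unit tests use 1–2 precursors at
  reduced depth chosen to preserve the adequate-depth variant regime
  (per-site alternate support well above the 3-read cutoff).

## Known limitations

* A terminal substitution is indistinguishable from a 1-nt tail and is
  reported as a tail.
* Multi-allelic sites are resolved to the highest-support alternate;
  indels are not called; there is no genotype-likelihood model.
* ALT support is counted within a sample, not pooled across replicates.
* The identifier caps offsets at 5 nt by design; `max_shift` beyond 5 is
  therefore not representable.
* ncRNA biotype vocabularies vary across annotation sources; unknown
  biotypes map to `other`.
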