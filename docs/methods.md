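# Methods

This note documents the models, algorithms and design choices behind
`dlohic`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Read model

A DLO Hi-C read is modeled as `tagL + full_linker + tagR + adapter`
(padded to the read length), where the tags are restriction-fragment ends
~20 bp long and the full linker is ~40 bp.  Each tag terminates at an
enzyme cut site; for a site written `L^R` (e.g. `T^TAA`) the junction
therefore reads `…L | linker | R…`.  This junction structure is what the
de novo detector exploits, and the simulator reproduces it on both
strands: for the reverse-complement-palindromic sites real protocols use,
a minus-strand tag ending at the bottom-strand cut carries exactly the
same `L`/`R` remnants as a plus-strand tag.

## Linker enumeration

Two half-linkers ligate head-to-head on opposite strands, so combination
XY is assembled as `halfX + revcomp(halfY)`.  Because published protocol
descriptions do not pin the assembly rule down, the plain concatenation
`halfX + halfY` is also kept as an alternate per-read candidate; whichever
scores higher wins, and in practice (and in all simulations) the
head-to-head form does.  One half-linker yields the single AA combination
(in situ protocol); two yield AA, AB, BA, BB.  AB and BA sequences are
mutual reverse complements, which is why reverse-orientation scanning
deduplicates against them.

## Linker location

Smith–Waterman local alignment with linear gap costs (match +1, mismatch
−1, indel −1), vectorized across reads.  A hit is accepted at
`min_score_fraction` (default 0.8) of the candidate's full length — the
protocol papers report score distributions but no cutoff, and 0.8 cleanly
separates planted linkers (score ≥ 32/40 even with a few errors) from the
background of random 150-mers (best local score ≈ 12–18 against a 40-mer).
Tie-breaks are fully deterministic: maximal score, then earliest start,
then linker-type order AA<AB<BA<BB, head-to-head before concatenation,
forward before reverse orientation.  The same rules are implemented in the
plain-Python oracle the tests compare against.

## Adapter consensus and trimming

Adapter detection anchors a sample of reads (default 100) at their
detected linker end and calls, per downstream position, the most frequent
base when its frequency reaches `min_base_frequency` (0.6).  The genomic
tag after the linker is random across reads, so only the adapter — and the
few conserved cut-site remnant bases, too short to qualify — forms a
called run of at least `min_overlap` (6) positions.  One degenerate case
is documented in the tests: a sample of *identical* reads conserves the
tag as well, so the consensus is the whole conserved tail (it still ends
in the adapter).  Trimming scans read positions left to right and clips at
the first position where the adapter prefix matches with at most one
mismatch per 8 bases and at least 6 bases of overlap; an earlier start
implies a longer overlap, so a genuine adapter always beats spurious short
tail matches.  The batched implementation proposes candidates with a
16-bp seed window and verifies each with the exact full-overlap rule
(the seed filter is complete: a position passing the full rule can never
have more seed mismatches than the full allowance).

## De novo linker and enzyme discovery

1. Count k-mers (k = 12) in a read sample (default 10,000 reads); seeds
   must be overrepresented (≥ 5% of the sample).
2. For each seed (skipping seeds contained in an already-built consensus
   or its reverse complement), collect reads containing the seed on either
   strand, orient and anchor them, and extend a per-column base-frequency
   consensus (call threshold 0.6) in both directions.  The conserved run
   is `L + full_linker + R` — the cut-site remnants are as conserved as
   the linker itself.  Runs reaching the read end are adapter clusters and
   are discarded.
3. Split each consensus into site + linker under symmetric-cutter
   constraints: the recognition sequence `L + R` (length 4, 6 or 8, cut
   offset 1..n/2) must be a reverse-complement palindrome and the middle
   must have even length.  Homodimer middles are additionally
   reverse-complement palindromes `h + revcomp(h)`, which pins down the
   half-linker; all clusters must agree on the site.  Half-linkers are
   returned ordered by cluster abundance.

With two half-linkers that share a long prefix (the HindIII-style design
differs only in the last two bases), the most frequent seeds sit in the
shared region; their clusters mix A- and B-reads and break at the variant
columns, failing validation.  The half-specific seeds ranked below them
then produce clean clusters — this is why seed masking skips, rather than
consumes, exploration slots.

## Mapping

The aligner contract is `align(reads, max_edit_distance) -> one hit per
read`.  The production backend shells out to bwa (`aln`/`samse`, or `mem`
when `ReadsType=long`); the built-in backend packs every genome window
into 2-bit codes and counts mismatches by XOR/popcount over both strands —
exact, gap-free, and practical up to a few megabases.  It reports MAPQ 37
for a unique best placement and 0 for ties, consistent with the
unique/multi cutoffs.  "Mapping score" is interpreted as SAM MAPQ with a
*strict* cutoff (score > 20 unique for aln, > 30 for mem; a score equal to
the cutoff is multi — the boundary is otherwise undefined).  Chunked
mapping canonicalizes output by read id, so results are independent of
chunk size and scheduling.  Iterative mapping starts at edit distance 0
and re-aligns only the still-unmapped reads with one more allowed
mismatch per round, capped at `n_max` = 3: "until no unmapped reads
remain" cannot terminate for contamination reads, so a cap is required.
Multi-mapped reads are kept in the tables but excluded from pairing.

## Pairing, classification, deduplication

Fragment assignment uses the tag's 5'-most mapped base (pos for +,
alignment end − 1 for −) and binary search over the digestion index;
digestion scans forward-strand site occurrences only, which is exact for
palindromic sites (a non-palindromic site would need both strands — a
documented limitation).  Classification precedence is heterodimer >
self-ligation > re-ligation > valid, since AB/BA pairs are the
random-ligation gauge regardless of their coordinates.  The short/long
boundary is inclusive at 5,000 bp, measured between 5' coordinates.
Duplicates are single-linkage clusters over the position-sorted stream
(same strands, both ends within 2 bp); chains like 100/102/104 collapse
into one cluster and the first pair in sort order is retained.
Classification happens before deduplication; all classes are counted, and
only valid, non-duplicate, homodimer pairs reach the matrix (heterodimer
inclusion is switchable).

One geometric subtlety: for 5'-overhang cutters, a minus-strand tag on the
*right* of the linker ends at the bottom-strand cut, so its 5'-most base
lies `overhang` bases past the top-strand cut — inside the neighboring
fragment under the 5'-most-base rule.  The fragment-end labels (s/t) of
such tags are therefore systematically 's' on the downstream fragment.
The simulator defaults to the strand combinations whose assignments are
exact (left tags on either strand, right tags on +) and exposes
`allow_minus_right` for full realism; truth labels are always computed
with the pipeline's own definitions, so recovery comparisons remain exact
either way.

## Matrices

Bins are `pos // resolution`; intra matrices are canonicalized to the
upper triangle and chromosome pairs ordered lexicographically, so total
counts are conserved at every resolution (defaults 1 Mb and 100 kb; the
fragment length bounds the useful maximum resolution).  `expected(d)`
averages observed counts over the full diagonal *including empty cells*
— the standard distance-decay convention — and O/E cells with zero
expected are 0 rather than NaN so vectors stay comparable.  Matrix
comparison flattens the dense symmetrized matrix row-major; whole-genome
vectors concatenate chromosome pairs in lexicographic order.  Cosine
similarity and Pearson correlation follow their textbook formulas and
raise on zero vectors / zero variance.

## Synthetic data generator

The simulator emulates the study conditions end to end: a random genome
(default two 100-kb chromosomes) with the restriction site planted every
~1.5–2.2 kb on top of natural occurrences; constructs per class
(default 1,000 valid, 100 each of self-ligation, re-ligation, heterodimer,
100 junk reads); 150-bp reads, 20-bp tags, a 33-bp adapter; AA:BB
homodimer mix 55:45; 20% inter-chromosomal valid pairs and 25% short-range
(≤ 5 kb) intra pairs, echoing the proportions real libraries show; a 5%
PCR duplicate rate (copies jittered ≤ 2 bp per end); optional per-tag SNP
rate.  Each non-duplicate construct occupies a distinct (cut site, strand)
combination per end, and distinct cut sites are at least the recognition
length (> 2 bp) apart, so the planted duplicates are exactly the pairs a
2-bp window can flag — duplicate-recovery checks are therefore exact, not
statistical.  Self- and re-ligation constructs draw from shuffled pools of
qualifying fragments/cut sites without replacement; requesting more than
the genome holds is a parameter error.

What the generator does *not* emulate: base-call error models and quality
variation (flat qualities; SNPs stand in for all mismatch processes),
chimeric/truncated constructs, variable tag lengths, copy-number or
mappability structure, and real contact-distance decay (valid-pair
distances are drawn from a two-band mixture, not a power law).  Passing
tests therefore demonstrate algorithmic correctness of the stages on
protocol-faithful constructs, not end-to-end accuracy on real libraries.

## Problem sizes used in validation

The test-suite and acceptance-script runs use deliberately desk-scale
conditions chosen to exercise every branch: discovery libraries of
~17,000 reads (10,000 sampled), a 10,000-construct classification mixture
on a 1-Mb genome with the built-in aligner, a 1,650-tag iterative-mapping
library with 10% SNP tags, and 1,000 random read/linker pairs for the
alignment oracle.  All randomness flows from a single seed argument.

## Known limitations

* The built-in aligner is gap-free; indel-carrying tags only map through
  the bwa backend.
* Discovery assumes a symmetric (palindromic) cutter with site length
  4–8 and both half-linkers longer than ~8 bp.
* Reverse-orientation reads are supported in linker location and
  splitting, but adapter trimming assumes forward constructs (reverse
  reads are only simulated without adapter).
* No matrix balancing (ICE/KR) and no .cool/.hic containers; matrices are
  sparse triplet text plus a bins BED, which downstream converters accept.
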