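# Methods

This note records the models, conventions and numerical choices behind the
toolkit, the defaults and why they were chosen, and what the synthetic
benchmark does and does not demonstrate.

## Sequence identity

Several stages need a pairwise "fraction of shared content" between
transfrags. We define, for shorter sequence *s* and longer *l*,

    identity(s, l) = max(0, 1 − d(s, l) / |s|)

where *d* is the unit-cost edit distance of a semi-global alignment (*s*
global, free end gaps on *l*; edlib's infix/HW mode). Properties that
motivated this convention:

- an exact substring scores 1.0, so containment of a fragment in its parent
  registers as full identity — the behaviour nucleotide CD-HIT's
  shorter-sequence denominator is meant to capture;
- a copy mutated at per-base rate μ scores ≈ 1 − μ;
- the value is unique: it does not depend on which of several optimal
  tracebacks an aligner reports, so an independent DP oracle can check it
  to 1e-9.

The denominator is the shorter sequence's length. Both strands are compared
by default (assembled transfrags have arbitrary orientation).

## Greedy clustering (default identity 0.95, k = 11)

Records are processed in descending length order, ties by ascending id —
this makes the result deterministic and invariant under input permutation,
and guarantees every representative is at least as long as its members.
Assignment is first-hit (the greedy classic); best-hit is available as a
parameter. The k-mer prefilter skips a representative comparison only when
it is provably safe: if identity ≥ c is achievable, at most
E = ⌊(1−c)·|s|⌋ edits exist, each destroying at most k of the |s|−k+1
k-mer windows of the shorter sequence, so at least (|s|−k+1) − k·E window
k-mers of the candidate must occur verbatim in the representative. When
that bound is non-positive the comparison is made unconditionally; enabling
or disabling the prefilter never changes the clustering.

## ORF calling and gene consolidation

The CDS of a transcript is its longest ATG-initiated open reading frame
over all six frames (standard genetic code), stop codon included; an ORF
running off the contig edge is kept but flagged incomplete. Ties are broken
by strand (forward first), then frame index, then scan position. The
minimum CDS is 90 nt.

Coding transcripts are grouped into genes by single-linkage over CDS
identity ≥ `altmid_min` (0.90); the longest CDS (ties: longest transcript,
then id) is the primary. Members are classified `part` when their CDS is
shorter than `part_max_frac` (0.70) of the primary's — partiality overrides
the alternate labels — otherwise `althi` at identity ≥ 0.98 and `altmid`
at ≥ 0.90. Members joined transitively whose direct identity to the primary
falls below 0.90 keep the floor label `altmid`. These three thresholds are
explicit stand-ins for the opaque internals of coding-potential
consolidators in the EvidentialGene tradition: the category *semantics*
(high/medium alignment to primary, partial incomplete) are reproduced, the
exact cutoffs are configurable, and no amino-acid clustering, UTR evidence
or codon-usage model is used. `althi1`/`althi` are merged: their published
distinction is undefined. The CDS-pair prefilter uses k = 8 because the
lossless bound above is positive for every CDS ≥ 90 nt only for k ≤ 8 at
c = 0.90.

## Containment coverage

Coverage of a shorter sequence *s* by a longer *t* is the fraction of *s*
under the union of matched blocks. Blocks are ungapped: exact k-mer hits
(k = 15) are merged along each alignment diagonal, adjacent runs are
bridged when the bridged block keeps identity ≥ `block_identity_min`
(0.95, the gap counted as mismatches), and block ends are extended to the
best-scoring endpoint under match +1 / mismatch −2 with an X-drop of 20 —
score-maximal extension cannot drift into unrelated sequence, which keeps
the 90% boundary sharp. An extension that would pull the block's identity
below the floor is discarded. The 95% block-identity floor is an explicit
assumption (the original all-vs-all BLAST step's cutoffs are unpublished)
and is exposed as a parameter; no e-value model is used at these scales.

Pruning removes every record with a hit covering strictly more than
`coverage_min` (0.90) of its length against a strictly longer record, in a
single pass against the original set — matching a BLAST self-alignment
report post-processed once, so a fragment contained only in another removed
fragment is still removed. Equal-length mutual containments keep the
lexicographically smaller id ("longer transcript" leaves the case
undefined; id order is deterministic).

Because blocks are ungapped, coverage of redundancy that contains true
indels is slightly underestimated (conservative: such sequences are kept).
The test oracle is an exhaustive iterated local-alignment DP over all
diagonals.

## Expression filters

The per-condition filter keeps a transcript iff the arithmetic mean TPM
within **any** level of **any** declared factor reaches 1.0 (inclusive).
"Within each experimental condition" could also be read as *all*
conditions, but the filter's purpose is discarding artifacts while
retaining condition-specific transcripts — requiring all levels would
delete genuinely seasonal transcripts that downstream differential
expression is supposed to find. The aggregation is the arithmetic mean
(not max or median) so the oracle is unambiguous. The post-consolidation
filter discards mean TPM strictly below 0.1: a mean of exactly 0.1
survives, mirroring the literal wording "below". Transcripts absent from a
quant file are treated as TPM 0 with a warning, since assemblies and
quantifications may be regenerated independently.

## miRNA screen

"Alignment with at most two mismatches" is implemented as full-length
ungapped Hamming matching on both strands: at mature lengths (~22 nt) a
gapped local hit with ≤ 2 mismatches is effectively a full-length ungapped
match, and the choice makes the exhaustive sliding-window oracle exact.
The hairpin score is consumed as an input table (it is the output of an
external hairpin classifier; lower is more hairpin-like) with an inclusive
threshold of 0.71. The candidate set is exactly
{score ≤ 0.71} ∩ {≥ 1 mature match}.

## Pipeline order and ledger

Consolidation precedes containment, then the abundance filter — the
narrative order of the reference workflow. Library groups
(stranded/unstranded) are carried as labels only; assembly itself is
upstream. Read-mapping-rate and BUSCO checks require external tools and
reads; the ledger's free-text notes slot holds externally computed lines.
The ledger enforces `kept + removed = input` per stage and chaining across
stages, and the pipeline contains no unseeded randomness: re-runs are
byte-identical.

## Synthetic benchmark

The generator plants, from a single integer seed (substreams via
`numpy.random.SeedSequence`):

- **gene families** (default 450 genes, 1–4 isoforms, lengths log-normal
  with median ≈ 1.3 kb truncated to [200, 20000], GC 36% — the crustacean
  assembly range): a shared CDS core (ATG…stop, 55–75% of the transcript,
  preceded by an in-frame stop so the planted ORF is exactly recoverable)
  with isoform-specific UTRs. Alternates carry unique UTR sequence
  (alternative first/last exons) rather than being pure deletions of the
  primary — a deletion-only isoform is a substring of its primary and
  therefore *is* redundant by the pipeline's own definition; distinct UTR
  content is what makes an alternate worth retaining;
- **exact cross-assembler duplicates** (rate 0.40) and **mutated
  near-duplicates** (rate 0.15, substitutions at 0.01/base, 3-base
  truncation);
- **contained fragments** (rate 0.25): a parent substring (45–85% of the
  parent) plus a short unique flap; the manifest `cov` ∈ [0.93, 0.99] is
  the fraction of the fragment's *own* length covered by the parent —
  exactly what the containment stage measures. Fragments with cov ≥ 0.95
  are typically absorbed at the clustering stage, the rest at containment;
- **contaminants** (80, GC 0.50), designated unexpressed;
- **expression**: log-normal base abundance (σ = 1.0) with a log-normal
  season effect (σ = 0.7), per-sample noise (σ = 0.4), dropout 0.10,
  renormalised to TPM = 10⁶ per sample across a balanced 12-sample
  season × area × sex design;
- **miRNA fixture**: hairpins (arm + loop + reverse-complement arm) with
  matures planted at 0/1/2 mismatches and scores ≤ 0.71; decoys with good
  matches but scores > 0.71, good scores but 3 planted mismatches, and
  plain background. The synthetic scores stand in for the external
  classifier — the combination rule, not the scorer, is under test.

What passing shows: the stages remove exactly the planted redundancy
(survivor recall/precision ≥ 0.95, fragment removal ≥ 0.95, gene-partition
Rand index ≥ 0.95) under substitution-dominated artifact noise. What it
does not show: behaviour on real indel-rich mis-assemblies, chimeras
spanning two genes, paralog families near the 0.95 identity boundary, or
biased quantification — real data keeps those failure modes, and the
thresholds here inherit the reference workflow's values rather than being
tuned per dataset.

## Problem sizes

The default benchmark is ~2,100 records (≈ 3.5 Mb of sequence); the full
pipeline runs in about a minute on one core. The published krill build
this workflow mirrors operated at 1.65 M input transfrags with external
assemblers, quantifiers and BLAST — reproducing those dataset-scale totals
requires the original reads and tools, so the acceptance script instead
verifies the planted-structure recovery above plus the arithmetic
consistency of the published stage totals (used as printed inputs). One
published inconsistency is noted and left unresolved: the reference tables
print N50 2.761 and 2.759 for the same final assembly.
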