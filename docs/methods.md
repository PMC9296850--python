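# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `plastidqc`.

## Quadripartite structure inference

A plastome is modelled as a circular DNA string carrying two disjoint,
reverse-complementary repeats (IRa, IRb) separating a long (LSC) and a
short (SSC) single-copy region. Detection finds the *longest* pair of
disjoint, exactly reverse-complementary repeats:

* Windows are taken on the doubled sequence, so the search is invariant to
  rotation and to whole-genome reverse complement.
* Existence of a repeat pair of length *m* is monotone in *m*, so the
  maximal length is found by binary search. Each probe hashes all length-*m*
  windows of the sequence and of its reverse complement with a
  doubling-level polynomial rolling hash (modulus 2^31−1, O(log m) vector
  operations per probe after an O(L log L) precomputation) and joins equal
  hashes; every candidate pair is verified by direct string comparison, so
  hash collisions cannot produce a false repeat.
* IUPAC ambiguity codes are encoded with position-unique values and
  therefore never match anything, including themselves. A planted N in both
  arms truncates the detected repeat to the largest N-free piece.
* The longer single-copy gap is labelled LSC. Equally long maximal pairs
  are tie-broken by the minimal LSC start coordinate; exactly equal gaps
  (no LSC/SSC distinction) raise a structural error.
* `min_ir_len` defaults to 1,000 bp: plastome IRs in the target clade are
  an order of magnitude longer, and the floor avoids tRNA-scale false
  hits. Values below 100 bp are rejected.
* `ir_mismatches` is computed *after* detection (Hamming distance between
  reverse-complement(IRa) and IRb); with exact detection it is zero by
  construction, but the field is kept because partitions can also come
  from annotation transfer or simulation truth, where arms may differ.

Mismatch-tolerant arms and IR-free plastomes are out of scope: detection
reports `None` when no exact pair of at least `min_ir_len` exists, and
downstream region metrics are then unavailable ("n.a.").

**Canonicalization** rotates to LSC base 1 (order LSC→IRb→SSC→IRa) and
chooses the SSC orientation by smaller edit distance to a reference when
one is given (edit distances computed by infix alignment against the
doubled reference), otherwise the lexicographically smaller orientation.
This maps all rotation and SSC-isomer variants of a genome to one string
and is idempotent. Whole-genome strand is *not* canonicalized; callers
compare assemblies on the strand they were submitted.

## Soft coverage capping

The cap is one-tailed: pairs estimated at or below the target depth are
always kept; a pair at depth *d* above the target *t* survives an
independent Bernoulli(*t*/*d*) draw. Mates are kept or discarded
together, order is preserved, and a fixed seed reproduces the output
byte-identically. The expected retained count is Σ min(1, t/dᵢ).

Depth is estimated per pair as the minimum over mates of the median
canonical (strand-collapsed) k-mer count in a table built from the same
read set, scaled by L/(L−k+1) to convert k-mer depth into base depth
(a position sequenced at depth d is covered by ~d·(L−k+1)/L k-mer
copies from reads of length L). Without this correction a uniform
1,000× set capped at 500 retains ~0.63 of pairs instead of 0.50. The
default k = 31 (odd, so no k-mer is its own reverse complement; ≤ 31 so
k-mers pack 2-bit into a 64-bit word); the median makes the estimate
robust to sequencing errors at read ends.

Windowed coverage uses non-overlapping windows (default 250 bp) from
position 0, the final partial window averaged over its actual length.
Low-coverage flags are inclusive: a window at exactly the threshold
fraction (default 50%) of genome-wide depth is flagged.

The SNP/low-coverage co-localization test is an add-on formalization (the
association is classically asserted visually): the observed fraction of
SNPs in flagged windows is compared against ≥ 999 permutations of
uniformly placed SNPs, p = (1 + #perm ≥ obs)/(1 + n_perm). The null
assumes positional uniformity only; it does not model mutational
heterogeneity along the genome.

## Contig finishing

The pipeline mirrors manual organelle-assembly finishing:

1. **filter_short** removes contigs under 100 bp (inclusive keep at 100).
2. **order_contigs** anchors each contig with k-mers (k = 21) that occur
   exactly once forward in the circular reference; the majority strand
   wins and the modal implied start places the contig. Contigs lying
   wholly inside one IR arm match both copies with exactly tied votes; the
   tie is resolved by placing the contig where it covers reference span no
   other contig covers (the completeness argument a manual finisher would
   use). Contigs without anchors are returned as unplaceable.
3. **merge_overlaps** merges adjacent contigs sharing an exact
   suffix/prefix overlap of ≥ 15 bp (no mismatch tolerance — "without
   differences" is read strictly; mismatched overlaps are never merged),
   iterated to a fixpoint. Contigs fully contained in their neighbour are
   absorbed as redundant. The output never alters a base.
4. **trim_duplicate_endpoints** searches the first and last 25 bp against
   the opposite end region with ≤ 3 mismatches; a match within 100 bp of
   an end marks an over-extended endpoint, trimmed once from the 3' side,
   then the sequence is circularized. Duplications shorter than the motif
   length (25 bp) are undetectable by construction.
5. **find_polyN** reports maximal N-runs; polishing them is out of scope.

## Assembly metrics

NGA50/LGA50 are *simplified* reference-aware contiguity metrics: contig
anchors (unique reference k-mers, majority strand) are chained while the
reference diagonal is stable within 50 bp; a diagonal jump or strand
switch (a rearrangement) breaks the block. Repeat regions carry no unique
anchors but are traversed colinearly, so same-diagonal anchors chain
across the IRs. Block lengths are measured on the contig with unanchored
flanks assigned to the neighbouring block; blocks are ranked by length
and NGA50 is the block at which the cumulative sum reaches half the
reference (LGA50 its 1-based rank), undefined ("n.s.d.") below half.
This reproduces the full metric on clean and cleanly split assemblies but
is not a misassembly classifier; pathological inputs may differ from one.

## Pairwise comparison and PCoA

Alignment follows a shared-unique-anchor design: k-mers (k = 21) unique
in both sequences are chained by longest increasing subsequence,
same-diagonal runs merge into exact blocks, and inter-anchor segments are
filled with exact minimum-edit-distance dynamic programming (edlib).
Anchoring keeps large planted insertions/deletions as single contiguous
gap runs — a plain whole-sequence edit-distance path scatters them across
coincidental matches, which would inflate indel event counts. Identical
inputs short-circuit to a gapless alignment. Inputs whose edit distance
exceeds 30% of the longer length are refused: the method is for
conspecific, near-identical assemblies.

Differences: SNPcount counts columns where both rows carry residues and
the symbols differ; ambiguity handling is strict by default (any unequal
symbol pair counts, N=N does not) with a lenient IUPAC-intersection
switch. Indel events are maximal single-row gap runs. Because single-base
indels between near-identical assemblies are as informative as
substitutions, the headline comparison is `total_diff_count` =
substitutions + indel events, with both components exposed separately.

Region length differences are absolute per-region differences (LSC, SSC,
single IR); arms within one partition are equal by construction, and a
defensive mean-with-warning covers externally supplied unequal arms. The
length metrics can compensate (an IR gain offset by an LSC loss leaves
total length nearly unchanged), which is precisely the diagnostic pattern
reported for defective assemblies — the distance matrices are raw
difference counts and do not satisfy the triangle inequality.

PCoA is classical metric scaling: squared distances double-centered,
eigendecomposed, coordinates = eigenvectors × √eigenvalue. Negative
eigenvalues (non-Euclidean input) are truncated to zero with their total
magnitude reported; numerically zero eigenvalues (< 1e−9 of the largest)
are zeroed so axis scaling does not amplify round-off noise. Coordinates
are optionally translated so a designated final assembly sits at the
origin, and the first two axes are divided by their maximum absolute
value (range [−1, 1]). Per-axis absolute variance is eigenvalue/(n−1);
percent variance uses the positive spectrum only.

## Annotation transfer and auditing

Each reference gene's unspliced extent (coding-strand oriented) is
searched on both strands of the doubled target by infix alignment; the
best hit is accepted when identity ≥ 95%. The threshold applies to the
full query by construction (edit distance over query length), which
realizes the "identity and coverage both ≥ 95%" reading with a single
parameter. Genes without a qualifying hit are "missing"; several equally
good non-equivalent hits flag the gene ambiguous (transferred at the
first location). Sub-spans (exons) are mapped by offset from the coding
5' end — exact for equal-length matches, approximate under small indels.

CDS auditing applies checks in order — length mod 3 (bad_length), start
codon (no_start), terminal stop (no_terminal_stop), internal stops
(internal_stop) — with the first failure naming the status. The genetic
code is the bacterial/plant-plastid table 11; start codons default to
{ATG, GTG} (GTG initiates several plastid genes) with an ATG-only strict
switch. RNA-editing-aware translation and de novo prediction are out of
scope.

## Phylogenetic preparation

Regions are extracted per annotated genome: coding = concatenated CDS
spans, introns = gaps between spans of multi-span genes, spacers =
inter-gene intervals walking the circle, the wrap-around spacer across
the origin emitted once and named after its flanking genes; zero-length
spacers are skipped.

Simple indel coding: every distinct *internal* maximal gap span observed
in any taxon is one binary character; a taxon scores 1 with exactly that
gap, ? when one of its own gaps (or a terminal gap, treated as missing
data) strictly subsumes the span, 0 otherwise — including partial
overlaps, which the coding literature treats as distinct characters with
the absent state. The implementation is verified against an independent
literal-rule oracle exhaustively on all small gap patterns.

Inversions are user-supplied spans (their detection was manual in the
workflow this supports): each distinct span is one presence/absence
character and carriers' spans are reverse-complemented in the output so
sites align positionally. Concatenation is name-sorted (hence invariant
to input order), missing taxa are filled with `?`, and the binary
characters form a second partition in the exported PHYLIP/NEXUS/RAxML
files. Multiple alignment and tree search are external.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
dial. Defaults emulate the target genome: LSC 87,600 bp, SSC 13,400 bp,
IRs 30,500 bp (total 162 kb), 80 genes (≈ 85% in the LSC including the
conventional 5' gene block, ≈ 15% in the SSC, one intron-containing gene,
random strands), GC fraction 0.37. CDS genes are valid reading frames
(ATG…TAA, no internal stops); spacers and IRs are random sequence at the
genome GC. Genes are kept out of the IRs so that annotation transfer on
clean genomes is unambiguous. Region junction bases are fixed (first base
A, last base ≠ T per single-copy region) so that exact repeat extension
across junctions is blocked and detection recovers the planted arm length
exactly; the same constraint makes the generated SSC orientation the
lexicographically canonical one.

Reads: paired 150 bp from ~300 bp fragments (Normal insert, sd 30),
fragment starts sampled proportionally to a per-base coverage profile,
circular wrap-around supported, substitution-only errors at a constant
phred-40 quality. IR reads arise from both copies because the profile is
defined on the canonical genome. Note that 300 bp fragment sampling
smooths the realized coverage: a 250 bp dip in the *profile* realizes
shallower in mapped depth, so profile-level dips and realized flags are
asserted separately.

Individuals: `mutate_individual` plants exact numbers of substitutions
and single-base indels at recorded positions in the single-copy regions
(IR optional), separated by ≥ 30 bp and kept ≥ 60 bp from junctions so
alignment recovers exactly the planted counts. The default two-individual
emulation (2 substitutions + 1 indel = 3 differences) mirrors the
magnitude of intra-species plastome diversity in narrow endemics.

Assembler defects (10 modes, applied in order, each with truth):
junction_split (2 contigs broken at the IRb/SSC junction),
ir_expansion_compensated (IR grows into the LSC; LSClendif = IRlendif),
lsc_duplication_adjacent_ir, ira_truncation, missing_5prime_lsc_block
(default 17 genes), snp_cluster_low_coverage (placed in the largest
spacer-free-of-genes region by default start), spurious_insertion
(length uniform in [170, 334] bp), flipped_ssc, rotated_start,
polyN_insertion. Magnitudes that interact with exact-repeat extension at
junctions (IR expansion, IRa truncation, 5' deletion) are nudged by a
base or two when the flanking base would extend the repeat, and the truth
record always states the effective magnitude — recovery tests compare
against the record, never against nominal inputs.

What the generator does **not** emulate: indel sequencing errors,
quality-score profiles, GC-dependent coverage bias, heteroplasmy beyond
the SSC isomers, nuclear/mitochondrial plastid-like reads, or any
specific assembler's algorithm. Passing tests therefore demonstrate the
analysis stack's correctness on well-posed inputs, not robustness to
every artefact of real libraries.

## Problem sizes and numerical choices

The test suite and examples run a 54 kb plastome (LSC 30 kb, IRs 9 kb,
SSC 6 kb, 40 genes) that preserves every structural property of the
full-size genome at a fraction of the runtime; the acceptance script uses
the full-size 162 kb genome for structure, comparison, and defect
recovery, and 10–12 kb genomes at 1,000×/2,000× for the capping
contract (tens of thousands of read pairs). Rolling-hash modulus
2^31−1 with per-candidate verification; anchor k = 21 for ordering,
alignment, and NGA50; diagonal tolerance 50 bp for block chaining; all
simulation randomness flows through explicit integer seeds
(`numpy.random.default_rng`).
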