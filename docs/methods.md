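# Methods

## Setting and assumptions

Immunoglobulin genes are somatic mosaics: one V, optionally one D, and one
J germline segment joined with non-templated junction bases, then mutated
by somatic hypermutation (SHM). The package therefore never compares reads
against a whole-gene reference. All inference is anchored on (a) a library
of germline *segments* with region and frame annotations, and (b) the
assumption that sequences sharing a V(D)J assignment descend from a single
rearrangement, so their pre-mutation ancestor can be reconstructed as
library segments plus a majority-vote junction.

Coordinates are 0-based half-open throughout. Qualities are Phred+33 on
disk; Phred+64 input is rejected with an explicit error rather than
guessed at.

## Cleaning

Samples are coded by a MID tag pair, one tag per read end (the reverse tag
appears reverse-complemented on the forward strand). Matching is anchored
at the read termini and exact by default (`mid_max_mismatches = 0`):
anchoring reflects where ligated tags physically sit, and exactness avoids
cross-sample misassignment, the costliest failure mode. A read is tried
as-is and, if its pair is not listed in the sample sheet, as its reverse
complement — a reversed read presents its pair swapped, and treating that
as a chimera would discard every reverse-oriented read. A pair that is
identifiable in some orientation but unlisted in either is classified a
PCR chimera. This makes cleaning idempotent under orientation: a read and
its reverse complement yield the same sample and retained sequence.

Primers are located within a terminal window of `len(primer) +
max_mismatches` bases by unit-cost edit distance (substitutions,
insertions and deletions all cost 1), because pyrosequencing homopolymer
errors hit primer regions too; an exact substring scan runs first and the
DP reproduces it identically. Ties are broken by cost, then by placement
closest to the read terminus, then by span closest to the primer length.
The matched span is trimmed, since primer-region mismatches are PCR
artifacts that must not be counted as somatic mutations later.

The cascade order is fixed — MID pair → chimera → primers → length →
quality — and each read lands in exactly one category, so the report
partitions the input exactly, per sample and in total. Thresholds are
inclusive (`≥`); mean quality is computed on the fully trimmed read. The
default length window is 250–600 nt (typical 454 Ig amplicons) and the
default mean-quality threshold is 25; both are configurable.

## Duplicate collapsing

Uniqueness is exact string identity of the bases. Sequences differing by a
single base are distinct uniques — near-duplicate clustering would erase
exactly the variation SHM analysis is after. The first occurrence is the
representative (it keeps its own quality string); scope is strictly per
sample.

## V(D)J assignment

Segments are found by Smith–Waterman local alignment with match +2,
mismatch −3, gap open −5, gap extend −2 — fixed published-style scoring so
results are deterministic and oracle-testable. V is chosen over all V
segments; J over the read suffix after the V match; ties go to the longer
matched span, then the lexicographically smaller segment id. Matches are
then extended ungapped to the outer read boundaries: local alignment clips
terminal mismatches, and an uncovered read prefix/suffix would otherwise
reappear downstream as a phantom indel against the clone consensus.

D is called only on an exact-or-one-mismatch ungapped match of at least
`min_d_length` (default 5) inside the junction; junction D identification
is unreliable, and an absent D never blocks clone grouping.

The reading frame comes from the V segment's annotated codon phase carried
through the alignment. A rearrangement is *indeterminate* when the matched
J span is below `min_j_overlap` (default 10 nt) — too little evidence to
anchor the 3' frame; *non-functional* when the junction shifts the J
segment's FR4 out of the V-established frame or the in-frame translation
contains a stop before the end of FR4; otherwise *functional*. CDR3 is
defined junction-centered: end of V FR3 through start of J FR4. Reads
failing assignment (no V or J above `min_segment_score`, default 40) are
set aside and counted, never silently dropped.

## Clones and consensus germline

Clones are keyed by (V, D-or-none, J); including D is the default and can
be switched off. Within a clone, sequences are multiple-aligned by
center-star: the center minimizes summed pairwise edit distance (ties:
longest, then first), every other sequence is globally aligned to it
(match +1, mismatch −1, gap −2), and pairwise alignments merge under
"once a gap, always a gap". For the low-divergence sequence sets that
clones are, center-star is near-optimal, exactly reproducible, and needs
no external aligner binary.

The consensus germline takes the V and J library bases verbatim over the
widest member-matched spans and a column-majority junction, with the gap a
votable symbol: a majority gap drops the column, and ties resolve in the
fixed order A < C < G < T < gap. Members plus consensus are then
re-aligned (consensus row first in the PIR output), region boundaries are
re-derived on the consensus by re-running segment assignment on it, and a
Metadata summary is written per clone. Known limitation, preserved
deliberately: grouping by segment identity alone can merge independent
rearrangements that happen to share V(D)J; junction-identity clonotyping
is out of scope.

## Homopolymer indel artifacts

Pyrosequencing miscounts homopolymer run lengths, and without a gene
template the only reference for indel calling is the clone's own consensus
germline. Indels are read off the finalized clone alignment (maximal gap
block in the consensus row = insertion; in the member row = deletion;
positions on ungapped consensus coordinates). An indel is an *artifact*
when its length is at most `max_artifact_len` (default 2), it lies in or
within `flank` (default 1 nt) of a homopolymer run of length ≥ `min_run`
(default 3), and its bases repeat the run base — except that an insertion
falling strictly *inside* a run is accepted regardless of the reported
base: when a point substitution sits in the same run, the pairwise aligner
merges the two events and blames the substituted base for the gap, so
insisting on base identity there systematically misses real run-length
errors. The three knobs come from the 454 error literature and are
configurable and logged.

Sequences partition into indel-free / artifact-indel / genuine-indel sets;
bases are never edited. The default pipeline proceeds with indel-free
sequences only, but genuine-indel sequences are written to their own
output so real SHM indels remain available. In clones of two or three
members an artifact can contaminate the consensus junction and shift blame
onto a sibling sequence; both then leave the indel-free set, which is the
conservative outcome.

## Lineage trees

Each clone gets a rooted tree whose root is the consensus germline and
whose every edge carries exactly one mutation event — a substitution or an
atomic insertion/deletion block. Construction: (1) each member becomes its
mutation set relative to the consensus; (2) the node set is closed under
pairwise intersection to a fixed point, yielding inferred common
ancestors; (3) each node attaches to the largest proper subset present
(ties prefer observed nodes, then the smaller node id; nodes with no
proper subset attach to the root); (4) edges carrying k > 1 events expand
into chains of k−1 inferred intermediates, applied in ascending position —
the within-edge order is unobservable, so a fixed convention keeps output
deterministic.

Under the infinite-sites condition (no site mutated twice within the
clone) the member sets form a laminar family, the construction recovers
the unique perfect phylogeny, and the tree cost (edge count) equals both
the union of the members' mutation sets and the brute-force Steiner
minimum — this is asserted against an exhaustive oracle in the tests. With
homoplasy the construction is a deterministic heuristic; topology
tie-breaks are conventions, not biology. Trees are emitted as adjacency
TSV, Graphviz DOT (observed nodes boxed, inferred oval; rendering is left
to Graphviz) and Newick with unit branch lengths. Graphical measures per
tree: node/leaf counts, root outdegree, leaf depth min/mean/max, trunk
length (root to first branching node), mean internal outdegree. Size-1
clones stay in repertoire counts but are skipped by tree building.

## Mutation statistics

Mutations are counted per tree *edge*, not per sequence — a mutation
shared by many descendants is one event; this is the point of tree-based
counting. For substitution edges the parent and mutated codons are
translated in the clone's consensus frame: same amino acid = silent,
different = replacement, per region from the consensus region map. Codons
containing gaps or N, positions upstream of the frame start, codons made
ambiguous by an upstream indel on the same path, and nonsense codons
(stop gained or lost) are `not_applicable` — the last exclusion keeps
R = total of the 20×20 amino-acid substitution matrix an exact identity.
The R/S ratio is reported NA when S = 0. Hotspot motifs default to the
canonical SHM targets — WRC/GYW with the C/G mutated and WA/TW with the
A/T mutated (W = A/T, R = A/G, Y = C/T) — evaluated in the parent
sequence's context; the fraction is NA when a tree has no substitutions.

## Repertoire tables

V–J usage is tabulated on the full cartesian grid of gene-level names
(allele suffixes stripped), zero-filled, as clone counts and
unique-sequence counts with percentages of the sample totals (0 when the
total is 0). Group averages are unweighted means of per-sample
*percentages*, so each individual contributes equally regardless of
sequencing depth — the appropriate normalization when PCR bias makes raw
depths incomparable; averaging percentages deliberately differs from
pooling counts, and a test pins that difference. Clonal size tables
report, per clone, unique members and total sequences (members plus their
PCR duplicates).

## Synthetic data

The simulator generates what the pipeline consumes: per clone a random
V(D)J rearrangement with a 6–15 nt junction; per member independent
per-base substitutions (default 2%, a realistic mutated-repertoire load);
optional single-base indels injected inside homopolymer runs ≥ 3 (default
5% of reads) emulating pyrosequencing artifacts; PCR duplicates (30% of
reads gain a geometric number of exact copies); dual MIDs and primers at
both ends; Gaussian per-base qualities (mean 32, sd 4, clamped to [2, 40]
— the cleaner only uses means, so the model is deliberately minimal);
30% of reads reverse-complemented; and optional defect classes
(unrecognizable MIDs, chimeric pairs, degraded primers, low quality) to
exercise every discard category. Every emitted read has a truth row.

What it does not emulate — and what passing tests therefore do not show —
includes flowgram-level 454 error structure, lineage-correlated mutation
histories (members mutate independently off the germline; multi-step
lineages are constructed directly in the lineage tests), indel SHM, and
real IMGT allele structure (the toy library's six ~300 nt V segments are
stop-free random codons with ≤ 80% pairwise identity, far more diverged
than real V alleles, which makes segment recovery easier than in
production use). The library loader accepts real annotated IMGT-style
FASTA for production work.

## Problem sizes and numerics

Test and acceptance runs use corpora of roughly 1,000–1,200 reads across
2–3 samples, 500-read/500-replicate arms for the recovery and sensitivity
rates, 1,000 random instances for the primer-DP oracle and 200 for the
lineage Steiner oracle — sizes at which every property is measured tightly
while the whole suite stays fast. All randomness is seeded; identical
configurations produce byte-identical outputs (wall-clock timings are kept
in a side log, outside the deterministic ledger). Integer scoring
throughout the DP kernels avoids floating-point ties; percentage sums are
checked to 1e-9.
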