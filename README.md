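# igpipe

Template-free analysis of high-throughput immunoglobulin (Ig) gene
sequencing, from raw multiplexed amplicon reads to clonal lineage trees,
mutation statistics and repertoire tables.

## The problem

Ig (antibody) genes are assembled somatically from V, (D) and J germline
segments with non-templated N-nucleotides at the junctions, then further
diversified by somatic hypermutation. As a consequence **no whole-gene
reference exists**: generic read-cleaning and variant-calling tools, which
compare reads against a template, cannot process Ig amplicon data. Every
step has to work from the read itself plus a *segment* library, and the
pre-mutation ancestor of each clone has to be reconstructed rather than
looked up.

`igpipe` implements the complete workflow for this setting:

1. **clean** — assign reads to samples by the MID (multiplex identifier)
   tag pair at both read ends; discard reads whose identifiable pair is
   not in the sample sheet (PCR chimeras); locate and trim primers by
   bounded-cost edit-distance dynamic programming; filter by length range
   and mean Phred quality. Every discarded read is counted in exactly one
   category, so `input = retained + Σ discards` holds exactly.
2. **dedup** — collapse exact duplicate sequences per sample (PCR copies),
   keeping a representative → duplicates map.
3. **assign** — find the highest-homology germline V and J segments by
   Smith–Waterman local alignment (match +2, mismatch −3, gap open −5,
   gap extend −2); call a D segment only on a near-exact junction match;
   reconstruct the read's germline and FR/CDR region map; classify the
   rearrangement as functional / non-functional (frame shift or premature
   stop) / indeterminate (J evidence too short).
4. **clones** — group sequences sharing the same V(D)J key; align each
   clone (center-star multiple alignment); build the consensus germline =
   library segments + column-majority junction; re-align members against
   it; emit per-clone Metadata.
5. **indels** — call insertions/deletions against the clone consensus and
   flag short indels in or next to homopolymer runs as 454-style
   sequencing artifacts; partition sequences into indel-free /
   artifact-indel / genuine-indel sets.
6. **trees** — per clone, a rooted lineage tree (root = consensus
   germline) in which every edge is exactly one mutation; unobserved
   ancestors are inferred by intersection-closure of mutation sets.
   Exact minimum-mutation (Steiner) trees under infinite sites.
7. **mutations** — replacement/silent (R/S) counts per region counted
   once per tree edge, a 20×20 amino-acid substitution matrix, and
   AID/pol-η hotspot motif fractions (WRC/GYW, WA/TW).
8. **repertoire** — V–J gene usage tables (counts and percentages),
   depth-normalized cross-sample averages, clonal size distributions.

A ground-truth simulator (`igpipe.simulate`) emulates 454-style Ig
amplicon corpora — rearrangements, hypermutation, homopolymer indel
artifacts, PCR duplicates, dual MIDs/primers, mixed orientations — so
every stage is tested against known truth without external data.

## Worked example

```bash
igpipe simulate --seed 3 --n-samples 1 --n-clones 4 --out sim/
igpipe run --config run.cfg        # see below
```

with `run.cfg`:

```
fastq=sim/reads.fastq
sample_sheet=sim/samples.tsv
mids=sim/mids.tsv
primers=sim/primers.tsv
library=sim/library.fasta
out_dir=out
```

prints the per-stage ledger, e.g.

```
clean            ALL          in=18      out=18
dedup            S1           in=18      out=11
assign           S1           in=11      out=11
clones_pass1     S1           in=11      out=5
indels           S1           in=11      out=11
functionality    S1           in=11      out=2
clones_final     S1           in=11      out=5
trees            S1           in=5       out=3
mutations        S1           in=3       out=65
repertoire       S1           in=5       out=24
```

reading: 18 reads all cleaned into sample S1; 11 unique after duplicate
collapse; all 11 assigned a V(D)J and grouped into 5 clones; none carried
indels; 2 of 11 were functional (the rest carry out-of-frame junctions or
junction stop codons — expected for uniform random junction lengths);
lineage trees were built for the 3 clones with two or more members,
carrying 65 mutation-edge records; the V–J usage grid has 6 × 4 = 24
cells. Under `out/` each sample has `assignments.tsv`, per-clone
`metadata.tsv` + `alignment.pir`, `indels.tsv`, `trees/*.adj.tsv|.dot|.nwk`,
`rs_table.tsv`, `aa_matrix.tsv`, `hotspots.tsv`, `vj_*.tsv`,
`clonal_sizes.tsv`, and a group-average V–J table across samples.

Individual stages run standalone (`igpipe clean`, `igpipe dedup`,
`igpipe assign`, `igpipe clones`) on each other's on-disk outputs.

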