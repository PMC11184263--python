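# Methods

This note records the models, conventions and deliberate design choices
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Coordinates, alphabets, formats

All in-memory and GFF3 coordinates are 1-based inclusive. The only
half-open, 0-based coordinates in the package are in the BED-like motif
export, whose header says so. Nucleotide sequences are `ACGTN`
(case-folded on input; `U` is rejected rather than converted, since the
pipeline never consumes RNA FASTA); peptides are the 20 amino acids plus
`*` and `X`. The FASTA writer wraps at 60 columns so round trips are
byte-exact. Parsers never drop rows silently: malformed rows are hard
errors carrying the line number, and duplicate sequence ids, empty
sequences and alphabet violations abort with the offending id/characters
named.

## Scaffolding preparation

In-silico mate pairs transfer the contiguity of a donor assembly to a
scaffolder. For each insert size *s*, fragments are tiled from position 1
in steps of `step` while they fit; read1 is the first `read_length` bases
of the fragment and read2 the last, with read2 reverse-complemented under
FR orientation (read1 under RF). Pairs in which either read exceeds
`max_n_fraction` N content (default 0.1) carry no linking signal and are
dropped and counted. Insert-size presets are 2/5/10/15 kb for short-read
donors and 2/5/10/20/50/75/100 kb for long-read donors. Defaults of
`read_length=100`, `step=500` and FR orientation are declared package
defaults — the donor-assembly tooling this stage emulates does not
publish its values — chosen because 100 bp mimics the short reads
scaffolders accept and a 500 bp step gives dense joins at desk scale; all
are configurable, and the emitted SSPACE-style library manifest records
the orientation and error fraction (default 0.25) per library.

Gap breaking removes every maximal N-run *strictly longer* than
`max_gap` (default 5000) and splits the scaffold there; pieces are
renamed `<orig>.<k>` left to right and pieces shorter than
`min_piece_length` (default 200) are dropped and counted. A gap is a run
of `N` only — soft-masked lowercase has no gap semantics, because the
gaps being removed are scaffolder-inserted. The operation is idempotent
and conserves non-gap bases (both enforced by tests). The generic length
filter is strict (`< min_len` dropped); the pipeline default applies it
to assembly sequences, though the same function serves read filtering.

## Assembly statistics

N50 is the length of the sequence at which the descending cumulative
length first reaches half the total; it is always the length of a member
sequence. GC content is `100·(G+C)/(A+C+G+T)` — N is excluded from the
denominator, the common convention for gapped assemblies, and the choice
is fixed here because summary tables rarely state theirs. All printed
percentages round half-up (not banker's), which reproduces published
two-decimal completeness values deterministically from their found/total
counts. Throughput in gigabases is `pairs × read_length × 2 / 10^9`,
half-up to one decimal.

## Missed-gene rescue

A candidate is an orthogroup whose focal protein-model column is empty
while the focal transcript column and at least one outgroup column are
non-empty. Novelty confirmation rejects a candidate if *any* of its
transcripts aligns to an existing gene model with E-value strictly below
1e−6. ORF extraction scans all six frames: an ORF is a maximal stop-free
codon run ending at a stop or at the frame end; with `allow_partial`
(default) the run at the frame start may lack ATG and is emitted as a
5′-partial CDS — mirroring downstream start-codon correction as an
attribute rather than coordinate surgery — otherwise runs are trimmed to
their first ATG. Ties break by frame order +1,+2,+3,−1,−2,−3 then smaller
start. The 30-codon minimum (configurable) prevents spurious two-codon
"genes" on random sequence. When a candidate has several transcripts, the
longest ORF overall is kept and alternates recorded. Genome placement is
format-level (any 12-column hit table): a candidate whose coding region
hits more than one distinct scaffold is rejected as unplaceable, one with
no hits as unaligned; HSP coordinates on a shared scaffold are not
inspected, only scaffold identity. Emitted gene/mRNA/CDS features use
transcript coordinates (translating the CDS reproduces the stored
peptide); lifting to genome coordinates would require alignment
coordinates that the 12-column hit format does not carry.

## Single-copy ortholog consolidation

Three routes feed the final set, with provenance precedence
direct > tree > isoform:

1. **direct**: orthogroups with exactly one member of each focal species,
   unioned across clustering runs (labelled by MCL inflation). A gene
   appearing with two distinct partners anywhere across runs is a
   conflict; the gene and all its pairs are removed (conservative,
   mirroring discard-on-conflict practice) and reported.
2. **tree**: cherries — internal nodes whose leaf set is exactly one gene
   of each focal species — in midpoint-rooted gene trees with at least
   four leaves (the consolidation is run on orthogroups of four or more
   genes). A strict two-leaf cherry is required by default; genes in more
   than one cherry are ambiguous and dropped. Midpoint rooting places the
   root halfway along the longest leaf-to-leaf path; ties among equally
   long paths break by lexicographically smallest leaf-label pair, a
   midpoint landing exactly on an internal node roots there, and
   all-zero-length trees root at the first internal node with a warning.
   Leaf labels map to species via a configurable prefix regex
   (default `^([A-Za-z0-9]+)_`).
3. **isoform**: orthogroups that collapse to exactly one locus per focal
   species once a trailing isoform suffix (default `.t<n>`/`.i<n>`) is
   stripped; cross-run conflicts are discarded as in route 1.

The finalized set merges identical pairs (provenance unioned), removes
genes with different partners across routes, and is asserted to be a
partial matching on every output. Alignment and tree inference themselves
are upstream tools; this module starts from tables and newick.

## Chitinase motif and classification

The catalytic signature is modelled as ordered elements — literal
residue, any-non-stop (`[^*]`), optional-any-non-stop (`[^*]?`) — with
the canonical pattern F,D,G,(X),D,X,D,X,E. Scanning enumerates leftmost
non-overlapping matches with the optional element greedy (the longer
variant preferred at equal start; only presence/absence matters for
classification, so this affects reporting only). Genome scanning
translates all six frames (stops `*`, ambiguous codons `X`, trailing
bases dropped) and converts match positions to forward-strand 1-based
coordinates; the reported span always translates back to the matched
peptide. Ambiguity (`X`) satisfies the non-stop classes but fails
literals; a strict mode makes `X` fail classes too. Intron-interrupted
motifs are missed by design — the scan is splice-unaware.

Reciprocal best hits use bitscore as the "top hit" metric (stable under
database-size changes, unlike E-value), ties broken by smaller E-value
then lexicographic subject id, with tie events logged. A protein is a
*chitinase* when it is an RBH partner of a true-chitinase query and
carries the motif; *chitinase-like* when it has a Glyco_hydro_18 domain
at independent E-value strictly below 0.05 but no motif; otherwise
*neither*.

## Conserved differential expression

Thresholds are inclusive: strict = FDR ≤ 0.001 and |log2FC| ≥ 2, relaxed
= FDR ≤ 0.01; a pair qualifies when either species is strict and the
other relaxed. Direction agreement (same fold-change sign) is required by
default — the biological claim is "higher in the same tissue in both
species" — with a flag to disable it for sensitivity analysis. The two
tables must declare the same contrast orientation in their metadata
header; a mismatch is a hard error. Genes with several rows (isoform-
level DE) reduce to the minimum-FDR row before filtering. DE statistics
and quantification are consumed as tables, not recomputed: the bespoke
content is the cross-species filter. The PCA helper only joins
log2(TPM+1) values over pairs; the PCA fit itself is standard and out of
scope.

## Macrosynteny

Gene position is the midpoint of its span (annotation conventions differ;
midpoint is insensitive to them). For each (scaffold, chromosome) cell
with at least `min_orthologs` (default 3, avoiding single-gene "blocks")
shared orthologs, the one-sided hypergeometric upper tail of the cell
count against the scaffold and chromosome margins is computed and BH-
corrected across all tested cells at alpha 0.05 — the standard exactly
testable choice for synteny-block significance. A scaffold's primary
chromosome is its most ortholog-rich significant cell (ties: smaller q,
then lexicographic id, logged). The chromosome count is the number of
distinct primary chromosomes; a scaffold is a putative translocation when
a secondary chromosome holds ≥5 of its orthologs, ≥10% of its total, and
that cell is itself significant. Degenerate single-chromosome inputs make
the enrichment null undefined (every cell spans the whole table);
scaffolds are then force-assigned to the only chromosome with p = q = 1.
Gene order within scaffolds is deliberately ignored; the dot-plot export
lays chromosomes out in id order and scaffolds by (assigned chromosome,
descending length), so coordinates are independent of input order.

## Synthetic data

The generators emulate the *structure* of a two-species ctenophore
comparison — one fragmented focal assembly, one intact partner genome
that doubles as synteny reference and DE partner — not its sequence
realism. Defaults: 13 chromosomes (the chromosome number at stake in the
synteny analysis), four clustering runs labelled by the MCL inflations
1.5/5/8/10, a 10% missing-annotation rate, 10% isoform expansions, 10%
cherry cases, planted DE effects log2FC ~ Normal(±3, 0.5) redrawn until
|log2FC| ≥ 2 with near-zero p-values against Uniform(0,1) nulls and
BH-computed FDR columns, and translocations that move a block of ≥5 (25%
of a scaffold's) partner orthologs to another chromosome. Genes are laid
out with 300 bp bodies and 200 bp spacers; sequence content is uniform
random, so passing tests demonstrate the *logic* of each stage (set
recovery, coordinates, thresholds), not robustness to real-data artifacts
such as repeats, uneven gene density, codon bias, alignment noise or
partially wrong annotations. Misclustering swaps partner members between
adjacent orthogroups within a run, which other runs expose as conflicts:
recall degrades smoothly with the rate while precision is preserved.
Motif planting back-translates a pattern realization with uniform codon
choice (no codon-usage model) into non-overlapping positions on either
strand, recording exact frames and coordinates; at the genome sizes used
the analytic per-position match probability of the pattern
((1/20)^6·(19/20)^2·(1+19/20)) keeps expected spurious hits well below
one. Every generator threads a single `numpy.random.Generator` seeded by
the caller; identical seeds reproduce byte-identical outputs.

## Problem sizes

The acceptance computation uses 520 ortholog pairs over 13 chromosomes
(two scaffolds per chromosome, 15% translocated scaffolds) for the
recovery metrics, 12 planted motif sites on a ~150 kb genome, and 20
replicates of 5000 pairs over 195 scaffolds with 2% placement noise for
the chromosome-count stability check; oracle-equivalence tests run 1000
random instances per statistic. These sizes exercise every rule and
boundary while keeping the whole suite in seconds on one CPU.

## Known limitations

Rescued gene models are emitted in transcript coordinates (see above).
Genome motif scanning does not splice. The conserved-DE filter assumes
both tables were produced under the same contrast design and replicate
structure; it checks orientation metadata only. The synteny test
conditions on observed margins and, with very few placements, has little
power — cells under `min_orthologs` are never tested. The synthetic DE
model outputs (log2FC, FDR) tables directly rather than count-level
negative-binomial data.
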