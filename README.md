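# ctenokit

Comparative-genomics toolkit for ctenophore (comb jelly) genome projects.
It re-implements, as one tested Python library with a thin CLI, the bespoke
computational stages used to assemble and interpret the genome of the
ctenophore-eating ctenophore *Beroe ovata*:

* **Scaffolding preparation** — in-silico mate-pair libraries cut from a
  donor assembly (fragments tiled along each sequence; the two
  fragment ends become an FR/RF read pair), scaffold breaking at N-gaps
  longer than 5 kb, and minimum-length filtering (<200 bp dropped).
* **Assembly statistics** — N50, GC content (N excluded from the
  denominator), bp in sequences ≥25 kb, BUSCO/CEGMA-style completeness
  percentages and sequencing-throughput arithmetic.
* **Missed-gene rescue** — orthogroups that contain focal-species
  transcripts and outgroup protein models but no focal protein model are
  candidate missed genes; candidates are confirmed novel (no alignment to
  existing gene models at E < 1e−6), reduced to their single longest open
  reading frame over six frames, and kept only when the coding region
  aligns to exactly one genomic scaffold.
* **Single-copy ortholog consolidation** — one-to-one pairs are unioned
  over clustering runs at several MCL inflations, augmented by cherries
  (two-leaf clades of one gene per species) in midpoint-rooted gene trees
  and by orthogroups that collapse to one locus per species after isoform
  suffixes are stripped; any gene seen with two partners is discarded, so
  the final set is a partial matching.
* **Chitinase classification** — the chitin-degrading catalytic signature
  `FDG(X)DXDXE` (as the peptide pattern `FDG[^*]?D[^*]D[^*]E`) is scanned
  over proteomes or whole-genome six-frame translations; proteins are
  called *chitinase* (reciprocal best hit to a true-chitinase query and
  motif present) or *chitinase-like* (significant Glyco_hydro_18 domain,
  independent E < 0.05, motif absent).
* **Conserved differential expression** — an ortholog pair is a conserved
  tissue-defining gene when one species passes FDR ≤ 0.001 and
  |log2FC| ≥ 2, the other passes FDR ≤ 0.01, and the fold-change signs
  agree.
* **Macrosynteny** — orthologs are placed at gene midpoints; each
  (scaffold, chromosome) cell with ≥3 shared orthologs is tested with a
  one-sided hypergeometric enrichment, Benjamini–Hochberg corrected;
  scaffolds get a primary chromosome, the count of distinct primary
  chromosomes estimates the chromosome number, and scaffolds with a
  significant, well-populated secondary chromosome are flagged as
  putative translocations.
* **Synthetic data** — seeded generators produce every input the pipeline
  consumes (two-species genomes with known linkage, orthogroup tables
  with planted one-to-ones/paralogs/isoforms/missing annotations, gene
  trees with planted cherries, DE tables with planted conserved genes,
  genomes with planted catalytic motifs), each with a ground-truth
  manifest, so every stage is testable without any download.

## Worked example

Simulate a two-species genome, consolidate single-copy orthologs and infer
the chromosome number:

```sh
ctenokit simulate genomes --seed 5 --out gsim
ctenokit simulate orthogroups --seed 5 --out osim
ctenokit scos --runs "i1.5=osim/orthogroups_i1.5.tsv,i5=osim/orthogroups_i5.tsv" \
    --trees osim/trees --species-a Bova_prot --species-b Ml \
    --tree-species-a Bo --tree-species-b Ml
ctenokit synteny --pairs single_copy_orthologs.tsv \
    --gff-a gsim/species_a.gff3 --gff-b gsim/species_b.gff3
```

which prints

```
234 single-copy ortholog pairs -> single_copy_orthologs.tsv
234 placements (0 skipped); estimated chromosome count 13; 0 putative translocations
```

The 234 pairs are the simulation's 182 directly clustered one-to-ones plus
26 rescued from tree cherries and 26 from isoform collapsing (the
remaining 26 planted genes are missed-annotation rescue targets, which by
construction have no protein model to pair). The chromosome count of 13
matches the planted linkage structure: scaffolds map to mutually exclusive
chromosomes of the partner species.

Library use mirrors the CLI: each stage is a plain function over explicit
domain types (`Assembly`, `HitTable`, `OrthologPair`, ...) in
`ctenokit.scaffold`, `ctenokit.stats`, `ctenokit.rescue`,
`ctenokit.orthologs`, `ctenokit.motifs`, `ctenokit.dge`,
`ctenokit.synteny` and `ctenokit.simulate`.

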