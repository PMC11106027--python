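# polyxpop

Amino-acid homorepeats (polyX) — runs of a single residue such as
polyglutamine (polyQ) — mutate by DNA replication slippage and are
therefore candidate mutational hotspots. Expansions of polyQ tracts beyond
critical lengths cause nine neurodegenerative diseases, yet naturally
occurring, apparently benign length variation of the same tracts within
the human population is far less studied. `polyxpop` is a pipeline for
quantifying that variation from large population-variant catalogues: it
detects homorepeats in a reference proteome, overlays protein-level
variant records, measures how often repeats of each length stratum carry
variants compared with random regions of matched length, classifies the
variant types observed inside polyQ tracts, and scores how well each long
polyQ tract's length is conserved across primate orthologs.

It is written for computational biologists working with population
catalogues (gnomAD-style allele-count data), a one-protein-per-gene
reference proteome, and ortholog alignments; a fully seeded synthetic-data
module generates all inputs at desk scale with ground truth.

## Method

1. **Homorepeat scan.** Maximal pure runs of one amino acid with length
   ≥ 3 (1-based inclusive coordinates), stratified into length classes
   `3`, `4-5`, `6-7`, `8+`.
2. **Variant ingest.** Simplified protein-level records
   (protein, reference residue, position, type, span, allele count AC).
   Exome- and genome-derived sets are pooled by site key (allele counts
   summed) and filtered at AC ≥ 10; single sets use AC ≥ 100. Insertions
   whose inserted residues equal the reference substring immediately
   preceding the anchor are refined to *duplications* — inside a repeat,
   a slippage repeat-unit gain.
3. **Overlap enrichment.** Per length class, the fraction of repeats
   intersecting ≥ 1 variant interval is compared with the same fraction
   for 10 000 random regions resampled from the class's empirical length
   distribution and placed uniformly over the proteome; the ratio is the
   fold enrichment.
4. **polyQ variant classification.** Variants intersecting polyQ tracts
   are tabulated per (length class, type label) with distinct-site counts
   and summed allele counts (`Gln > Arg`, `Deletion`, `Duplication`,
   `Frameshift`, `STOP`, `Insertion`).
5. **Conservation.** For each polyQ ≥ 8, the tract is mapped to its
   column span in a MAFFT-style ortholog alignment (six primates), the
   glutamines each species aligns into the span are counted, and the
   sample standard deviation (SD) of those counts summarises cross-primate
   length conservation. With-variant tracts are split into
   large/medium/low variation tertiles and compared by variant status and
   disease annotation.

## Worked example

The bundled deterministic fixture encodes a toy proteome with polyQ
tracts in every length class and a raw variant table (duplications
written as plain insertions) whose classification reproduces a published
per-length-class polyQ variant-type table:

```sh
polyxpop fixture -o fx
polyxpop run-all --proteome fx/fixture_proteome.fasta \
                 --variants fx/fixture_variants.tsv \
                 --mapping fx/fixture_idmap.tsv -o run
```

The run report prints:

```
proteins: 15
homorepeats (min length 3): 15
variants after filtering/mapping: 389 (AC >= 10)
residue coverage: 20.72%
overall overlap frequency: 80.00%
```

and `run/polyx_variant_table.tsv` begins:

```
length_class  type_label  n_sites  sum_allele_count
3             Gln > Arg   14       105904
3             Gln > His   13       176822
3             Gln > Glu   10       341790
...
8+            Deletion    90       1547410
8+            Duplication 81       452267
8+            Frameshift  51       579171
```

`n_sites` counts distinct variant sites (position + type + alternate)
inside tracts of that class; `sum_allele_count` totals the individuals
carrying them. The 8+ rows show the slippage signature: long tracts vary
mostly in length, with deletions carried by ≈3.4× more alleles than
duplications, while classes 4–7 gain duplications about twice as often as
deletions (by sites).

Synthetic full-pipeline inputs (proteome + variants + ortholog
alignments, with ground-truth tables and a checksummed manifest) come
from `polyxpop simulate -o synthetic --seed 42`.

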