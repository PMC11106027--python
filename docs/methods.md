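# Methods

## Repeat model and coordinates

A homorepeat is a *maximal pure* run of one amino acid: every residue in
the interval equals the repeat residue and both flanking residues (when
they exist) differ. All intervals in the package are 1-based inclusive,
matching protein-position conventions in variant annotation; a BED-like
0-based half-open export is available and clearly flagged. Non-standard
letters (X, U, B, Z) are tolerated in sequences but excluded from repeat
output unless `include_nonstandard=True`: repeats of interest are runs of
the twenty standard amino acids. An impurity-tolerance parameter for
near-pure repeats is deliberately absent — only exact runs are in
validated scope.

Length classes `3`, `4-5`, `6-7`, `8+` partition the integers ≥ 3. The
lower bound of the longest class is **length ≥ 8** ("8+"), consistent
with the ≥ 8-glutamine threshold used for the ortholog conservation
analysis. Class labels use ASCII hyphens so every TSV, CLI flag and file
name is 7-bit safe.

## Variant records

Records are consumed at protein level: one row per (protein, position,
type, alternate/insert, span) with an allele count (AC). AC is treated as
an opaque prevalence weight — whether the source counted alleles or
carriers does not affect any computation here. Synonymous rows are
rejected at parse time. The *site key* includes the alternate residue or
inserted sequence, so two substitutions at one position are two sites;
this is what the distinct-site counts in the classification table count.

Merging exome- and genome-derived sets pools allele counts for identical
keys before applying the AC ≥ 10 threshold (pooled evidence for the same
allele); a `mode="union"` flag instead unions records that pass the
threshold individually. Thresholds default to AC ≥ 100 for single-source
sets and AC ≥ 10 for the merged set.

**Duplication refinement.** Source annotations usually encode repeat-unit
gains as plain inframe insertions. An insertion is reclassified as a
duplication iff its inserted residues equal the reference substring of
the same length ending at the anchor position. Inside a polyQ tract this
labels every pure-Q insertion that copies preceding glutamines as a
duplication — the protein-level signature of replication slippage — while
leaving e.g. a proline insertion untouched. Windows extending before
residue 1 never match. Insertions and duplications anchor at a single
residue (the residue whose copy precedes the inserted material);
frameshift and stop records anchor at their first affected residue with
span 1, since their downstream effect is not modelled as a span.

## Overlap statistics and the random baseline

A repeat overlaps a variant iff their inclusive intervals intersect; a
repeat counts once however many variants hit it. The baseline draws, per
length class, 10 000 regions whose lengths are resampled with replacement
from the class's observed repeat lengths and whose placements are uniform
over all valid (protein, start) pairs — longer proteins are
proportionally likelier, regions may overlap each other and true repeats.
Fold enrichment is observed frequency / baseline frequency and is
reported as not-available when the baseline frequency is zero. No
significance test is attached: the fold changes are descriptive.

Proteome variant coverage counts full affected intervals (a 3-residue
deletion covers three positions); an `anchors_only` flag restricts to
first positions.

Every stochastic operation takes an explicit seed; the pipeline default
seed is 20240520, recorded in the run manifest together with SHA-256
checksums of every output, so identical configurations reproduce
identical bytes.

## Conservation scoring

A human tract maps to the alignment columns from its first to its last
residue, *including* interior columns where the human row is gapped: an
ortholog's expanded tract counts fully as aligning with the human region
(a flag restricts counting to human-residue columns). Aligned-glutamine
counts ignore gaps and non-Q residues. The per-tract dispersion is the
sample standard deviation (divisor n−1) over the non-human counts —
chosen because at most six species contribute; `ddof=0` switches to the
population form, and a flag includes the human count itself. SD is
undefined (NaN) below two counts. The measure is descriptive; no
normality is assumed.

With-variant tracts are ranked by SD and split into large/medium/low
tertiles whose sizes differ by at most one, ties broken by accession then
start so the partition is deterministic. Tertiles are a convention, not a
claim about natural clusters; quantile boundaries are configurable.
Disease annotation is a user-supplied (protein, tract start) list. Group
comparisons report both distinct-variant counts and allele-count sums, so
either reading of "variants per tract" is available.

Multiple sequence alignment itself is out of scope: alignments are
consumed as files (MAFFT output in practice), and the human row is
validated against the reference proteome on read.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the biology of any particular database:

- **Proteome** — lengths lognormal (median ≈ 400 aa, clipped to
  60–3000), residues drawn from an approximate human proteome
  composition; homorepeats injected at random non-adjacent positions with
  flanking residues forced to differ, so injected lengths are exact and
  the scanner must recover every truth row verbatim. Accidental
  background runs are allowed elsewhere (full-proteome checks use an
  independent regular-expression oracle instead of the truth table).
- **Variants** — each position independently variant with probability
  0.0145, matching the ≈1.45% residue coverage that population-scale
  catalogues achieve on the reference proteome; types drawn from a
  missense-dominant mix; allele counts from a Pareto-tailed integer
  distribution (shape 1.2, scale 8) that straddles the AC thresholds so
  filtering is genuinely exercised. Duplications are *emitted as raw
  insertions* copying the preceding residues; only correct refinement
  recovers them.
- **Orthologs** — per tract and species, the aligned-glutamine count is
  `max(0, L + rint(N(0, σ)))` with σ = 2 glutamines by default;
  contractions appear as gap columns, expansions as insertion columns
  placed inside the tract span (before its last residue) so column
  mapping is exercised. Expected recovered SDs are validated against a
  Monte-Carlo oracle that applies the identical rounding/flooring — no
  closed-form bias claim is made for the rounded model.

What the generators do **not** emulate: codon structure and nucleotide
context (so no realistic transition/transversion or CpG effects), site
frequency spectra, linkage between variants, alignment errors, ortholog
misassignment, or any correlation between repeat location and variant
rate beyond what a test injects on purpose. Passing tests therefore
demonstrate correctness of the measurement machinery under a known model,
not database-specific real-data values; headline real-data numbers
require the full gnomAD/UniProt/Ensembl inputs through the same code
path, which is documented but not exercised by tests.

The classification worked example is a deterministic fixture: one toy
protein per polyQ tract, with each published (class, type) cell realised
as that many distinct sites at enumerated tract positions and spans, and
the published allele totals split near-evenly across sites. Two published
length-3 `Gln > Lys` rows (7 sites and 1 site) necessarily pool into one
8-site cell here, because tabulation is key-level and aggregates all
sites sharing (class, label); the published split is not reconstructible
from a site table and no cause for it is guessed.

## Numerical and scale choices

- Tabulated rows sort within class by descending site count, label as
  tie-break; tables round-trip bytewise through TSV.
- Calibration tests use a 200 000-residue Q-free proteome: large enough
  that the realised variant rate and the sharing of variants between
  overlapping random regions are small next to the binomial sampling
  error of 10 000 regions, which is the yardstick the closed-form
  1−(1−p)^L check uses. Null fold-enrichment checks build their 99%
  interval from 300 Monte-Carlo replicates of the no-enrichment null.
- SD parameter recovery uses 500 injected tracts per dispersion value and
  a 20 000-replicate oracle per tract length.
- The pooled-evidence merge, per-repeat double counting of multi-repeat
  spanning variants, and interval (not anchor-only) coverage are the
  defaults; each has a flag for the alternative reading.

## Known limitations

- Transcript-isoform resolution is delegated to the supplied
  one-protein-per-gene mapping; no liftover or genotype-level processing.
- The VCF adapter expects per-allele consequence annotation (VEP-style
  CSQ with ENSP/Protein_position/Amino_acids) and covers the five mapped
  consequence terms only.
- Fold enrichments carry no confidence intervals in pipeline output.
- Phylogenetic non-independence of the six primates is ignored: SD treats
  species as exchangeable draws.
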