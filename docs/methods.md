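# Methods

## Agreement model

All comparisons are made at the protein level. A *source* is either a
(tool, gene model) pair — by default the grid {ANNOVAR, SnpEff, VEP} ×
{Ensembl, RefSeq} — or an integration strategy that unions several such
pairs. For each variant the union of all in-scope sources' UniProt
accession sets is the **reference set**; there is no external gold
standard for SNP-to-protein assignment, so the union of everything
observed serves as the pragmatic denominator. A source is *full* when it
equals the reference, *partial* when it is a proper nonempty subset, and
*none* when it is empty. An empty reference (no source annotated the
variant) excludes the variant from agreement statistics; such variants
are counted separately as unannotated.

Two closed taxonomies follow from the status assignments:

* **Tool level (23 categories).** Over three tools there are 3³ = 27
  status triples; the all-none triple is excluded by definition, and the
  three "exactly one nonempty source, with status partial" triples are
  unrealizable (a lone nonempty set necessarily equals the union). The
  remaining 23 are all realizable, verified by exhaustive enumeration of
  the 8³ subset triples of a 3-element universe. Labels are generated by
  a fixed grammar (full tools joined by " and ", partial tools appended
  as "; X subset", none omitted; all-full = "Exact Match", no-full
  prefixed "No full match") in the canonical tool order ANNOVAR, SnpEff,
  VEP. How many of the 23 occur in a given dataset is an empirical
  outcome; the implementation exposes the full space and reports the
  observed subset.
* **Gene-model level (7 categories)** for the pairwise Ensembl/RefSeq
  comparison of within-model unions: Exact Match, each one-sided strict
  subset, each one-sided exclusive case, Partial Overlap and Fully
  Disjoint — again verified exhaustively.

Quantitative coverage is the pair (captured, total) = (|P ∩ R|, |R|).
Integration strategies are pure unions (no prioritization when sources
disagree); the strategy unioning all tools and both models equals the
reference for every variant, so its coverage is 100% by construction —
this identity is the anchor the acceptance script recomputes.

## Identifier mapping

Gene identifiers are routed by namespace according to the gene model
that produced them: Ensembl-model annotations resolve through the
Ensembl-gene-ID index of an HGNC-style crosswalk; RefSeq-model
annotations try Entrez first and fall back to gene symbol (Entrez is the
stable key; symbols drift — the fallback order is a package decision,
exposed in `MODEL_NAMESPACE_ORDER`). Mapping enforces one UniProt
accession per gene to avoid transcript-isoform inflation; a
multi-accession crosswalk cell is resolved to the lexicographically
smallest accession and logged (uniqueness is required, but no canonical
tie-break exists, so we chose a deterministic one). Only approved,
protein-coding rows with an accession map; non-coding rows found in the
crosswalk are excluded and tallied, while identifiers absent from every
consulted index are returned as *unmapped* — deprecated IDs therefore
surface as unmapped counts, never as errors.

## Region classification

Genic/intergenic status is read off ANNOVAR's field routing (gene-role
field populated → genic; closest-gene field only → intergenic; neither →
unannotated), not recomputed from interval intersection. When both
fields are populated the genic call dominates. Within-model analyses use
each model's native boundaries; cross-model analyses standardize every
variant to a fixed reference model (Ensembl by default) so gene-model
boundary differences are not conflated with tool behavior. Variants
genic in one model but missing from the reference model's labels are
reported under the reference label (unannotated) and counted.

## Statistics

Testing on individual SNPs would treat linkage-correlated variants as
independent, so per-variant numerators are summed into annotation events
per chromosome (a SNP mapped to k proteins contributes k events) over
units 1–22 and X. Strategy pairs are compared with two-sided paired
t-tests on the 23 matched chromosome values, Bonferroni-corrected within
each genomic context (whole/genic/intergenic); the default 12-strategy
grid gives C(12,2) = 66 comparisons per context, so m = 66. Degenerate
pairs (identical vectors → t = 0, p = 1; constant nonzero differences →
undefined p) are flagged, not dropped — synthetic fixtures can
legitimately produce them. Significance tiers: ns (p ≥ 0.05), \*
(p < 0.05), \*\* (p < 0.01), \*\*\* (p < 0.001), \*\*\*\* (p < 0.0001).

Pathway overrepresentation uses the one-sided hypergeometric upper tail
(equivalently Fisher's exact test, alternative "greater") of the query
protein set against each pathway, relative to a background reference
list; BH step-up FDR runs across all pathways in the database, and the
significance flag is FDR < 0.05. Query members outside the background
are dropped with a warning (their treatment by external enrichment
services is undocumented; dropping is our stated behavior).

## Synthetic data

The generator defines the study conditions for every test:

| parameter | default | meaning |
|---|---|---|
| `n_variants` | 1000 | variants per table |
| `n_chromosomes` | 23 | chromosome units (1–22, X) drawn uniformly |
| `class_mixture` | 0.699 Exact Match, 0.230 ANNOVAR and SnpEff, 0.040 SnpEff, 0.021 ANNOVAR and SnpEff; VEP subset, 0.010 no-full | category distribution, shaped like genome-wide Ensembl agreement |
| `genic_fraction` | 0.615 | probability a variant is genic |
| `vep_intergenic_dropout` | 0.95 | probability VEP's sets are emptied on an intergenic variant, emulating its tool-native near-absence of nearest-gene assignment |
| `universe_size` | 5000 | distinct genes |
| `max_ref_size` | 3 | cap on per-variant reference-set size (multi-gene SNPs) |
| `frac_deprecated` / `frac_noncoding` | 0.02 / 0.05 | crosswalk rows absent entirely / present without accession |

Planting inverts the classifier: full tools receive the whole sampled
reference set, partial tools a random proper nonempty subset, and
no-full patterns use leave-one-out subsets whose union restores the
reference. Round-trip identity (`classify(plant(label)) == label`) holds
for all 23 labels under the identity protein mapping — planting operates
at the gene level precisely to isolate the classifier from crosswalk
noise. Both gene models plant the same category with independently
sampled genes, so cross-model overlap is at background level. One seeded
`numpy` generator is threaded through all draws; a fixed seed gives
byte-identical artifacts.

What the generator does **not** emulate: realistic coordinates, linkage
disequilibrium, allele frequencies, the empirical distribution of
multi-gene SNPs (exposed as `max_ref_size` rather than fixed), or
correlated tool errors. Passing tests therefore demonstrate the
correctness of the agreement/statistics machinery under controlled
mixtures, not the field behavior of any real annotator.

## Numerical and design notes

* The gene-field parser is total: separators and missing markers are
  dialect-configurable (defaults `;`/`,` and `.`, empty, `NA`, `-`),
  `(dist=N)` suffixes are stripped, and malformed rows are skipped with
  a counted warning rather than failing ingestion.
* Coverage percentages are rendered to one decimal; a zero-denominator
  stratum is reported as undefined (NaN), never 0%.
* Fisher p-values use `scipy.stats.hypergeom.sf` directly (exact to
  machine precision against brute-force tail summation for backgrounds
  ≤ 200 in the tests); BH adjustment uses `statsmodels`' step-up, checked
  against an independent brute-force implementation.
* Problem sizes in the test and acceptance runs — 10,000-variant tables
  for mixture recovery and the union-integration identity, 1,000
  variants in the acceptance script, backgrounds of a few hundred
  proteins for enrichment — were chosen as comfortably sufficient for
  the binomial/chi-square tolerances used while keeping the suite quick
  to run.

## Known limitations

* Genome-wide percentages reported for real multi-million-SNP datasets
  depend on those external resources and are out of scope; the package
  reproduces the framework's structural identities and worked-example
  arithmetic.
* Native annotator output formats (multianno, `ANN=` strings, VEP
  tabular) are not parsed; inputs must be harmonized wide tables.
* Agreement is over protein identity sets only; consequence severity
  (missense vs. synonymous) is ignored by design.
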