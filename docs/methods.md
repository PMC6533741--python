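# Methods

## Scope and model

`cleftminer` implements two hypothesis-testing pipelines around a curated
catalog of candidate genes for cleft lip with or without cleft palate
(CL/P), plus the synthetic generators needed to exercise them.

### Candidate-gene catalog

The catalog is an ordered table of HGNC-style symbols with cytogenetic locus
and a syndromic/nonsyndromic classification.  Symbols are normalized by
trimming, uppercasing and removing internal whitespace; normalization is
idempotent.  Duplicate symbols collapse to the first occurrence with a
warning, and aliases that collide with another record's primary symbol are
dropped in favor of the primary (the literature uses inconsistent symbol
spellings, and silently keeping both would double-count genes in
enrichment).  The packaged catalog contains 172 distinct genes; published
summaries of this literature disagree slightly on the count (172 vs 177,
and one analysis used 161), so the foreground set for any enrichment run is
an explicit argument rather than a hard-coded list.

### Target-map construction

miRNA-target evidence rows are `(source, mirna, gene, validated)`.  Two
filters build the analysis map:

* **Prediction consensus** — a pair must be predicted by at least
  `min_sources` distinct prediction sources.  Only rows with
  `validated == False` count as prediction support, so a validated-evidence
  database can never inflate the consensus count.  The default is 2 of 3
  sources: requiring all three is very conservative given the low mutual
  overlap of target predictors, while accepting any single source is known
  to be noisy; the choice is configurable (1-3) and recorded in run
  metadata.
* **Validated filter** — the pair must carry experimentally-validated
  evidence in at least one source.

miRNA identifiers match case-insensitively (first-seen spelling is kept);
no mature/stem-loop harmonization is attempted.  The background universe
defaults to the union of all surviving target genes — the smallest universe
consistent with the data, which is conservative for enrichment because
every universe gene is targetable by construction.  An explicit universe
(e.g. all protein-coding genes) can be supplied instead and must cover
every target gene.

### Per-miRNA enrichment

Each miRNA is a 2x2 table: k = |targets ∩ foreground|, K = |foreground ∩
universe|, n = |targets|, N = |universe|.  The test is the one-sided
(enrichment-only) Fisher's exact test, i.e. the hypergeometric upper tail
P(X >= k), computed via `scipy.stats.hypergeom.sf` (log-space-stable).
Benjamini–Hochberg q-values are computed across exactly the miRNAs tested
in the run (not genome-wide), via `statsmodels.stats.multitest`.  Rows are
sorted by (q, p, miRNA id) so ties break deterministically and output files
are byte-stable.  Significant miRNAs (q < 0.1 by default) feed the family
rollup: per gene, the number of *distinct known* seed families among the
significant miRNAs whose overlap contains the gene.  miRNAs with no known
family (family id "NA"/missing) are tested for enrichment but excluded
from family counting — a gene targeted only by such a miRNA has 0 families.

### Generic gene-set enrichment

The same hypergeometric statistic runs over GMT annotation collections
(GO/KEGG/HPO-style).  Terms are intersected with the universe; terms whose
foreground overlap is below `min_overlap` are removed *before* testing, so
the BH family contains only tested terms.  Defaults follow common practice
for the two styles of run this supports: 4 for pathway collections, 5 for
phenotype-ontology collections.  No EASE-style modification and no
ontology-level pruning are applied; users pre-filter their GMT if needed.

### Inter-rater agreement

`cohen_kappa` implements κ = (p_o − p_e)/(1 − p_e) for the screening
reliability check in catalog curation, with the convention that p_e = 1
(both raters concentrated on one identical label) returns 1.0.  It is
cross-checked against scikit-learn in the tests.

### Trio TDT

Transmission counting is dosage-based and fully vectorized.  For each SNP
and each trio with all three genotypes present, the child's allele-B dosage
must lie between the minimum forced by homozygous parents and the maximum
permitted by carrier parents; trios failing this Mendelian check are
excluded at that SNP only (per-SNP exclusion preserves the rest of the
family's information and is the standard TDT convention).  Heterozygous
parents then contribute one transmission each; the heterozygous x
heterozygous mating with a heterozygous child is phase-ambiguous and
contributes one transmission of each allele.  The statistic is
(b − c)²/(b + c) with an upper-tail chi-square(1) p-value; SNPs with
b + c = 0 are uninformative and excluded from scan output.

Coordinates: BED intervals are 0-based half-open on disk, MAP positions are
1-based; a SNP at 1-based position p is tested as point p − 1, optionally
with a symmetric flank (default 0, since no windowing rule is implied by
"variants in the genes").  Only biallelic markers are tested; multiallelic
MAP entries are rejected at load with a warning.  Allele A is the
lexicographically smaller observed allele — the statistic is invariant to
this labeling (swapping labels swaps b and c).

Gene-level summary: each gene's p-value is the minimum across its SNPs with
no intra-gene correction, because neighboring SNPs in a gene are typically
in strong linkage disequilibrium and a per-gene Bonferroni would
overcorrect.  Tier labels use genome-wide 5e-8, gene-wide 2.5e-6, and a
candidate-wise Bonferroni threshold alpha / G computed from the number of
genes G actually tested in the run (genes with at least one informative
SNP).  Half-missing trios are dropped at that SNP; imputed-genotype
handling is out of scope (the scan targets directly genotyped variants).

## Synthetic generators

`simulate_target_universe` draws each null miRNA's target set uniformly
without replacement; planted miRNAs draw with foreground genes weighted
`enrichment_odds : 1`.  Defaults (universe 3000, foreground 150, 50 miRNAs,
target sizes 30-80, 3 planted at odds 10) give planted miRNAs an expected
foreground fraction of ~0.34 against a null expectation of 0.05 — strong
but not degenerate enrichment, comparable in spirit to the real analysis
where significant miRNAs had 5-29 candidate genes among their targets.

`simulate_trios` draws parental genotypes under Hardy-Weinberg equilibrium
at minor-allele frequency `maf` (default 0.3, a common-variant regime that
keeps most SNPs informative) and transmits alleles to the child:
homozygous parents deterministically, heterozygous parents transmitting
allele A with probability `tau` (0.5 = null; per-SNP overrides plant
distortion).  Default 300 trios x 200 SNPs keeps an expected ~252
informative transmissions per SNP, enough for the chi-square approximation
to hold.  Each generator call uses a single seeded `numpy` Generator
stream, so identical specs produce byte-identical PED/MAP and target-map
files.

What the generators do **not** emulate: linkage disequilibrium between
SNPs (loci are independent), ascertainment and population structure,
genotyping error and missingness, and the correlated target sets of real
miRNA families (simulated miRNAs draw independently).  Passing tests
therefore demonstrate correctness of the statistics and the planted-signal
operating characteristics, not robustness to those real-data features —
the TDT's stratification robustness, for example, is a design property
that the independent-trio simulation cannot stress.

## Numerical choices

* Hypergeometric tails come from `scipy`'s survival function; the test
  suite verifies agreement with exact big-integer enumeration to better
  than 10 significant digits for every table with N <= 60.
* BH q-values come from `statsmodels`; the suite verifies equality with a
  literal O(m²) implementation of the step-up definition on random
  vectors.  Ties in p share a q-value.
* k = 0 returns p = 1 exactly (P(X >= 0) = 1) without touching the
  survival function.
* Degenerate inputs fail loudly: empty catalogs/interaction lists/pair
  sets raise empty-input errors; out-of-bounds test parameters raise
  domain errors; an all-uninformative panel warns and yields empty output.
* Every output table has a fully specified sort order so reruns are
  byte-identical and diffs are meaningful.

## Sizes used by the packaged checks

The acceptance script measures the TDT type-I error on one panel of
2000 SNPs x 300 trios (standard error ~0.005 around the nominal 0.05), and
recovery rates over 100 seeded runs each for planted enrichment (defaults
above) and planted transmission distortion (tau = 0.75 at one SNP of 50,
10-SNP target gene, 300 trios).  These sizes give stable estimates in a few
seconds; all randomness derives from the script's `--seed`.

## Known limitations

* The published FDR values in the packaged enrichment table cannot be
  re-derived: the raw prediction databases, the exact background universe
  and the raw p-values behind them are not recoverable from the table, so
  the package reproduces its *structure* (gene lists, counts, family
  rollup) and carries the printed values through verbatim.
* The catalog encodes the published summary table as printed, including a
  few entries whose classification differs from the accompanying text
  (e.g. genes listed as nonsyndromic that the text also reports in
  syndromic cases).
* No support for X-chromosome-specific TDT, sibship-based designs, or
  haplotype tests; one child per family is assumed by the simulator
  (the reader accepts any pedigree but only extracts complete trios).
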