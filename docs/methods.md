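# Methods

## Problem and scope

A small number of human polymorphisms are also segregating in chimpanzees at
orthologous positions.  When two or more such shared polymorphisms (SPs)
cluster within 4 kb and sit on a shared haplotype, recurrent mutation is an
unlikely explanation and long-term balancing selection (LTBS) maintaining the
alleles since before the human–chimpanzee split becomes the leading
hypothesis.  `tspfunc` implements the downstream triage and functional
characterization of such candidate regions:

1. **Tier cascade.**  Candidate SP regions are promoted to *cbSP*
   (candidate balanced SP) when they carry balancing-selection scan support —
   an NCD call in at least one population OR a maximum standardized
   BetaScan2 score ≥ 2.0 — and cbSP regions are promoted to *ctSP*
   (candidate trans-species SP) when they additionally show
   identity-by-descent support — ≥ 3 clustered SPs OR an ARGweaver TMRCA
   ≥ 140,000 generations.  All four thresholds are inclusive and both
   criteria at both levels are unions.  The scan statistics themselves
   (NCD, BetaScan2, ARGweaver) are consumed as input tables, never
   recomputed.
2. **LD expansion.**  Each SP is expanded to proxies at haplotype r² ≥ 0.8
   in any of the AFR / EAS / EUR panels, unioned across populations keeping
   the maximum r².  r² is the standard haplotype measure
   D² / (p_A(1−p_A)·p_B(1−p_B)), identical to the squared Pearson
   correlation of the 0/1 allele columns.
3. **Annotation.**  Four evidence classes are attached to the SP-plus-proxy
   universe: Ensembl-regulatory-build-style feature overlap (six feature
   classes, half-open BED semantics), GTEx-style eQTL membership at
   p ≤ 5e-5, GWAS-catalog associations at p ≤ 5e-8 (inclusive) and
   UK-Biobank-style PheWAS associations at p < 1e-8 (strict).  Association
   joins are by rsID; a region inherits evidence carried by any member SP
   or any of its proxies.
4. **Enrichment.**  Three statistics: a constrained permutation null for
   regulatory overlap, one-sided exact binomial tests per trait category,
   and per-tissue odds ratios with two-sided Fisher exact p-values.

## Statistical procedures and numerical choices

**Permutation null.**  The query regions are shuffled across the genome
preserving each region's chromosome and length and avoiding a merged
exclusion set (assembly gaps, blacklist, MHC; the default MHC interval is
chr6:28,477,797–33,448,354 in hg19 coordinates and is configurable).
Placement is exactly uniform over the valid start positions: the maximal
runs of valid starts are enumerated per (chromosome, length) and a start is
drawn by a weighted run choice plus a uniform offset.  This replaces
rejection sampling: it is exactly uniform by construction, never degenerates
when exclusions are dense, and costs one cumulative sum per region.
Shuffled regions may overlap one another, matching bedtools-shuffle
defaults.  The shuffled side is the query set by default; a `shuffle=
"features"` flag permutes the feature track instead, since either convention
appears in practice.  The overlap statistic is the number of
(query, feature) overlapping pairs.

**Empirical p.**  p = (1 + #{null as-or-more-extreme}) / (1 + n_perm), with
ties counted as extreme.  The add-one estimator never returns 0 and is
conservative; its minimum attainable value is 1/(n_perm+1), i.e. ≈ 9.99e-4
at the default 1000 permutations.  Because the statistic is an integer
count, heavy tie mass makes the estimator visibly super-uniform under the
null; calibration checks therefore use feature densities at which overlap
counts are large enough (≈ tens) for the discrete statistic to behave
quasi-continuously.

**Binomial category enrichment.**  For a category with k hits out of n
total and background probability p0 estimated from the full catalog,
p = P(X ≥ k | n, p0) by the exact upper tail.  Bonferroni is applied over
the number of categories tested (394 for a full EFO-style vocabulary;
0.05/394 ≈ 1.27e-4), with a nominal tier at p < 0.05.

**Tissue odds ratios.**  Per tissue, the 2×2 table is foreground (cbSP
variants' eQTL rows) vs background (all other catalog rows) by hit/miss.
OR uses the Haldane–Anscombe +0.5 correction on all cells when any cell is
zero (flagged `corrected`); the p-value is the two-sided Fisher exact test
on the uncorrected table.  Fisher was chosen over a normal approximation
because foreground counts per tissue are small.

**Coordinates.**  Internally 0-based half-open (BED semantics); variant
tables, VCF and GFF3 are converted at the I/O boundary (a variant at
1-based pos occupies [pos−1, pos)).  Chromosome names are normalized to
`chrN`; unplaced contigs pass through.  Strand is ignored throughout.
Mixed naming conventions in one intersection are an error rather than a
silent empty join.

## Synthetic data: what it emulates and what it does not

The generator produces every input with ground truth, at a reduced scale
chosen to keep a full run in seconds on one CPU:

* **Genome**: five 8-Mb chromosomes with two 150-kb exclusion blocks each
  (a stand-in for gaps/blacklist/MHC).
* **Regions**: 125 clusters of 2–4 SPs within 4 kb (80/15/5% mix, mean
  ≈ 2.25 SPs), matching the 125-region / 263-SP scale of the published
  candidate set.  48% of regions get a high Beta score (≥ 2) and 14.4% an
  NCD call; NCD calls are nested inside the Beta set by default because in
  the study the NCD-supported regions were a subset of the Beta-supported
  ones (union still 60/125).  TMRCA is a young/ancient mixture (15%
  ancient ≥ 140k generations, 20% missing), sized so the expected ctSP
  count is ≈ 18 of 60.
* **Panels**: per population, each region is an LD block: every block
  member copies a founder haplotype (frequency ≈ 0.5) and receives
  independent flip noise at rate eps = (1 − t^(1/4))/2, giving expected
  pairwise r² ≈ t (default t = 0.9; t = 1 yields perfect LD).  Decoy
  variants nearby are independent draws.  5% of non-SP panel variants get
  no rsID to exercise the no-rsID exclusion rule.
* **Features**: 5000 features of 800 bp (≈ 10% bp coverage, the order of
  regulatory-build coverage) with a planted fold (default 1.0, i.e. no
  enrichment, matching the study's non-significant regulatory result; the
  enrichment test-beds plant fold 3 explicitly).
* **Catalogs**: 20 trait categories with Zipf background probabilities;
  planted associations draw variants from the cbSP-plus-proxy universe with
  p ~ log-uniform in [1e-12, 1e-8] so they clear both association
  thresholds; 48% of cbSP SPs are planted as eQTL (the study's per-SP
  rate), with tissue draws up-weighted 4× in four planted tissues.

The generator does **not** emulate coalescent genealogies, recombination
gradients, allele-frequency spectra under selection, population structure
beyond independent per-population panels, or catalog biases (LD between
catalog entries, ancestry imbalance).  Passing tests therefore demonstrate
correctness of the counting, thresholding and statistical machinery under
known truth — not power or calibration on real 1000G/GTEx/GWAS data.
Because LD blocks are confined to each 4-kb cluster, the proxy universe per
region (~12 variants) is an order of magnitude smaller than the study's
(~100 per region), so evidence-coverage percentages on synthetic bundles
run a little below the published ones; per-variant rates are matched
instead.

## Degenerate inputs and tie-breaks

* r² is undefined (error) for monomorphic columns at top level; during
  panel-wide expansion monomorphic candidates are skipped silently.
* Unphased VCF panels are refused, not phased.
* Multi-allelic sites are split to one 0/1 column per alternate allele.
* A tag absent from every panel yields an empty proxy set flagged as a
  warning record, not an error.
* Regions with < 2 SPs, SPs outside their region, duplicate region ids,
  p-values of 0, unknown catalog sources and unknown tissue labels are
  rejected at ingest with line numbers.
* An annotation referencing a region outside the matrix universe is an
  error, never dropped.

## Pipeline determinism

One global seed is expanded into per-stage substreams via
`numpy.random.SeedSequence.spawn`; the run manifest records the per-stage
seeds, every threshold applied, per-stage row counts and a sha256 checksum
of each output, and a rerun with identical inputs and seed is
byte-identical.

## Known limitations

* The published headline counts that depend on external catalog releases
  (6,171 LD-expanded variants, 59/60 regions with evidence, 23 regulatory
  cbSPs, 64 eQTL cbSPs, 52 GWAS variants, 150 PheWAS variants) require the
  original supplementary tables and catalog snapshots as inputs; the
  package reproduces the counting given such tables but ships only
  synthetic stand-ins.
* The proxy-search window (500 kb) is a conventional choice; the original
  proxy service's window is unstated.
* GO-term enrichment, colocalization/fine-mapping, liftover and live
  catalog queries are out of scope.
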