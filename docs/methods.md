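# Methods

This note documents the models and procedures implemented in `sigcrypt`,
the assumptions behind them, the tunable parameters with their defaults,
and what the synthetic-data generator does and does not emulate.

## Problem setting

The package analyses somatic mutations accumulated in clonally expanded
organoid lines from a two-group cohort (high-fat diet vs. standard diet;
by default 5 mice × 4 clones per group). Because each line is grown from
a single stem cell, heterozygous somatic variants sit at a variant allele
fraction (VAF) near 0.5, and the mutation catalog of a clone is a direct
readout of the mutational processes that acted in its founder cell. The
question the pipeline answers is whether the two groups differ in their
mutational spectra and signature activities.

## Variant handling

**Consensus calling.** Each clone's variants come from two callers; only
records that PASS both callers' filters and agree on the normalized
`(chrom, pos, ref, alt)` key are retained. Normalization trims shared
allele prefixes/suffixes and left-aligns indels against the reference, so
representational differences between callers cannot break the match.
Records at one locus with conflicting REF alleles are treated as
malformed input. The VAF of a consensus record is taken from the primary
caller; the per-record fallback order when reading a VCF is FORMAT/AF,
then FORMAT/AD (alt / total), then INFO/AF.

**Clonality QC.** A sample passes if the median VAF of its consensus
variants lies in [0.4, 0.6] (configurable window), with at least 50
VAF-bearing records required for a verdict; fewer gives an explicit
*indeterminate* status rather than a failure. The summary also reports
the IQR and the fraction of VAFs below 0.3, which flags subclonal
contamination even when the median is acceptable.

**Channel classification.** SNVs are classified into the 96
pyrimidine-centered trinucleotide channels; purine-reference variants
are reverse-complemented together with their context. The 7-category
collapse splits C>T by CpG status (3' G in pyrimidine orientation).
Indels are classified into the curated 83 channels: 1-bp indels by
homopolymer length (deleted/inserted base collapsed to the pyrimidine
strand), longer indels by the number of tandem copies of the indel
sequence in the flanks (counted on both sides; for deletions the deleted
copy itself is included, so the label index is the unit count minus
one), and deletions with no full flanking copy but a partial one are
scored as microhomology — the longest proper prefix of the deleted
sequence matching the start of the right flank, or proper suffix
matching the end of the left flank. Classification requires flanks of
6 × indel length; a contig boundary legitimately truncates a repeat run
and is accepted when flagged. Adjacent same-sample SNVs are merged into
DBS records, which are counted and reported but not signature-analyzed.
Variants outside the catalog's schema are never dropped silently; they
are tabulated with a reason in the catalog's `unclassified` report.

## Profile comparison

Group profiles are means of per-sample normalized profiles (each clone
contributes equally regardless of burden), with per-channel standard
deviations. Pairwise comparison uses cosine similarity on normalized
columns. The bootstrap comparison draws, per replicate, every sample's
column as a multinomial with the sample's observed total and its
normalized profile as weights, aggregates per group, and averages over
replicates (default 10,000); the cross-group cosine of the averaged
bootstrap profiles is the headline statistic. Per-channel group tests
are two-sided Welch t-tests on per-sample counts, Holm–Šidák corrected;
Welch is used because there is no reason to assume equal variances
between diet groups.

## De-novo extraction and rank selection

The factorization model is non-negative matrix factorization under the
generalized Kullback–Leibler divergence — up to a constant, the negative
Poisson log-likelihood of the counts, the natural objective for mutation
catalogs. Multiplicative updates run until the relative objective change
falls below `tol` (default 1e-8) or `max_iter` (default 10,000); the
signature matrix is kept column-stochastic throughout by pushing scale
into the exposures. The updates never increase the objective, which the
test suite asserts per iteration.

The number of signatures is chosen by a stability/accuracy tradeoff.
For every candidate rank k:

1. the original catalog is factorized from `n_inits` random starts
   (best objective kept) — the matching reference;
2. `n_resamples` Poisson-perturbed copies of the catalog (every entry
   replaced by a Poisson draw at that mean, matching the count noise
   model) are each factorized the same way;
3. each perturbed solution's columns are greedily matched one-to-one to
   the reference columns by descending cosine, pooling all columns into
   k clusters. The reference is the original-matrix solution because
   objectives of factorizations of *different* perturbed matrices are
   not comparable;
4. average stability (AS) is the mean silhouette width of the pooled
   columns under cosine distance (defined as 1 at k = 1, where a
   silhouette does not exist — required so that a single-signature
   solution is expressible);
5. consensus signatures are normalized cluster means, and accuracy is
   the mean sample cosine distance (MSCD) between original columns and
   their non-negative least-squares reconstruction from the consensus.

The chosen rank is the stable rank (AS ≥ `stability_min`, default 0.8)
with the smallest MSCD, ties to the smaller rank; if no rank is stable,
the smallest evaluated rank. Defaults: `k_range` 1–4, `n_resamples` 30,
`n_inits` 10. The recovery studies in the test suite and acceptance
script run the same algorithm at reduced cost (`n_resamples` 8,
`n_inits` 3, `tol` 1e-6, `max_iter` 2000) — problem sizes chosen so the
whole study stays desk-scale while leaving the selection behavior
unchanged on the study conditions.

**Identifiability caveat.** Rank recovery requires the exposure matrix
to vary across samples. A cohort whose clones all share one mixture (the
homogeneous regime) is numerically close to rank one no matter how many
signatures generated it: factorizations at higher ranks are then
non-unique, their stability collapses, and the scan correctly prefers a
single consensus signature. The recovery study therefore simulates
severalfold between-clone activity variation (gamma shape 3, CV ≈ 0.6,
typical of real cohorts), while the homogeneous regime (dispersion 0) is
used to demonstrate the single-signature selection on a cohort without
differential processes. Both regimes are exercised in the tests.

**Decomposition.** A de-novo signature is decomposed onto a reference
catalog by forward selection: starting from the empty set, the reference
signature whose inclusion (non-negative least-squares refit) raises the
reconstruction cosine by at least `min_gain` (default 0.01) is added,
until no candidate clears the bar. Weights are reported as percent of
the NNLS coefficients (summing to 100); if even the first candidate
fails the gain threshold, the single best signature is returned with a
low-confidence flag.

## Refitting

**Plain refit** solves per-sample non-negative least squares against a
fixed signature set; since signature columns sum to one, exposures are
mutation counts. Near-duplicate reference pairs (cosine > 0.95) trigger
a collinearity warning.

**Best-subset (strict) refit** repeatedly removes the lowest-contributing
signature and re-fits, accepting the removal while the sample's
reconstruction cosine drops by at most `max_delta` (default 0.004, the
strict-refitting convention); the first rejected removal stops the
process. Greedy backward elimination is the default because it is
tractable for reference sets of 60+ signatures and coincides with the
exhaustive search on well-separated signatures; an exhaustive mode
(subset minimal in size among those within `max_delta` of the full-set
cosine, ties by cosine) is provided for ≤ 12 signatures and used as a
cross-check oracle in the tests. Note the two criteria can differ on
poorly explained samples: greedy bounds each *step*, the exhaustive
bound is *total* — on recoverable data they agree.

**Bootstrapped refit** redraws each sample's column as a multinomial
(observed total, normalized observed profile), re-runs the strict refit
per replicate (default 1000), and reports per (sample, signature) the
fraction of replicates with nonzero exposure and the mean contribution
where found.

**Presence test.** For a target signature, two Poisson maximum-likelihood
refits are computed — exposures fitted by the same multiplicative
updates that minimize KL divergence — once with and once without the
target. Because a zero exposure is absorbing under multiplicative
updates, the with-model is fitted both from a uniform start and from the
without-model's optimum seeded with a small positive target exposure,
keeping the better; this guarantees the nesting inequality. The
statistic is the log-likelihood ratio, and since the null (exposure 0)
lies on the boundary of the parameter space, the p-value is the
boundary-corrected 0.5·P(χ²₁ > 2·LLR). A target within cosine 0.999 of
another reference signature is flagged non-identifiable.

## Synthetic data

The generator emulates: a two-group layout (default 5 mice × 4 clones
per group); per-clone expected exposures equal to the group mixture
scaled to the clone's mean burden (defaults ~1200 SNVs and ~170 indels
per clone, i.e. cohort-scale burdens of ~48,000 SNVs and ~6,700 indels
spread over 40 clones), jittered per signature by a mean-one gamma
multiplier (shape 20 by default, CV ≈ 0.22); Poisson channel counts
around S·e; clonal VAFs as Beta(50, 50) and non-clonal samples as a
mixture with a Beta(12.5, 37.5) subclonal mode near 0.25 carrying 65% of
the mass (an equal-weight mixture would place the sample median exactly
at the 0.4 filter boundary and separate poorly). Reference-like
signature sets are sparse Dirichlet draws redrawn until all pairwise
cosines fall below a separation bound (default 0.3).

The fixture writer additionally materializes channel draws as an on-disk
reference FASTA plus two pseudo-caller VCFs per sample: each mutation is
embedded in a sequence cassette that realizes its channel exactly
(trinucleotide for SBS; homopolymer/repeat/microhomology flanks for
indels, built from T-free units so guard bases cannot extend a run or
shift an alignment), caller B writes indels in a non-parsimonious
anchor-padded representation to force the normalization path, and an
overlap parameter controls the fraction of variants both callers see.
Every simulated artifact returns its generating parameters, so recovery
error is always computable.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: sequencing and alignment error,
coverage variation, caller-specific error modes, germline leakage,
mutational strand asymmetries, regional mutation-rate variation along
the genome, and correlations between signatures' activities. Synthetic
signatures are sparse random profiles, not the real catalog entries;
tests demonstrate algorithmic correctness and statistical calibration,
not biological conclusions.

## Numerical choices and degenerate inputs

- NMF guards all ratios with an epsilon of 1e-12; an all-zero catalog
  column is rejected before factorization; a Poisson resample that zeroes
  a column is nudged by 1e-9.
- Rank-selection ties in MSCD go to the smaller rank; greedy matching
  breaks cosine ties by enumeration order.
- `best_subset_refit` refuses `max_delta` ≥ 1 (it would allow removing
  every signature).
- Zero-mutation samples are an error wherever a profile is required, and
  the offending sample is named.
- All stochastic procedures (simulation, bootstrap, NMF initialization,
  resampling) take explicit seeds and are bit-reproducible under them.

## Known limitations

- Reference signatures are used as given; no renormalization to the
  target genome's trinucleotide frequencies is applied.
- The presence test's independent-Poisson channel model ignores
  overdispersion; its type-I error is calibrated on the synthetic
  conditions (measured ≤ 0.035 at nominal 0.05, i.e. conservative due to
  the boundary correction).
- Greedy backward elimination is not guaranteed optimal outside the
  well-separated regime (see above).
- DBS events are counted, not signature-analyzed.
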