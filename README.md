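# sigcrypt

Somatic mutational-signature analysis for clonal organoid cohorts —
from variant call sets to mutation catalogs, signature extraction,
refitting, and presence testing, with a synthetic-cohort simulator that
carries ground truth for every stage.

## What it is for

Whole-genome sequencing of clonally expanded organoid lines turns each
line into a faithful record of the mutational processes active in its
founder stem cell. Given per-clone somatic variant sets from two callers
and a two-group cohort design (e.g. high-fat diet vs. standard diet,
5 mice × 4 clones per group), `sigcrypt` answers the question: *do the
groups differ in their mutational spectra or signature activities?*

The pipeline:

1. **variants** — consensus intersection of two callers' PASS sets on
   normalized `(chrom, pos, ref, alt)` keys; VAF clonality QC (median
   VAF ∈ [0.4, 0.6]); classification of SNVs into the 96
   pyrimidine-centered trinucleotide channels (SBS-96, collapsible to 7
   categories with C>T split by CpG) and of indels into the curated 83
   channels (ID-83: homopolymer, repeat, and microhomology context;
   collapsible to ID-16); catalog construction `M` (channels × samples).
2. **profiles** — normalized group profiles with per-channel sd;
   pairwise cosine similarity; multinomial bootstrap of the mutational
   matrix (default 10,000 replicates) with cross-group cosine; Welch
   t-tests per channel with Holm–Šidák correction.
3. **extraction** — de-novo signature extraction by NMF under the
   generalized Kullback–Leibler divergence `M ≈ S·E` (the Poisson count
   likelihood), with automated rank selection trading off the average
   stability (AS, silhouette of matched factorization columns across
   Poisson-perturbed resamples) against the mean sample cosine distance
   (MSCD) of the reconstruction; decomposition of de-novo signatures
   onto a reference catalog by forward selection.
4. **refitting** — non-negative least-squares exposures; best-subset
   ("strict") refitting by backward elimination under a cosine
   degradation threshold (default 0.004); bootstrapped refitting with
   per-signature found-fractions; and a signature presence test: a
   likelihood-ratio test between Poisson maximum-likelihood refits with
   and without the target signature, with a boundary-corrected
   `0.5·P(χ²₁ > 2·LLR)` p-value.
5. **synthetic** — cohort, catalog, VAF, and on-disk VCF/FASTA fixture
   generation with known signatures, exposures, and channel draws.

Catalogs, signature sets, and exposures are exchanged as tab-separated
matrices (first column channel labels, header of sample/signature IDs).

## Worked example

Simulate a null cohort (both diet groups share four equally active
signatures drawn from an eight-signature reference set), compare the
groups, and refit:

```python
import sigcrypt as sc

refs = sc.make_reference_signatures("SBS96", 8, separation=0.4, seed=1)
active = refs.signature_ids[:4]
mixture = sc.GeneratingMixture.null(refs.subset(active))
catalog, truth = sc.simulate_cohort(sc.CohortDesign(seed=1), mixture)

comp = sc.bootstrap_group_profile(catalog, sc.BootstrapConfig(n_replicates=10_000, seed=2))
print(f"cross-group bootstrap cosine: {comp.cross_group_cosine:.4f}")

res = sc.SignatureRefit(catalog, refs).fit(method="strict")
print(res.summary())
```

Output:

```
cross-group bootstrap cosine: 0.9950
Signature refit (strict, max_delta=0.004)
  catalog: SBS96, 40 samples
  reference set: 8 signatures, 4 active after refit
  reconstruction cosine: min 0.9811, mean 0.9896

  mean exposure (mutations) of active signatures:
    SYNSBS961: 309.4
    SYNSBS962: 307.0
    SYNSBS963: 305.4
    SYNSBS964: 287.2
```

Reading the numbers: the bootstrap-averaged profiles of the two groups
are nearly identical (cosine 0.995 — no qualitative difference in
mutational spectra), the strict refit retains exactly the four
generating signatures out of eight candidates, and their mean per-clone
exposures (~300 mutations each of a ~1200-mutation clone) recover the
equal-activity design. `SignatureExtraction(catalog).fit(seed=0)` runs
the de-novo rank scan the same way and returns the per-rank AS/MSCD
table, the consensus signatures at the chosen rank, and their
decomposition onto a reference set.

A thin CLI wraps the same library:

```bash
sigcrypt simulate --schema SBS96 --n-signatures 4 --seed 1 --out cohort/
sigcrypt extract  --catalog cohort/catalog.tsv --kmin 1 --kmax 4 --seed 0 \
                  --reference cohort/generating_signatures.tsv
sigcrypt refit    --catalog cohort/catalog.tsv --reference cohort/generating_signatures.tsv
sigcrypt compare  --catalog cohort/catalog.tsv --groups cohort/groups.tsv --bootstrap 10000 --seed 0
```

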