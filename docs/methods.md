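# Methods

This note documents the statistical procedures implemented in flavopipe,
the defaults they ship with, what the synthetic-data generators do and do
not emulate, and the design choices made where the procedure left room.

## Study design assumed

A paired, two-arm intervention cohort: each subject provides a sample at
week 0 and week 24 and belongs to exactly one arm (cranberry or placebo).
Samples collected at UTI events are excluded from every analysis. All
pairing logic is driven by the sample metadata (sample, subject, arm,
visit); a subject missing either timepoint is excluded rather than
imputed.

## Community profiling

**Rarefaction.** Counts are subsampled per sample to a fixed depth without
replacement (multivariate hypergeometric draw), with an explicit seed;
samples below the depth are dropped, never padded. Default depth 5000
reads — chosen in the original analysis as the knee retaining ~80% of
samples at ~75% of maximal Chao1; `rarefaction_depth_scan` reproduces that
trade-off table for depths 1000–20000. After rarefaction, OTUs with fewer
than 10 total reads are removed (`min_total_reads_per_otu = 10`), since
ultra-rare OTUs carry no power in a 34-subject cohort.

**Alpha diversity.** Chao1 in the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))` (the classic form is available via
`bias_corrected=False`); Shannon entropy in bits (log base 2). Both follow
the conventions of the QIIME lineage of tools the study used.

**Beta diversity and ordination.** Bray-Curtis dissimilarity
`d = 1 − 2Σmin(x,y)/Σ(x+y)`. PCoA is classical metric scaling: the squared
distance matrix is Gower-centered and eigendecomposed; axes are ordered by
eigenvalue. Negative eigenvalues (Bray-Curtis is non-Euclidean) are
reported but excluded from the explained-variance denominator; no
Lingoes/Cailliez correction is applied.

**Cohort-structure comparisons.** Same-subject vs different-subject
distances, and per-subject week0→week24 shifts between arms, are compared
with the two-sided Wilcoxon rank-sum test. All cross-subject pairs enter
the between-subject set even though pairs sharing a sample are correlated;
this is the naive convention of such comparisons and makes the test
somewhat conservative under the null (verified by simulation in the test
suite). The arm-shift comparison requires at least two paired subjects per
arm; a 1-vs-1 comparison is refused rather than reported as a vacuous
p = 1.

## Paired differential abundance

For each feature and each paired subject, the fold-change is
`log2((reads_wk24 + c) / (reads_wk0 + c))` with pseudocount c = 1 read for
OTU counts; a subject with zero reads at both visits contributes exactly
0. The two arms' fold-change vectors are compared with a two-sided
Wilcoxon rank-sum test per feature, and p-values are Benjamini-Hochberg
corrected across all tested features. Significance is called at adjusted
p < 0.05 (`alpha`).

Filters applied first: subjects must have both visits; OTUs must be
present (≥1 read) in at least 25% of the retained samples, pooled over
arms and timepoints (`prevalence_fraction = 0.25`). For functional tables
(pathways, gene families) the prevalence filter is instead per arm at the
subject level — a feature must be present in ≥50% of each arm's paired
subjects (`feature_prevalence_fraction = 0.5`) — and the pseudocounts are
0.001 (pathways) and 0.0001 (gene families) on relative abundances. The
asymmetry between the two prevalence conventions is deliberate: each
mirrors the corresponding upstream procedure as described.

**Wilcoxon implementation.** When the smaller group has ≤8 observations
and the pooled values are tie-free, the exact null distribution is used;
otherwise the normal approximation with midranks, tie-corrected variance
and continuity correction. A forced-exact mode enumerates labelings of the
midranks when ties are present (feasible only for small groups). The test
suite verifies both paths against an independent full-enumeration oracle.

**Orthogonal validation.** The pairwise-differences variant transforms the
rarefied table to relative frequencies, takes per-subject differences
(week24 − week0) per feature, and runs the same arm comparison and BH
correction. On synthetic data its per-arm median signs agree with the
fold-change medians for ≥95% of informative features.

**Exact-sequence abundance.** A shotgun read counts toward a 16S query if
its full sequence occurs verbatim (no mismatches) as a substring of the
query or its reverse complement; counts are normalized by the sample's
total reads. Searching both strands is a package choice; requiring exact
identity is inherent to the method.

## Oligotyping

Reads pre-aligned to the OTU consensus are profiled column by column with
Shannon entropy in bits over the 5-symbol alphabet {A, C, G, T, gap};
ambiguity codes are excluded from counts. Sites with entropy ≥ 0.2 bits
(the tool authors' recommended cutoff) are candidates, ranked by entropy
with ties broken by position; by default only the top site is used,
mirroring the single-site usage in the motivating analysis. Oligotypes are
the concatenated alleles at the selected 1-based positions. At a per-base
error rate of 0.5%, a monomorphic column's entropy is ~0.05 bits, far
below the cutoff, which is why the threshold separates real polymorphism
from sequencing noise.

## Metagenome identity (ANI)

Per-position calls carry the reference and called allele, the summed base
quality, and the high-quality depth (the caller's DP4 sum). Filtering is
two-stage: (1) drop calls with quality sum < 50; (2) compute the mean and
population SD of depth over the survivors and drop calls with depth
strictly above mean + 3·SD — such positions typically collect
cross-mapping reads from homologous sequence in more abundant community
members, which would deflate the ANI. The filter is idempotent in practice
on realistic depth distributions (asserted on generated data rather than
proved; a second pass recomputes the cutoff over survivors).

ANI = 1 − (variant calls / passing calls); although the underlying
procedure tallies the variant fraction, the identity is what is reported
(99.3% rather than 0.7%). Breadth is the fraction of reference positions
with a passing call; samples with breadth < 0.5 are excluded from cohort
ANI summaries. The species boundary is 95% ANI, inclusive. Multi-allelic
subtleties are ignored: any non-reference call counts as one variant.

Between assembled genomes, ANI is the unweighted mean over shared
orthogroups of per-orthogroup identity (identical columns / columns where
neither sequence is gapped); per-position pooling across orthogroups is
available behind a flag. 16S copy number is estimated as locus mean depth
divided by genome-wide median depth.

## Characteristic genes

Samples are classed by the focal OTU's 16S relative abundance: positive at
≥0.9%, negative strictly below 0.01%; the band between (including exactly
0.01%) is unclassified and excluded. A gene is present in a sample when
≥75% of its length has at least one aligned read. Categories, assigned as
the highest rule met with n_pos/n_neg the class sizes:

1. enriched in positive samples — per-gene Fisher exact test on
   covered/uncovered × positive/negative, BH-corrected p < 0.05, and the
   positive coverage fraction exceeding the negative (the two-sided p is
   direction-blind on its own; requiring the enrichment direction is a
   package choice);
2. highly enriched — covered in ≥ n_pos − 1 positive and ≤ 1 negative
   samples (parameterized so the rule generalizes beyond the original
   19/44 split, where it reads "≥18 and ≤1");
3. category 2 and unique to the reference genome's orthogroups;
4. OTU-specific — covered in all positive and 0 negative samples;
5. category 4 and unique to the reference.

When gene records carry no orthogroup-uniqueness flag, categories 3 and 5
are reported as unavailable rather than silently zero.

Transporter-like genes are flagged when any of the keywords *transport,
symport, permease, efflux, pump, antiport* occurs case-insensitively as a
substring of the product, COG, GO or Pfam text (so "antiport" matches
"antiporter"; a word-boundary mode exists behind a flag). Enrichment of
flagged genes in the characteristic set is a Fisher exact test whose
default background excludes the characteristic set from the comparison
cells (table [[30, 87], [362, 3527]] at the original scale); an inclusive
background is available via flag. Two-sided Fisher p-values use the
minimum-likelihood convention; the odds ratio reported is the sample
cross-product estimate.

## Synthetic-data generators

`generate_cohort` draws a shared log-normal baseline composition
(σ = 2.0, putting the most abundant taxon near 20–40% relative abundance,
as in typical gut profiles), perturbs it per subject
(`subject_effect_scale`, default 1.0 natural-log units — subjects are far
more similar to themselves than to each other) and per visit
(`time_effect_scale`, default 0.15 — communities are stable over 24 weeks
relative to inter-subject spread), then draws week-0 and week-24
multinomial samples at uniform depths (5000–150000 reads). One planted
taxon sits at ~1% baseline relative abundance and is carried by ~70% of
subjects (non-carriers contribute exact-zero counts and hence fold-change
0). Its week-24 expected abundance is multiplied by 2^1.5 in the planted
arm and 2^−0.75 in the other arm by default: the motivating differential
was driven by an increase in one arm *and* a decrease in the other, and a
single-arm effect cannot clear BH correction across ~200 features once
both arms' non-carriers tie at zero, no matter how small the noise.
Setting the planted effect to 0 disables both multipliers, leaving the
arms exchangeable for null calibration. Effects multiply expected counts
before multinomial sampling, so compositional side-effects on other taxa
are present, as in real data.

`generate_position_calls` plants variant positions as independent
Bernoulli(divergence) draws (default 0.7%, i.e. true ANI 99.3%), Poisson
depths (default 20×), quality sums scaling with depth (~30 per read, so
depth-1 positions fail the quality-sum filter naturally), and consensus
miscalls only when erroneous reads outnumber correct ones — vanishingly
rare at 20×, which is what makes ±0.1% ANI recovery achievable. Optional
contaminant positions receive 10× the mean depth and a variant allele to
exercise the 3-SD depth filter.

`generate_aligned_reads` draws reads from per-site allele mixtures over a
random consensus with independent per-base errors. `generate_gene_coverage`
covers planted characteristic genes at ≥0.8 in all positive and <0.5 in
all negative samples; background genes are class-independent (70% "core"
genes covered everywhere, the rest uniform), so a planted set is exactly
recoverable and false category-4/5 calls are essentially impossible by
construction.

**What the generators do not emulate:** taxonomic correlation structure
(taxa are independent given the subject), overdispersion beyond the
log-normal-multinomial (a Dirichlet-multinomial alternative would be the
natural extension), read-level errors in the cohort tables, chimeras,
primer bias, within-sample strain mixtures in the call generator, and any
biology of the intervention itself. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the assumed
sampling model, not robustness to every artifact of real amplicon or
shotgun data.

## Numerical choices and degenerate inputs

* Ties in medians use the standard even-n midpoint; rank ties use
  midranks everywhere.
* BH adjustment is the step-up formula with monotonicity enforcement and
  clipping at 1; verified against an independent oracle.
* All-zero count vectors, empty groups, all-zero contingency tables,
  out-of-range abundances and length-mismatched alignments raise
  `ValueError` rather than returning sentinel values; error messages name
  the offending sample where applicable.
* PCoA eigenvalues below a relative tolerance of 1e-12 are treated as
  zero; a collinear configuration yields one positive axis explaining
  100%.
* Every output file carries a header with package version, seed and a
  config hash, and pipelines are deterministic given (inputs, seed).

## Problem sizes used in validation

Recovery checks run at the design scales of the motivating study:
100-seed loops for planted-taxon recovery (18 v 16 subjects, 219 taxa),
ANI recovery (100 kb genome, 20× depth), and characteristic-gene recovery
(200 genes, 19 v 44 samples); 5000 reads for oligotype frequencies; a
null cohort of ~200 features for type-I calibration. These sizes
keep the full validation under a few minutes on one CPU while matching
the original data's dimensions where they matter.

## Known limitations

* The rank-sum and Fisher tests are the classical univariate procedures;
  no compositional (e.g. CLR) or mixed-model alternatives are provided.
* The within/between-subject comparison inherits the non-independence of
  distance pairs (see above); its p-values are conservative.
* The ANI estimator treats calls as independent across positions and
  ignores mapping bias; it is a descriptive identity, not a phylogenetic
  distance.
* Characteristic-gene categories depend on hard thresholds (0.9%/0.01%
  classification, 75% coverage); sensitivity to these is not explored
  automatically.
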