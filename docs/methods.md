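# Methods

This note documents the models, rules and numerical choices behind
`mipmosaic`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Read model and preprocessing

A MIP (molecular inversion probe) captures a target interval between two
hybridization arms; the sequenced amplicon spans arms + target. Because arm
bases are copied from the probe rather than the genome, an allele observed
inside a read's arm span is unreliable. The package therefore tracks, per
site and allele, both the total deduplicated support and the *off-arm*
support, and the somatic filter counts only the latter. The VAF
denominator, by contrast, uses **all** deduplicated reads at the site —
the arm exclusion applies only to the supporting-read filter, which is the
closest literal reading of the filtering rules this pipeline reproduces.
Whether arm masking should also shrink the depth denominator is genuinely
ambiguous; we keep arm reads in depth and document it here.

Duplicates are recognized by identical mapping coordinates plus the shared
dual UMI. The consensus base per position is the majority over duplicates;
ties go to the base with the larger summed quality, then lexicographically
(the underlying study's tooling does not specify a tie-break; this one is
deterministic and order-independent). Consensus quality is the maximum over
reads carrying the chosen base. Deduplication is idempotent.

Coordinates are 1-based inclusive throughout the package; BED I/O converts
to 0-based half-open at the boundary.

## Germline filter and selection

Candidates come from a binomial genotyper (emission at VAF ≥ 0.2 with a
log-likelihood-ratio quality against a 0.1% error model, scaled to
resemble Phred-scaled caller qualities); externally produced VCFs can be
substituted. The filter is a pure conjunction: (1) ≥ 10 supporting reads,
(2) ≥ 20 depth, (3) VAF ≥ 0.3, (4) QUAL ≥ 50, each evaluated in every
region where the site is adequately covered, and (5) the variant must be
detected in all such regions — a region with fewer than 10 reads at the
site failed to cover it and is exempt. We require rules 1–4 per covered
region (not merely detection), the stricter of the two available readings.

Selection to the deleteriousness step requires: maximum population AF
across ancestry groups < 0.001 (rejection if *any* group reaches 0.1%, the
conservative reading), carrier exclusivity to disease or control
individuals, a protein-altering consequence (missense / nonsense /
frameshift / splicing, with a splice delta score > 0.5 also promoting),
and membership of the configured disease gene panel. Cross-disease
variants are retained and labeled rather than dropped.

## Somatic consensus and filter cascade

Three caller profiles stand in for the external low-VAF callers so the
pipeline runs end-to-end without them (their real VCFs are equally
accepted): each emits variants whose binomial LLR against its error prior
exceeds a per-profile threshold; profile R is tuned lowest-VAF but calls
no indels. Consensus: SNVs are retained when called by R plus at least one
other caller — M-P-only pairs are excluded as a high-false-positive
combination — and indels require both M and P; single-caller candidates
are always dropped. Evidence and VAF are always recomputed from the
deduplicated reads, never taken from a caller.

The eight-rule cascade (all thresholds config, defaults as listed):
depth ≥ 50; off-arm variant support ≥ 15; mean variant base quality
strictly > 30; ≥ 2 distinct probes among the off-arm supporting reads
(we apply the arm exclusion to probe counting too, for consistency);
0.001 ≤ VAF ≤ 0.4 (a 0.35 ceiling is available as a config override,
reflecting an alternative statement of the same pipeline); at most 3
candidates of the same sample within any 20-bp window, with **all**
members of an offending window removed (the conservative reading of
"filtered out"); population AF < 0.1% in every ancestry group; and
recurrence in at most 2 individuals cohort-wide, controls included.

The contamination screen is a stand-in heuristic (the original procedure
is described only in supplementary material not reproduced here): a sample
is flagged when ≥ K (default 5) of its low-VAF candidates coincide with
germline variants private to one other sequenced individual, and the
matching candidates are removed.

## Deleteriousness and individual labeling

Precedence: a clinical benign/likely-benign classification overrides
everything; nonsense, frameshift and canonical-splice variants are assumed
damaging; a splice delta score > 0.5 marks a variant splice-altering;
missense variants need fully damaging verdicts from ≥ 3 of the 10
configured predictors, with possibly/likely-damaging verdicts never
counted. The damaging category per predictor is: deleterious for SIFT,
LRT, FATHMM, PROVEAN, MetaSVM, MetaLR; probably-damaging for PolyPhen2;
disease-causing for MutationTaster. MutationAssessor and FATHMM-MKL have
no published category in this context; we map them to their conventional
top categories ("high", "damaging") and expose the whole map in config.

A deleterious variant in a dominant gene makes the individual
germline-positive. Recessive genes require two hits: a lone deleterious
heterozygous variant leaves the individual germline-free (but is
recorded), two germline hits in the same gene make it germline-positive,
and a germline + somatic deleterious pair in one recessive gene produces a
two-hit record — a cellular, not constitutional, second hit.

## Spike-in benchmarking

Mixing a fraction *f* of a spiked genome makes its heterozygous SNPs
appear at expected VAF *f*/2, so the generator sets the mixing fraction to
twice the tier label and only heterozygous sites are scored. Sites covered
by a single amplicon or at depth < 100 are excluded as panel-design
failures. False positives are calls outside the truth set, excepting the
background genome's own germline SNPs and excluded sites; with zero calls,
precision is reported as 1.0 with an explicit undefined flag. The FPR
denominator is not defined in the source material; we report FP per
evaluable megabase alongside the raw count. Whether probe *copies* count
as separate amplicons is unstated; we count distinct probes.

Benchmark truth sites are placed ≥ 21 bp apart. Biological SNPs on a
1.4-Mb panel are effectively never adjacent, and without spacing the
random placement could manufacture candidate clusters that trip the 20-bp
window rule — an artifact of the toy geometry, not of the pipeline.

## Burden statistics

For carrier 2×2 tables the package reports the **conditional
maximum-likelihood odds ratio** — the estimator of the exact test,
maximizing the noncentral hypergeometric likelihood given all margins —
with the exact test-inversion CI and Fisher's two-sided p. The sample
(cross-product) OR would differ in the third digit on the tables this
pipeline reports; the exact estimator is the one consistent with the
printed test results. Degenerate margins return an undefined-OR flag.

Individual-level enrichment uses a Gaussian linear mixed model on
per-individual variant counts:
`count ~ diagnosis + mean_depth + sex + PMI + n_samples`, random intercept
per sequencing batch (continuous covariates are centered and scaled for
numerical stability). Gaussian-on-counts follows the source analysis; a
Poisson alternative would be natural but is not what the reported effects
estimate. With a single batch the model degrades to OLS with a warning.
p-values are **unadjusted** by design, mirroring the reported analysis;
apply your own multiplicity control when scanning many strata. The batch
(rather than donor) random effect is a choice: donors are rows, so a donor
effect is not identifiable here.

## Focality and concordance

A variant's regional map records VAF and depth in every assayed region;
"detected" means ≥ 3 off-arm supporting reads (the validation assays'
criterion is unpublished; the threshold is config). Focal = detected in
exactly one region. Note that the focal fraction of *called* variants sits
below the implanted fraction whenever per-region sensitivity is below 1: a
focal variant gets exactly one chance to clear the 15-read support rule
while a shared variant gets one per region, so detection enriches for
shared variants. The same ascertainment bias applies to any real cohort. Concordance between discovery and validation VAFs is
ordinary least squares with a 95% CI band and a t-test of the slope
against the identity line; a numerically perfect fit degenerates to exact
slope comparison.

## Repeat expansions

Repeat counts are `floor(inter-anchor span / 6)` after locating both flank
anchors by mismatch-tolerant infix alignment (edlib, ≤ 10% mismatches), so
substitution errors inside the repeat do not truncate counts. Reads
missing an anchor are flagged unanchored and never counted; an anchor
found at two disjoint optimal locations flags the read ambiguous. Allele
classes: < 20 normal, 20–30 intermediate, > 30 pathogenic.

Clustering splits sorted counts where adjacent values differ by more than
3. The threshold must resolve wild-type alleles a few repeats apart (4 vs
9, or 5 vs 9) while absorbing count jitter, which values ≥ 5 cannot do.
Clusters lying entirely in the pathogenic range are merged into a single
expanded allele call and flagged mosaic when their spread exceeds 50: a
spectrum of expanded lengths in one sample is somatic instability of one
allele, not many inherited alleles. The enrichment chemistry biases toward
shorter fragments, so no VAF is estimated for expansions — only presence,
size range and phase. Phasing groups reads by their exact alleles at the
heterozygous flank SNPs and reports, per expanded cluster, which wild-type
allele's haplotype it shares. One documented discrepancy in the source
material (wild-type alleles "4 and 5" in text vs "4 and 9" in the figure)
is resolved in fixtures in favor of the figure; both work.

## Synthetic-data generator

The generator's defaults are the study conditions: target VAF tiers 0.5%,
1%, 2.5%, 5%, 10%; ~2,000× unique depth for benchmarking; germline
implants at VAF 0.5/1.0 in every region; somatic implants focal with
probability 0.78 and otherwise shared by ≥ 2 regions; 11 default CNS
regions (prefrontal, primary motor, premotor, temporal, occipital,
anterior cingulate cortices, hippocampus, cerebellum, cervical / thoracic
/ lumbar spinal cord); GC-based probe copy rebalancing (60–70% → 2,
70–80% → 5, 80–90% → 8, > 90% → 10 copies). The dual UMI is 5+5 nt by
default (the probe backbone's description and its printed blocking-oligo
sequence disagree on 4 vs 5 nt; the width is config).

Error model: independent per-base substitutions at a uniform rate with a
uniform alternative base. Correct bases draw qualities ~N(37, 2) (clipped
to 25–41, typical of modern short-read chemistry); erroneous bases draw
low qualities (uniform 10–25). The marginal miscall behaviour matches the
configured rate while keeping reported qualities informative, so the
base-quality filter is genuinely exercised — a model in which all
qualities equal the Phred of the error rate would make the strict ">Q30"
rule vacuous or impossible rather than discriminating.

What the generator does **not** emulate: polymerase/ligase chemistry,
GC-dependent capture efficiency beyond the copy rule, indel sequencing
errors (indels are implanted, not error-generated; the read-level
simulator implants SNVs only, and indel candidates enter through caller
sets and site-level evidence), mapping artifacts, strand bias, and
molecule-level haplotype linkage in the cohort simulator (each variant is
drawn independently per molecule). Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics under a clean
substitution-error model, not robustness to alignment or chemistry
artifacts in real data.

## Problem sizes

Tests and the acceptance script run the study's *per-site* conditions
(≈ 2,000× deduplicated depth, 0.1% error, the published VAF tiers) on a
small panel — a few hundred-bp contigs tiled by overlapping probes — and
small cohorts (a dozen individuals, 2–3 regions), which preserves every
per-site statistic while keeping simulations desk-sized. Mixed-model
calibration uses 200 null and 100 alternative replicates at 200 cases /
100 controls. Cohort-scale quantities that depend on hundreds of
controlled-access genomes (the real burden effect sizes) are out of scope;
the printed 2×2 tables and proportions are recomputed from their published
counts instead.
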