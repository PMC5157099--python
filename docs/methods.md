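# Methods

## Scope and data flow

`allelecn` estimates tumor purity, ploidy and allele-specific integer copy
number, and classifies SNVs by somatic status and clonality, from per-target
coverage of hybrid-capture sequencing plus a variant VCF. It starts from
coverage tables (GATK DepthOfCoverage dialect or plain TSV); BAM processing
and variant calling are upstream concerns. The pipeline is

GC-normalize → select best normal from pool → log-ratios → weighted CBS →
SNP-based breakpoint refinement → 2D grid search → heated-Gibbs copy
assignment per optimum → SNV state posteriors per optimum → ranking,
bootstrap, flags → outputs.

An existing segmentation (SEG file) can replace the coverage stages, in
which case exon-level data is emulated on the supplied interval grid.

## Coverage normalization

**GC correction.** Coverage is divided by the median of its equal-frequency
GC bin (bins of ≥ 50 targets, at most 40 bins) and rescaled to preserve the
sample mean. A binned-median estimator was chosen over a loess fit because
it is *exactly* idempotent — the median of a rescaled bin is the rescaled
median, so re-normalizing already-normalized coverage is a no-op — whereas
any local-regression trend refitted on noisy flat data retains sub-percent
wiggle and fails idempotence at numerical tolerance. Targets with zero
coverage pass through as zero.

**Pool of normals.** Samples are scaled to a common mean (making everything
downstream invariant to per-sample sequencing depth), compared to the
per-target pool median, and summarized by the per-target SD of those
coverage ratios. Segmentation weights are proportional to 1/SD, scaled to
mean 1, clipped at 3 (so near-zero-variance targets cannot dominate the
segmentation statistic), and renormalized to mean 1 over retained targets;
an all-identical pool degenerates to unit weights. Targets whose pool median
is below 20% of their chromosome's median are masked (strict `<`, with a
1e-12 relative guard against float round-off at the boundary). For
best-normal selection, every sample is rescaled so its maximum coverage
equals 100 (rescaling both directions, not only capping, which buys exact
scale invariance), a 3-component PCA is fitted across normals
(target-centered, no variance scaling), and the tumor's nearest normals by
Euclidean distance in PC space are chosen; multiple normals are averaged
with weights 1/distance.

**Log-ratios.** r_t = log2((tumor_t/mean tumor)/(ref_t/mean ref)) on
retained targets; mean-centering (not median) is used, with residual
mis-centering absorbed by the calibration shift during fitting. Sex is
called from relative chrX/chrY coverage (male: chrY > 25% and chrX < 75% of
the autosomal mean; female: chrY < 5% and chrX ≥ 75%; otherwise unknown,
treated as female). Males lose chrX and chrY from the model; chrY is always
excluded.

## Segmentation

The weighted CBS maximizes over all circular arcs the statistic
(m₁ − m₂)/√(1/W₁ + 1/W₂) on weight-sums W, with significance from
permutations of (value, weight) pairs. P-values use the add-one estimator
with sequential early stopping in both directions: clearly insignificant
splits stop after a few hundred permutations; a split with zero exceedances
is accepted once enough draws have resolved the alpha boundary. The
pipeline's default CBS alpha is 0.01 so that the SNP-based pruning step has
borderline breakpoints (p > 0.001) to act on; the `segment_cbs` function
default remains 0.001 for standalone use.

σ_ri is the weighted per-target SD of a segment's log-ratios (floored at
1e-4); the segment likelihood multiplies by the target count, approximating
a product of per-target likelihoods. `Segment.se` exposes the standard error
of the mean where a mean-scale quantity is needed (Ward cut height).

Heterozygous SNP candidates are dbSNP members with tumor fraction in
[0.1, 0.9] within a target or its 50 bp flank; fractions are mirrored
(min(f, 1−f)). Pruning removes breakpoints with CBS p > 0.001 whose flanks'
mirrored fractions do not differ (Welch t-test p > 0.2, or fewer than 3 SNPs
on either side). Copy-neutral LOH splitting scans candidate SNP cut points
(≥ 10 SNPs per side), takes the pooled-SD-minimizing cut, and accepts at
Welch p ≤ 0.005, recursing; children keep the parent's mean log-ratio. Ward
clustering on (mean log-ratio, mean mirrored fraction; 0.5 when SNP-free)
then re-centers segments within clusters cut at 0.5 × the mean standard
error. The segmentation function is a plug-in point: any callable with the
same signature can replace CBS (joint coverage+allelic-fraction segmenters
are deliberately out of scope).

## Purity/ploidy fitting

The grid search scores purities 0.15–0.95 (step 0.05) × ploidies 1.0–6.0
(step 0.1) by summing each segment's best copy-state log-likelihood
(log-sum-exp optional), treating ploidy as continuous. Local optima are
points ≥ all 8 neighbors; connected near-equal plateaus (ridges, e.g. a flat
genome) collapse to their highest-purity representative; at most 20
candidates are kept.

Each candidate is refined by a heated Gibbs sampler (temperature
max(1, 4·0.9ᵏ)): per sweep, copy states are sampled from the heated
conditional (states 0–7 plus subclonal), purity is sampled on the 0.15–0.95
step-0.01 grid *restricted to ±0.1 around the candidate* — fine-tuning
within its own basin; with the unrestricted grid every candidate drifts into
the same coverage-only attractor and the solution diversity that the SNV fit
is supposed to arbitrate is lost — and a global log-ratio shift is sampled
on an 11-point grid within ±0.25 × mean σ_ri. Ploidy is recomputed from the
assignment each sweep (subclonal segments are excluded from the ploidy
average — they carry no integer copy number). Convergence: ML assignment
unchanged for 3 sweeps, cap 100. A deterministic coordinate-descent polish
follows from the best visited configuration; for ≤ 6 segments the polish is
an exact vectorized search over all assignments. If the fitted ploidy moved
more than 0.75 from the candidate, one retry widens the shift range to
±1 × mean σ_ri; still-divergent solutions are flagged discarded. Candidates
that converge onto the same (purity, ploidy) are de-duplicated. All
stochastic steps derive from one integer seed; identical seeds give
identical solutions.

The subclonal state's log-density equals a Gaussian 2σ mismatch, so a
segment goes subclonal only when every integer state fits worse than two
(per-target) SDs; ties among equal-likelihood copy states break toward the
lower C.

## SNV model

States enumerate C ∈ 0..7 (weighted by the segment's copy posterior),
K ≤ ⌊C/2⌋ with flat prior 1/(C+1), multiplicity M, and germline indicator g.
Karyotype-allowed multiplicities (M = K, M = C−K, and for somatic also M = 1
and the subclonal M = 1/3 replacing the invalid M = 0) share P_K = 0.999;
remaining integers share 1 − P_K; when no disallowed integer exists the
allowed states carry all mass (1/n_s each), keeping the prior normalized.
Somatic priors: matched calls 0.999/0.0001; unmatched by database evidence —
COSMIC count > 2: 0.95, dbSNP: 0.0005, both: 0.01, neither: 0.5. Depth is
capped at 300 so unmodeled high-coverage biases cannot dominate. Two
contamination states (expected fractions (pC + 2(1−p−c))/(pC + 2(1−p)) and
c/(pC + 2(1−p)), c = 0.01, prior 0.01 each) are admitted for dbSNP variants
only; in high-purity unmatched mode a homozygous-germline state scores
reference reads as independent errors (binomial, ε = 10⁻³/3, prior 0.05 —
the paperless constant here is the state's relative weight, config-exposed).

Filters: homozygous variants removed (matched: normal fraction > 0.9;
unmatched: tumor fraction > 0.95; skipped in high-purity mode), and
mapping-biased SNPs removed when the matched-normal fraction's two-sided
beta tail probability around 0.5 is < 0.05 (pool version: biased in ≥ 50% of
≥ 5 informative normals). Posterior ties break toward germline. The cellular
fraction of a somatic call is h = (f/M)(pC + 2(1−p))/p, reported raw and
clipped at 1 with a flag when the raw value exceeds 1.

The SNV fit likelihood used for ranking is the sum of each variant's best
state log-likelihood. The optional purity post-optimization instead
maximizes the copy-number likelihood plus the SNV *marginal* likelihood
(the state-sum normalizer): the max-state score is a ragged function of
purity — pairs of states can bracket the observed spread at wrong purities —
while the marginal is smooth and peaks near truth. Post-optimization is off
by default and recommended when variant classification is the goal.

Per-segment minor copy number K̂ maximizes the germline-SNP likelihood under
random phasing (a 50/50 mixture of M = K and M = C−K); SNP-free segments
fall back to the balanced ⌊C/2⌋. LOH ⇔ C = 1 or K = 0.

## Ranking and curation

Solutions are ranked by total (copy-number + SNV) log-likelihood. At low
purity a missing chromosome barely unbalances germline fractions, so a
leading near-haploid solution (purity < 0.35, ploidy < 1.5) yields to a
near-diploid alternative within log 2 of its score (config-gated, on by
default). Bootstrap re-ranking resamples variants with replacement
(500 replicates; skipped with a flag below 20 variants); the bootstrap value
is the fraction of replicates ranked first, solutions never in the top 2 are
removed, and a top value < 0.95 flags "ambiguous solutions". Goodness of fit
is 100·max(0, 1 − d/0.2) with d the mean |observed − expected| allelic
fraction of ML states. Curation flags (all thresholds config-exposed, chosen
as package defaults): NOISY_SEGMENTATION (mean σ_ri > 0.25), RARE_PLOIDY
(< 1.5 or > 4.5), EXCESSIVE_LOH (> 90% of genome length), EXCESSIVE_
HOMOZYGOUS_LOSS (C = 0 over > 5%), NON_ABERRANT (< 1% off C=2∧K=1),
POLYGENOMIC (subclonal > 20%), CONTAMINATION (≥ 2% of dbSNP variants in
contamination states), LOW_GOF (< 75%).

## Synthetic data

The generator emulates a benchmarking design of simulated genomes over
exome-like (2,000 targets across 22 autosomes, 100×) and panel-like
(560 gene clusters of 4–7 small targets, ~3,000 targets, 400×) grids.
Segment lengths are log-normal in target counts (σ = 0.6, minimum 5,
respecting chromosome boundaries); copy numbers are drawn Poisson around the
target ploidy (clipped to 0–7) and adjusted by single-segment steps until
the exact length-weighted ploidy is within 0.15 of the target. K is uniform
on 0..⌊C/2⌋. Coverage: per-target capture factors are log-normal with
CV 0.2, shared across tumor and normals; the tumor scales them by
(pC + 2(1−p))/2; every sample adds independent log-normal sampling noise
with CV 0.2·√(100/depth) and its own mild GC-bias slope (SD 0.4 in
log-space per unit GC). Variants: one germline het SNP per 10 targets,
phased to a random parental chromosome; 100 somatic mutations per sample
(clonal M = 1, with a 20% subclonal share at the model's average M = 1/3),
placed only on segments with C ≥ 1; depths Poisson(depth), alt counts
binomial around E[f]; dbSNP membership is true for germline with a 1%
false-negative rate and false for somatic with a 0.1% overlap rate, and 5%
of somatic variants carry a COSMIC count > 2 to exercise the prior table.
Everything is bit-reproducible given (design, seed).

What the generator does *not* emulate — real capture-bias structure
(GC-correlated, batch-specific), mappability artifacts, FFPE damage,
subclonal copy-number architecture, indels, and germline CNVs — bounds what
passing benchmarks show: they validate the estimator against its own
generative assumptions at realistic noise, not against every failure mode of
real libraries.

## Problem sizes and numerical choices

Cohort benchmarks use 20 samples per design at the grids above; a full
tumor-only fit of one exome-like sample takes a few seconds on one CPU
(CBS permutations dominate, bounded by the sequential stopping rule).
Degenerate inputs: constant profiles segment to one segment; an all-zero
coverage vector is an error; empty variant sets switch the pipeline to
copy-number-only mode; zero-coverage reference targets are masked with a
logged count. Breakpoint p-values at the early-accept boundary are
1/(draws+1) ≈ 0.001, intentionally at (not under) the pruning threshold.
Coordinates are 0-based half-open internally; VCF positions are 1-based;
SEG output uses 1-based starts.

## Known limitations

Copy numbers above 7 are folded into the subclonal state; whole-genome
inputs, multi-sample joint fitting, indels and explicit tumor-in-normal
contamination are out of scope. Purity/ploidy aliasing at purity below
~35% can leave the ploidy of the top-ranked solution off by a factor
close to a whole-genome duplication even when the correct solution is among
the candidates — the curation flags and bootstrap values mark these samples
rather than resolving them.
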