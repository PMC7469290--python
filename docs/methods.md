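# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic community generator
does and does not emulate, and the numerical decisions made where the
design was genuinely open.

## Genome comparison and dereplication

Sketches are bottom-s MinHash sets: the s smallest 64-bit hashes over a
genome's canonical k-mers (a k-mer and its reverse complement count once,
as their lexicographic minimum).  Defaults k = 21 and s = 100 000 follow
standard practice for genome-scale Mash comparisons.  Hashing is a
splitmix64-style finalizer over the 2-bit k-mer code, salted with a
configurable seed (default 42), so sketches are bit-reproducible across
platforms.  Jaccard similarity j is estimated by the merged bottom-s
procedure (shared hashes among the s smallest of the union of two
sketches) and converted to the distance d = −(1/k)·ln(2j/(1+j)), capped
at [0, 1]; 1 − d approximates per-base divergence, hence average
nucleotide identity (ANI).

Dereplication is two-stage.  Primary clusters form by average-linkage
hierarchical clustering on sketch distances cut at d = 0.10 (90 % ANI);
within each primary cluster, secondary clusters form on distances from
the *exact* (unsampled) canonical k-mer sets, cut at d = 0.01 (99 % ANI).
Using the exact k-mer distance in place of a whole-genome aligner for the
high-resolution stage is a deliberate substitution: at 99 % ANI on
substitution-dominated genomes the k-mer estimate is tight, and it keeps
the stage dependency-free and exactly testable.  Average linkage was
chosen to match the common dereplication tooling default; the winner per
secondary cluster maximises S = completeness − 5·contamination +
contamination·(strain heterogeneity/100) + 0.5·log₁₀(N50) (weight on log
genome size set to zero), ties broken lexicographically on genome id.
The quality filter keeps genomes with completeness ≥ 80 % and
contamination ≤ 10 %, both boundaries inclusive.

## Abundance estimation

Contig counts are scaled to counts per kb, then full-quantile normalized
across ten equal-frequency GC strata within each sample: each stratum's
empirical distribution is replaced by the average quantile function over
all strata, evaluated at the member's within-stratum rank (ties broken by
contig id for determinism).  This removes any monotone dependence of
coverage on GC while preserving within-stratum ranks, and is exactly the
identity when the strata already share one distribution.  Sample totals
are rescaled to the input totals; the output lives on the
length-corrected (coverage-density) scale, so values are summed per MAG.
One caveat observed on simulated data: because quantile averaging couples
the strata distributions, extremely shifted features (e.g. genomes an
order of magnitude up in one diet) are mildly compressed toward the
sample's bulk — a closure-type artifact shared by quantile methods.

The Hellinger transform is the square root of relative abundance, making
per-sample vectors unit length in the squared sense and Euclidean
distances ecologically meaningful.  Batch removal fits, per feature,
ordinary least squares on intercept + diet + animal + period dummies and
subtracts only the estimated animal/period components, so refitting the
same model on the output returns batch coefficients of zero; aliasing of
a batch column with the kept design is an error.  The order — transform,
then batch-correct — follows the stated analysis order of the workflow
this package reimplements.  Phylum summaries average per-sample phylum
percentages within each diet (percentages first, then means), so diet
columns sum to 100 exactly.

## Community structure and power

PERMANOVA uses the classical one-way partitioning (SS_total =
Σ_{i<j} d²_ij/N; within-group sums weighted by group size), pseudo-F =
(SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total, and
add-one permutation p-values under free relabelling, so the smallest
attainable p at 9999 permutations is 0.0001.  Free permutation (rather
than restriction to animal strata) reflects that animal and period
effects are removed before testing; both PCoA and PERMANOVA were verified
against an independent reference implementation.  PCoA is classical
scaling of the double-centred squared-distance matrix; negative
eigenvalues beyond round-off trigger a warning and are clamped.

The power analysis resamples the transformed, batch-corrected sample
table: within each diet group, samples are drawn *without* replacement up
to the group's size (replacement only for design slots beyond it, since
exact duplicates fabricate within-group similarity that a permutation
test reads as structure), distances are recomputed and PERMANOVA rerun;
rejection fractions are reported per batch of resampled matrices, giving
a power distribution and median.  Two properties matter for
interpretation: (i) within one study the estimate is conditional on that
study's samples — for designs close to the observed group sizes the
resampling degenerates toward a single dataset, so *marginal* null
calibration must be assessed across independent studies; (ii) at a
stringent α a small design can be structurally powerless — a 3:3:3
permutation test rarely reaches p = 0.001 regardless of effect size.

## Differential abundance

Counts per feature are modelled as NB(μ, α), var = μ + α·μ², log link,
with log median-of-ratios size factors as offsets.  The full design
~ period + animal + diet is tested against ~ period + animal by a
likelihood-ratio test at fixed per-feature dispersion, referred to χ²
with df = (diet levels − 1) = 2; log₂ fold changes per contrast (40 vs 80,
60 vs 80 % of maintenance energy) come from the full-model diet
coefficients, with the 80 % diet as reference.

Dispersion estimation is the critical numerical choice at this design
(14 samples, 10 model parameters, 4 residual df).  Per-feature moment or
Pearson estimates are far too noisy to hold fixed — the plain
moment-estimator pipeline showed null type-I error of 0.15–0.20 at
nominal 0.05 — so information is shared across features: gene-wise
Pearson (pseudo-likelihood) estimates with a residual-df correction are
shrunk, on the log scale, toward a mean-dispersion trend built from bin
medians plus the lognormal median-to-mean correction (medians keep a
high-dispersion subpopulation from dragging the trend).  Shrinkage
weights combine the analytic sampling variance of a log dispersion at 4
df (trigamma(df/2)) with a prior variance estimated from the residual
spread, floored at 0.0625.  Features more than 1.5 sampling-SD above the
trend keep their own estimate plus a one-sampling-SD margin: shrinking a
genuinely high dispersion down is the costly (anticonservative)
direction, and the margin compensates the 4-df uncertainty of a
self-estimated value.  With these choices the measured null type-I error
is 0.03–0.06 across true dispersions 0.1–1.0, with the deep tail at its
nominal level.  Non-convergent or all-zero features are flagged, get a
missing p, and are excluded from the Benjamini–Hochberg adjustment.

A practical caution established on simulated data: when a large fraction
of features shifts in one direction, median-of-ratios size factors absorb
part of the shift and bias every fold change (the classical composition
problem).  The bundled benchmark therefore plants its 30 differentially
abundant MAGs as 20 enriched and 10 depleted — the split observed in the
study this package reimplements — among 300 null MAGs.

## Functional attribution

The KO-per-sample matrix is the matrix product of MAG-by-KO annotation
counts and MAG-by-sample abundance, rounded to integers for the count
model (the attribution sums themselves use the unrounded product so that
contributions add exactly across taxon groups).  Pathway aggregation sums
member KOs; a KO in several pathways contributes to each; unmapped KOs go
to an explicit `unassigned` bucket.

For each contrast, the *overall* pathway change pools the counts of the
pathway's significantly differentially abundant KOs over each diet's
samples; the *attributable* change restricts the KO-per-sample
construction to the differentially abundant MAGs, split by taxonomic
group, with lfc = log₂((Σ_low + c)/(Σ_high + c)), pseudocount c = 1
(absolute pathway counts can be zero).  Scenario classification, with
threshold t = 0.5 on |lfc|: *attribution-only* if the pathway has no
significant KO but |attributable| ≥ t; *disconnect* if |attributable| ≥ t
and the overall change is small (|overall| < t) or of opposite sign;
*agreement* if both are ≥ t with the same sign; *none* otherwise.  The
threshold makes a qualitative judgement testable; it is configurable.
Because counts are summed per diet and the retained crossover leaves
4:5:5 samples for 40:60:80 %, the 40-vs-80 contrast carries a constant
−log₂(5/4) ≈ −0.32 offset relative to a per-sample mean — inherent to
the absolute-count definition and shared by overall and attributable
sides.

Annotation-hit filters: KO hits kept at identity ≥ 50 % and E < 1e−5;
CAZyme hits at coverage ≥ 35 % and E < 1e−18 (identity/coverage bounds
inclusive, E-value strict).  A protein counts once per distinct target
(best hit by lowest E), so multi-domain carbohydrate-active proteins can
contribute several annotation sites.

## The synthetic community generator

Genomes are substitution-only clones: a random root, primary-cluster
ancestors mutated at rate 0.12, optional secondary founders at 0.025
within a primary cluster, and members at half the secondary divergence
(default 0.005) from their founder, so pairwise divergences are
analytically controlled at every level; quality metrics straddle the
80/10 filter.  The catalogue-shaped preset reproduces the published
secondary-cluster size distribution (850 clusters over 1200 genomes) at
10 kb genome length — long enough that k-mer distance estimates separate
the 1 % and 10 % thresholds with wide margins, short enough that the full
dereplication runs in well under a minute.

Counts follow log μ = log(baseline·length_kb) + ln2·lfc(diet) + animal +
period + log gc_bias(GC), NB-sampled via a gamma–Poisson mixture
(variance μ + α·μ²), with 3 contigs per MAG, lengths 8–12 kb, baseline
200 per kb, and animal/period effects of sd 0.35/0.2 on the log scale.
Optionally, named groups of MAGs share one lognormal abundance factor per
sample — co-varying taxa whose joint fluctuations do not average out
under aggregation, the ecological noise structure real communities show.

The interplay preset plants, in a 200-MAG community, 8 strongly enriched
and 4 strongly depleted MAGs (|log₂FC| 3, the differential-abundance
truth), 80 "drift" MAGs with a small shared depletion that no per-MAG
test can see, and 108 flat MAGs in four taxa, two of which form a noisy
dilution background (per-MAG dispersion 0.45 plus a shared taxon factor
of sd 0.18).  KO carriage realises the three scenarios: amino acid and
energy metabolism are carried by the enriched/depleted MAGs (agreement,
both directions); carbohydrate metabolism pairs depleted-MAG-led
significant KOs with enriched-MAG carriage diluted into the noisy
background (disconnect); nucleotide metabolism buries a small
enriched-MAG signal under the co-varying background entirely
(attribution-only).  The planted intensities were designed analytically
so each label follows from the carriage arithmetic with margins against
estimation noise and against false-positive MAGs contaminating the
restricted sums.

One honest limitation: a shared taxon factor aligned with diet purely by
chance is statistically indistinguishable from a real diet effect, and at
4 residual degrees of freedom such alignments occur in roughly one
simulated study in ten, flipping one scenario label.  Scenario-recovery
checks therefore run replicate studies and judge the median — matching
how one would interpret a stochastic endpoint — rather than pretending a
single study is deterministic.

What the generator does not emulate: read-level error and mapping
ambiguity, indels and rearrangements (divergence is substitution-only),
genome-size variation within a community, annotation false positives
beyond Poisson jitter, and compositional closure of sequencing depth
(library sizes follow the planted abundances).  Passing tests therefore
validate the statistical machinery and its calibration, not robustness
to assembly or annotation artifacts.

## Problem sizes used in validation

Tests and the acceptance script run the catalogue dereplication at 1200
genomes × 10 kb, differential-abundance calibration at 2000 null
features, planted-recovery pooled over three 330-MAG studies, attribution
over three to five full pipeline replicates, PERMANOVA calibration over
500 null datasets, and power analyses at 200 resampled matrices × 999
permutations — sizes chosen so each check estimates its quantity with
useful precision while the whole suite completes in a few minutes.
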