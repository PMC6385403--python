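# Methods

## The comparative question and the shape of the pipeline

The pipeline asks whether temporally defined regeneration programs are shared
between a focal species (sampled as a bulk RNA-seq time course of bisected
larval fragments) and two comparator species whose regeneration time courses
are available only as processed tables. The chain is: call differentially
expressed genes (DEGs) in the focal species; cluster their fold-change
profiles into temporal classes; coarse-classify the comparator tables; bridge
the species with a reciprocal-best-hit (rBBH) ortholog map; and test each
(focal class, comparator cluster) pair for an excess of bridged genes with a
hypergeometric upper tail. Every stage is exercised end to end on synthetic
data with known ground truth.

## Differential expression model

Counts for gene *g* in sample *s* are modeled as negative binomial with mean
μ_gs and variance μ + φ_g μ² (a single quadratic overdispersion per gene).
One log-linear model per gene is fit over all 18 samples with a cell-means
group term (one level per fragment × timepoint, 9 levels) and an additive
batch covariate, with log effective library sizes as offsets. Each of the six
contrasts (ANT or POST at T0/T1/T2 versus the age-matched control) is tested
by refitting with the fragment group merged into its control group.

- **Test statistic.** The default is a quasi-likelihood-style F test: the
  1-df likelihood-ratio statistic divided by the per-gene residual deviance
  over its residual degrees of freedom (18 − p), referred to F(1, df). On
  all-null NB simulations at 2000 genes this gives an empirical type-I error
  of ≈ 0.046 at α = 0.05, whereas the plain chi-square reference is
  slightly more liberal (≈ 0.06); both are computed by
  `regencomp.benchmarks.de_null_type1`. The deviance-scaled form is kept as
  the default because the design has only two replicates per cell.
- **Dispersion.** Per-gene method-of-moments estimates pooled over the
  replicated design cells, shrunk toward a lowess trend of dispersion on
  log mean abundance with weight 0.7 to the trend. Genes with no
  within-group variability anywhere are floored at φ = 0. On simulations
  the estimator recovers φ = 0 (median < 1e-3) and φ = 0.4 (median ≈ 0.32).
- **Normalization.** Effective library sizes default to TMM
  (trimmed-mean-of-M-values) factors times the raw totals. Plain totals are
  available (`FilterParams(normalization="cpm")`), but with strongly planted
  programs total-count normalization induces a compositional shift that
  biases every null gene's fold change; concretely, it drags the recovering
  "down early" profile (−e, −e/2, 0) upward at the last timepoint until its
  centroid correlates above 0.9 with the "up late" profile (0, 0, e), at
  which point the consolidation rule merges two genuinely distinct temporal
  programs. TMM removes that failure mode, so it is the pipeline default.
  `cpm_normalize` itself always means plain counts-per-million (columns sum
  to 10⁶); the detection filter runs on that scale.
- **Fold-change reporting.** log₂ of the ratio of group-mean CPM (effective
  library scale) with a 0.5 pseudo-count on both sides — reporting only, so
  the sign is exactly antisymmetric under swapping fragment and control
  labels; the test always runs on raw counts.

## Temporal clustering

The DEG union's 6-column log₂ fold-change matrix is clustered with Euclidean
distance and Ward's minimum-variance criterion in the "D2" convention: merge
height = sqrt of twice the increase in total within-cluster sum of squares,
the convention R's `hclust(method="ward.D2")` applies to unsquared Euclidean
input. scipy's `linkage` implements exactly this; a hand-written greedy
agglomerator that recomputes every merge cost directly from cluster members
(`regencomp.reference.greedy_linkage`) serves as the independent oracle in
the tests and the acceptance script.

- **Cut height** is selected automatically: scan 200 grid heights between
  the smallest and largest merge height and return the smallest at which the
  cluster count is constant over a window (default 5% of the height span).
  A data-specific fixed height can be passed instead.
- **Consolidation** iteratively merges the cluster pair whose centroid
  Pearson correlation is highest, while it stays at or above 0.95. The
  threshold is 0.95 rather than a rounder 0.9 because the two planted
  profiles "recovering from down-regulation" and "late spike" are co-linear
  in time (ideal-shape correlation ≈ 0.87, sampled centroids 0.87–0.92):
  Pearson ignores magnitude, and a 0.9 threshold merges those two real
  programs in a large fraction of runs. Sampling splits of one pattern
  correlate above 0.97 and still merge.
- **Classification into classes I–V** is a sign rule on the consolidated
  centroids with a dead zone of δ = 0.25 log₂ units: I/II when the mean of
  the two first-timepoint entries exceeds +δ/−δ with both fragments on the
  same side; III/IV when the fragment means have opposite signs beyond δ;
  V when the last-timepoint mean exceeds δ while the early mean is inside
  the dead zone; anything else is "other".
- **Comparator transforms.** A normalized-count table is log₂(x+1)
  transformed and z-scored per gene (population SD; constant genes become
  all-zero rows with a warning) and clustered with ward2. A range-binned
  table (values {0,1,2} = lower/mid/upper third of each transcript's range,
  boundary ties to the lower bin, constant genes all-1) is clustered with
  average linkage (UPGMA). Both are cut to exactly three clusters and each
  cluster is labeled up_early / down_early / other by whether the first half
  of its centroid time course exceeds the second half by more than δ.
- **Which comparator genes are clustered.** The normalized-count comparator
  is clustered only over transcripts whose temporal log₂ SD exceeds the
  table's noise scale (0.35), mirroring comparator datasets that ship their
  own differential-expression call; the binned comparator is clustered in
  full (its real counterpart was restricted only to rBBH-matched
  transcripts, which the universe construction below already enforces).

## Ortholog bridge and overlap statistic

Best hits per query maximize bitscore, with ties broken by smaller e-value
and then lexicographic subject id (determinism matters for testing; the
choice is otherwise inconsequential). Duplicate (query, subject) rows keep
the max-bitscore row. A pair (a, b) is an ortholog when each is the other's
best hit; the result is one-to-one by construction and asserted.

The overlap universe for a comparator is the set of focal genes that were
clustered (the DEG union), have an rBBH partner, and whose partner is in the
comparator's clustered set. For focal class F and comparator cluster C:
n₁ = |F ∩ universe|, n₂ = |universe genes whose partner lies in C|,
k = their intersection, N = |universe|, and p = P[X ≥ k] for
X ~ Hypergeometric(N, n₁, n₂), computed through the log-space survival
function (`hypergeometric_overlap_logp` is the underflow-safe form; the
planted overlaps routinely reach p < 1e-40). Raw p is primary; BH-adjusted
values are always emitted alongside. The focal side is tested at the level
of the five consolidated classes, the comparator side cluster-by-cluster
(class labels ride along in the cell names) — one mislabeled mixture cluster
then costs only its own cell rather than diluting a class union.

Two properties are verified by simulation. First, planted recovery: under
the default synthetic configuration the (class I × up-early cluster) cell is
the global minimum-p overlap at p far below 1e-6 across seeds. One subtlety:
when classes I+II partition the universe and the up/down clusters partition
the partner labels, the (II, down) cell is the complementary corner of the
same 2×2 table and carries an *identical* upper-tail p by the symmetry of
Fisher's exact test — the recovery check therefore asks whether the planted
cell attains the minimum within floating tolerance. Second, null
calibration: permuting which partner each mapped focal gene points at makes
the overlap k exactly hypergeometric, and the resulting p-values pass a
two-sided KS uniformity check when the contingencies are large enough for
the discrete support to approximate a continuum (the calibration
configuration uses 5000 genes, 90% orthologs, all five programs shared,
giving universes above 1000 genes). At all-null desk scale the universe is
~130 false-positive genes, the discrete tail p-values are visibly
superuniform, and two-sided KS rejects mechanically even though the null is
valid; the all-null check therefore tests the scientifically meaningful
direction only — no anticonservatism (one-sided KS) and a bounded rejection
rate at 0.05.

## GO enrichment

Annotations are flat gene → term sets, typically transferred across the rBBH
map (each mapped focal gene receives its single partner's terms; no
ontology-graph propagation — that is a documented extension point).
Enrichment of a cluster against the annotated universe reuses the same
hypergeometric tail, skips terms with fewer than 3 universe genes, and
corrects within cluster by Benjamini–Hochberg. Agreement between annotation
sources is summarized per cluster as the Jaccard index of significant term
sets.

## nCounter analysis

Background per sample is the mean plus two sample standard deviations
(n−1 denominator) of the eight negative probes. Scaling vectors are
(across-sample mean of per-sample geometric means) / (per-sample geometric
mean), computed first from the positive controls and then from
positive-normalized housekeeping counts — computing both vectors on raw
counts would correct the per-sample scale twice, which in testing re-injected
the sample-scale variation as apparent dispersion and inflated the DE type-I
error to 0.16. Zeros are floored to 1 inside the geometric means (an
additive pseudo-count would break the exact inverse-scale property of the
factors). Target probes that never exceed their sample's background are
dropped. DE per probe uses the same cell-means + batch count GLM with
log-scaling offsets and a 1-df likelihood-ratio test (type-I ≈ 0.05 on null
panels; a deviance-scaled F variant is available), with a pooled
method-of-moments dispersion and Poisson fallback at zero. Concordance with
RNA-seq is classified per gene over the six shared contrasts: a contrast's
trend agrees when the two log₂ fold changes share a sign or either is within
±0.25 of zero; "trend_only" requires agreement in a strict majority of
contrasts, "trend+significance" additionally a majority of matching DE
flags, otherwise "discordant".

## Cytology statistics

Mann-Whitney U reports U = min(U_x, U_y). The exact mode enumerates all
labelings of the pooled observations and doubles the lower tail (capped at
1); auto mode uses it for tie-free samples with n+m ≤ 12 and otherwise a
normal approximation with tie and continuity corrections (the two agree
within 0.03 at 8+8). The difference of means is reported with a 95%
percentile bootstrap CI over independent group resamples (default 5000,
minimum 1000 draws; deterministic per seed; empirical coverage ≈ 95% at
n = 50 per group). Cell coordinates along the wound axis are split into
equal-width wound/middle/distal thirds with boundary points assigned
wound-ward; the upstream particle-size gates survive as an optional
area filter. Image segmentation itself is out of scope.

## The synthetic generator: what it emulates and what it does not

`SimulationConfig` defaults define the study conditions: 3 species, 2000
genes each, ortholog fraction 0.6, NB dispersion 0.2, library sizes
0.8–1.2 M, per-gene batch effects (log₂ SD 0.2) on the second replicate,
and five planted programs — up_early (150 genes, effect 2.0, shared across
species), down_early (150, 2.0), anterior/posterior_specific (100 each,
1.5), up_late (100, 2.0). Planted log₂ fold-change shapes decay linearly
for the early programs ((e, e/2, 0), mirrored for down_early), are constant
with opposite fragment signs for the axis programs, and rise only at the
last timepoint for up_late. Expected counts are renormalized to the drawn
library size, so the generator reproduces the compositional coupling real
library-size normalization faces. Orthology is independent of program
membership except that shared programs draw their genes from paired genes
and stamp the partner with the same program; 40% of the remaining pairs are
"divergent" — the comparator member runs its own randomly chosen program
while the focal member's expression is not mirrored. That fraction reflects
how regulated real comparator datasets are (roughly half of their mapped
transcripts carry a DE call) and gives the overlap universe a realistic
background of mapped-but-unshared genes. Comparator tables put the program
shapes on 4 pseudo-timepoints with log₂ noise SD 0.35 — one table as scaled
positive counts, one as per-gene range bins. Similarity tables encode every
truth pair as mutual top hits; decoys (rate 0.2 by default) score at most
0.8× the query's true-pair bitscore and always point at a subject whose own
best hit is its true partner, so recovery is exact at any decoy rate by
construction. The nCounter panel uses 8 negative probes (Normal(10, 3)
background, no sample scaling), 6 positive and 11 housekeeping probes riding
a lognormal per-sample factor, and ≥ 20 target probes sampled across
programs, two of them deliberately below background.

What the generator does **not** emulate: GC/length biases, tagwise
dispersion trends, unbalanced designs, many-to-many homology, cross-species
timing misalignment beyond coarse pseudo-time, and correlated gene modules
beyond the planted programs. Passing tests therefore demonstrate that the
*procedures* behave as specified under their stated model — calibrated
nulls, exact oracles, recoverable planted structure — not that any
particular biological dataset will show the same effect sizes.

## Problem sizes and numerical choices

Simulated experiments run at 2000 genes (recovery, DE calibration), 5000
genes (permutation-null calibration), 20 seeds for across-run rates, 200
permutations for null checks, and 1000 bootstrap draws inside coverage
simulations — sizes chosen so each experiment completes in seconds to about
a minute on one CPU while leaving the binomial noise on reported rates well
inside the margins being asserted. GLM fits clip the linear predictor at
±30, add a 1e-8 ridge to the normal equations, and iterate IRLS to a 1e-10
log-likelihood tolerance (max 50 iterations). Dispersions are floored at 0,
the hypergeometric tail is evaluated in log space, and all randomness flows
from numpy `SeedSequence`s spawned from the configuration seed, so every
pipeline run, including its written report, is byte-reproducible.
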