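# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated against, and the numerical choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Droplet QC

All three filters operate on Gaussian kernel density estimates (Silverman
bandwidth, 512-point grid padded by three bandwidths) of log10-transformed
summary statistics.

* **Cell-less barcodes.** The per-barcode UMI-total distribution of a
  droplet library is bimodal on a log10 axis: an ambient-only mode from
  empty droplets and a cell mode at higher depth.  Barcodes below the
  first local minimum of the density above `log10(#UMIs) = 2` are removed.
  Local minima are grid points no higher than both neighbours and strictly
  lower than at least one, so an exact two-point plateau at a valley
  bottom still counts while monotone runs do not.
* **Sparse genes.** Same rule on the per-gene detection-count density with
  a floor of `log10(#barcodes) = 3`.  A floor of 3 implies detection in
  ~1,000 barcodes, which only bites in large libraries; the floor is a
  parameter (`x0`) for smaller ones.  Genes detected in zero barcodes are
  always removed before density estimation (their log10 is undefined).
* **Multiplets.** Barcodes that captured more than one cell inflate both
  the gene count and the UMI total.  In each of the log10(#genes) and
  log10(#UMIs) densities, a local mode is treated as a multiplet
  population when its *location* exceeds `ratio = 1.5` times the global
  mode location (a ratio on the log10 axis) and its members — barcodes
  above the local minimum separating it from the global mode — comprise
  fewer than `max_frac = 5%` of barcodes.  The flagged sets from the two
  distributions are unioned.  Both knobs are exposed.

If no qualifying minimum or mode exists, the corresponding filter is an
identity transform and the report records that fact; all thresholds and
mode locations appear verbatim in the `QcReport` so summary tables can be
reproduced.

## Iterative clustering

The stage chain is: depth scaling (each barcode scaled to the median
barcode total, so profiles are depth-invariant), high-dispersion gene selection
(20 equal-occupancy mean-expression bins; log dispersion = log(var/mean)
z-scored within bin; keep z >= 1; a single-bin degenerate case falls back
to global z-scoring), log1p transform, per-gene centering and unit
scaling, randomized-SVD PCA retaining 50 components, a shared-nearest-
neighbor graph, and resolution-searched modularity clustering.  The log1p
before PCA is a variance stabilisation choice: without it the highest-
expressed genes dominate the principal components even after unit
scaling of the input counts.

**SNN graph.** Each cell's neighbor set is itself plus its k nearest
neighbors in PC space, k = min(750, n-1); the edge weight between two
cells is the Jaccard overlap of their neighbor sets, and edges below 1/15
are pruned.  Including the cell itself makes coincident cells share
identical sets (weight exactly 1) and makes the k = n-1 limit saturate at
weight 1 for every pair.  That saturation is also why the iterative
recursion additionally caps k at half the current subset size: for any
subset below ~1,500 cells the formula's k = n-1 would make every
neighborhood the entire subset, erase all edge-weight contrast, and
render subclustering impossible.  With the cap, the formula's value is
used unchanged whenever it is informative.

**Resolution search.** Modularity is optimised (RB-configuration
objective, seeded, two refinement iterations) at each resolution in
0.05–1.225, step 0.025.  Each candidate partition is scored by the mean
over clusters of the mean silhouette coefficient of that cluster's cells
in PC space — a balance of how isolable each cluster is against how
unifiable its members are; ties go to the lowest resolution.  Because
modularity optimisers always carve spatially coherent communities out of
structureless data, and those communities carry a small positive
silhouette that grows as subsets shrink, the best candidate must both
exceed a floor of 0.05 and beat, by a factor of 1.25, the best score the
identical search attains on a reference sample drawn from a Gaussian with
the same per-component variances (principal components are uncorrelated,
so this preserves the subset's global geometry while destroying cluster
structure).  Otherwise the trivial single-cluster partition is returned.
On planted-cluster simulations genuine splits score several-fold above
their reference while noise scores match it, so the margin is not a
sensitive tuning.

**Iteration.** The search runs on all cells, then recursively inside each
resulting cluster (re-selecting variable genes and re-embedding each
subset); a cluster converges when the search returns one cluster or the
subset has fewer than 50 cells (a guard against degenerate splits), with
a recursion-depth cap of 10 as a non-convergence guard.  Lineage paths
("3.1.2") record the full history; converged labels always refine
first-iteration labels.

## Markers and annotation

**Bimodal likelihood-ratio test.** Within a cluster, a gene's depth-scaled
expression is modelled as a point mass at zero (probability 1 - pi) plus
log-normal positives.  Comparing clusters A and B, the alternative gives
each its own pi and log-mean; the null shares both; the log-variance is
pooled across both groups in both models (estimated from the within-group
sum of squares).  The statistic 2(l_A + l_B - l_pooled) is referred to a
chi-square with 2 df (pi and mu free per group).  Degenerate cases: both
groups all zero gives statistic 0, p 1; a zero positive-part variance is
floored at 1e-8.  The vectorised implementation used by `find_markers`
is checked gene-by-gene against the scalar definition.

**Markers.** Every gene is tested for each ordered cluster pair; BH
adjustment is applied per pairwise comparison across genes; a marker of a
cluster must be overexpressed with adjusted p < 0.05 against *every*
other cluster (all-pairwise, not one-vs-rest).  This definition is
anti-symmetric: a gene cannot mark two clusters in one run.

**Annotation.** Markers are intersected with a reference TPM matrix
(columns sum to 1e6).  A marker votes only if its top reference type has
TPM >= 50 and at least 4x the second-highest type (genes expressed in
exactly one type pass any fold, including infinity); the cluster takes
the plurality type, with ties or empty vote sets mapped to `unassigned`.
Both thresholds are parameters; the defaults encode "strong and specific"
for bulk-sorted reference profiles.

**Heatmap downsampling** allocates a 2,500-cell budget across clusters by
largest-remainder rounding of proportional quotas, samples uniformly
within cluster, and guarantees every non-empty cluster at least one cell
(exceeding the budget minimally if there are more clusters than budget).

## Hurdle differential expression

Single-cell expression of a gene within a cell type is zero-inflated; a
condition can change the fraction of cells expressing the gene, the level
among expressing cells, or both, and the two have different biology.  The
condition effect is therefore decomposed:

* **Induction**: logistic regression of the binarised outcome on
  condition (control baseline) with a Normal random intercept per sample;
  the effect is a log-odds difference.
* **Level**: gamma regression with log link on expressing cells only,
  same random-effect structure; the effect is a natural-log fold change.
  The component is reported absent when either condition has fewer than
  two expressing cells.

The marginal likelihood integrates the per-sample intercepts with 31-node
Gauss–Hermite quadrature and is maximised by L-BFGS-B over (intercept,
effect, [log shape,] log sigma) with a negligible ridge (1e-6) on the
location parameters for stability under separation.  Wald standard errors
come from the observed information; because the likelihood is flat in
log sigma at the sigma = 0 boundary, the full Hessian can be near-singular
there and is used only when positive definite and well conditioned —
otherwise log sigma is held fixed and the reduced Hessian is inverted
(without this guard a few percent of null fits produce corrupted,
near-zero SEs and the type-I error triples).  On optimiser failure the
model falls back to a fixed-effects GLM with sample as a covariate and
the result is flagged; fitted |log-odds| > 8 is flagged as separation.
With the sample SD at zero the mixed estimates agree with fixed-effects
GLM estimates, which the tests verify against statsmodels.  The gamma
shape is estimated per gene, not pooled.

BH adjustment runs across genes within each (cell type, component).

**Proportion shifts** use a baseline-category multinomial regression of
cluster label on condition without a random effect.  With one binary
covariate its MLE is closed-form: each non-baseline cluster's effect is
the 2x2 log odds ratio against the baseline cluster (largest cluster by
default) with Woolf SE; zero cells receive an add-0.5 continuity
correction and are flagged.  Tests verify the closed form against the
iterative multinomial-logit fit.

**Preranked GSEA** ranks genes by a signed statistic — sign(effect) x
(-log10 p), since a p-value ranking needs a direction to distinguish up-
from down-regulation — and computes the classic weighted Kolmogorov-
Smirnov running-sum enrichment score (hit increments weighted by
|statistic|, miss decrements uniform), whose extreme is the ES in
[-1, 1].  The null shuffles gene labels; the p-value is two-sided on
|ES| with the +1 correction (smallest attainable p is 1/(B+1)); the
normalised score divides by the mean |null ES| of the same sign; the
leading edge is the set members at or before (after, for negative ES)
the extremum.  Sets with fewer than 5 ranked members are skipped.

## ISH statistics

Automated ISH quantification bins cells by puncta count (1..9, 10+), and
whether a low-puncta cell is truly positive for the probed marker is
uncertain.  For every cutoff b in 2..10 cells are binarised (positive:
>= b puncta), samples are pooled within species, and a two-category
multinomial (logistic) regression of positivity on species — closed form:
the pooled 2x2 log odds ratio with Woolf SE, add-0.5 on zero cells —
gives a per-cutoff species effect with mouse as baseline.

The nine per-cutoff effects are combined as mean / SE(mean).  The nine
binarisations reuse the same cells at nested cutoffs, so the effects are
strongly positively correlated and the naive sd/sqrt(9) standard error is
badly anti-conservative (more than half of null replicates exceed |z| =
1.96 in simulation).  The default standard error therefore combines the
between-cutoff spread with the sampling error under the worst-case
perfect-dependence assumption:

    SE = sqrt( var(effects)/9 + mean(per-cutoff SE)^2 )

which is conservative by construction (0/200 null rejections, full power
at a log-odds-2 effect in the tests).  The naive reading remains
available as `combine_bins(method="sem")`; identical effects under it
give SE 0 and |z| = inf, reported at the floating-point underflow
minimum rather than an exact zero p.  The combined z is exactly
sign-equivariant under swapping the species labels.

## Gene-family evolution

* **Orthology.** BLAST tabular hits are filtered to e-value < 0.1 and
  identity > 80 (strict); per query form the best subject (lowest
  e-value, then highest bitscore) is taken; forms aggregate to genes
  (default mapping strips the final dot-suffix); a gene pair is a
  one-to-one ortholog when each has some form best-hitting the other.
* **Orthogroup augmentation.** Annotated pseudogenes whose transcripts
  hit any protein-coding family member above the same thresholds join
  that family; conflicts resolve by best e-value, then identity, with
  exact ties flagged.
* **Putative pseudogenes.** Genomic homology hits (1-based inclusive
  intervals; overlap = at least one shared base; strand ignored) pass
  five stages: identity >= 40; union-merge of interval-overlapping hits
  of the same family (merged domain statistics take the best member;
  merging is idempotent); domain confirmation with e-value < 0.1 AND
  identity > 60; restriction to the family's locus scaffolds (derived
  from the annotations when not supplied); and removal of hits
  overlapping any annotated gene.  LILR and KIR never emit putative
  pseudogenes: their defining immunoglobulin domain is shared between
  the two families, so genomic hits cannot be attributed reliably —
  which the false-positive benchmark makes measurable.
* **Benchmark.** Among merged hits covering annotated genes, the
  false-positive fraction is the share whose covered gene belongs to a
  different family than the query, stratified by search genome; families
  at or above 5% are flagged.  On synthetic tables with planted
  cross-family confusion the benchmark recovers the realized planted
  fraction exactly.
* **Phyletic pattern.** Species x family counts of protein-coding (P),
  annotated pseudogene (Psi), and putative pseudogene (psi) records,
  with psi forced to zero for the excluded families and species absent
  from the annotations reported as explicit zeros.
* **Sankoff reconstruction.** Gene counts are states 0..S_max (default:
  the maximum tip count); the cost of changing from i to j genes along an
  edge is |i - j| — linear in the number of gains/losses, and any
  proportionality constant leaves the minimiser unchanged.  Branch
  lengths are ignored.  A bottom-up pass computes per-node minimal
  subtree costs and counts of optimal subtree assignments; a top-down
  outside pass completes them, giving for every internal node the set of
  states attaining the global minimum and a probability for each equal
  to its share of the globally minimum-cost full assignments (uniform
  measure over co-optimal histories, marginalised per node).  The MAP
  state is the most probable, ties resolved to the smaller count.  The
  DP is verified against exhaustive enumeration (`brute_force_parsimony`,
  guarded to <= 8 internal nodes and S_max <= 6) on random instances,
  including the per-state optimality sets, and the minimal cost is
  invariant to re-rooting.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under a seed and return the planted
truth needed for every downstream recovery metric.

* **Droplet experiments.** Cluster expression is gamma-Poisson (negative
  binomial, shape 10 by default) around cluster profiles built from a
  shared log-normal baseline with marker genes up-shifted by a planted
  log fold change; empty droplets draw the ambient (mean) profile at low
  depth; designated ambient genes (emulating haemoglobin from lysed red
  blood cells) add a Poisson background to *every* barcode at a fixed
  UMI fraction.  Cell and empty log10-depth modes sit at 3.4 and 1.7
  (SD 0.2 each), several bandwidths apart, as in a clean 10x library.
  Multiplets mix two parent cells' profiles and are resampled at an
  inflated capture depth whose log10 mode defaults to 1.6x the cell
  mode, so the planted population matches the mode-location detection
  rule the QC implements; they default to 3% of cells.  Not emulated:
  batch effects, ambient contamination beyond the designated genes,
  saturation/duplication noise, or cell-cycle structure — so passing QC
  and clustering tests demonstrates correctness of the procedures, not
  robustness to every real-data artifact.
* **Two-condition experiments.** Per gene, cells express with probability
  logit^-1(logit(pi0) + delta*I(treated) + b_sample) and expressing cells
  draw a gamma level with log-mean shifted by beta*I(treated) +
  b'_sample, rounded to a positive count.  Random intercepts are drawn
  independently per gene and sample (SD 0.15 by default; two samples per
  condition, 1,000 cells per condition), keeping genes independent so
  calibration rates over genes are meaningful.  Null calibration runs use
  SD 0 so the rejection rate isolates the fitter rather than the
  finite-sample behaviour of variance-component estimation with two
  samples per condition.
* **Gene-count histories** evolve by a jump process with constant gain
  rate (so an empty family can be re-seeded) and per-gene loss rate,
  simulated exactly along each branch.
* **Puncta tables** draw positivity per cell from a species-dependent
  Bernoulli (baseline log-odds plus the probe's planted species effect)
  and give positive cells 1 + geometric(0.35) puncta, binned 1..9 and
  10+ — a zero-inflated geometric, chosen for its monotone tail;
  the real segmentation pipeline's cell-size and focus artifacts are not
  modelled.
* **Homology tables** plant one-to-one orthologs as mutual best hits at
  ~95% identity over weaker within-family off-target hits, annotated
  pseudogenes hitting their family at 82–94% identity, intergenic
  decayed loci at 50–60% identity with passing domain confirmations, and
  an optional fraction of gene-covering genomic hits redirected to a
  different family, whose realized fraction is recorded as the planted
  false-positive truth.
* **Reference profiles** put each type's markers at a fixed multiple
  (1.5x the specificity factor, for margin) of the flat background and
  normalise columns to 1e6 TPM.

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 25–50 QC replicates
at 2,000 cells + 2,000 empties x 600 genes; one 2,000-cell x 800-gene
nested (3 majors x 2 subclusters) clustering run; 1,200 cells x 400 genes
for marker/annotation recovery; 200 null genes and 100 effect genes
(1,000 cells and 2 samples per condition) for the hurdle model; 200 null
and 50 power replicates of 4-sample, 300-cell puncta tables; and 200
random Sankoff instances with up to 6 tips and counts up to 4.  These
sizes give stable Monte-Carlo estimates for every threshold tested while
keeping a full run in minutes on one core.

## Known limitations

* The cluster-quality metric is a silhouette-based stand-in chosen for
  the search's apparent intent (isolation vs cohesion); it is pluggable,
  and other metrics may choose different resolutions on borderline data.
* The Gaussian reference used to calibrate split acceptance assumes
  roughly elliptical noise in PC space; heavy-tailed embeddings could
  still produce spurious splits.
* The putative-pseudogene pipeline consumes homology and domain hit
  tables; it does not run the underlying search engines, so its output
  quality is bounded by theirs.
* Co-optimal-state probabilities weight all minimum-cost histories
  uniformly; an alternative (uniform over per-node co-optimal states)
  can be derived from the reported optimal sets, but probabilities under
  weighted parsimony or likelihood models are out of scope.
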