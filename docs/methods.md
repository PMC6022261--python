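# Methods

## Quantification

For site *n* under condition *s* with IP count *t*, input count *c* and
size factors *d_t*, *d_c*, the methylation level is
m = (t/d_t) / (t/d_t + c/d_c).  Size factors are each library's total
read count divided by the mean total of libraries of the same kind
(IP or input), so they are dimensionless, average to one, and the
estimator reduces to t/(t+c) at equal depth.  A zero-coverage
measurement (t = c = 0) is 0/0; we return the uninformative midpoint
0.5 and keep its coverage of 0, so that the *weighting* layer — not the
quantifier — suppresses it.  Dropping such sites instead would discard
exactly the cases the method is designed to tolerate.

An M-value alternative is provided as
M = log₂((t/d_t + ε) / (c/d_c + ε)) with ε = 0.5; the additive offset
keeps zero counts finite, and the transform is antisymmetric under
swapping the IP and input roles.

Preprocessing follows the field's standard order: merge biological
replicates by summing counts within condition, estimate size factors,
quantify, quantile-normalize across conditions (reference = mean of the
column-sorted values; ties get the mean reference value of the tied
ranks), select dynamic sites (top 20 000 by row mean, then top 10 000
by row variance, ties broken by input order), and standardize each
site's profile to zero mean and unit sample (n−1) standard deviation.
Selection statistics are computed on the quantile-normalized beta
values.  A constant profile cannot be standardized and raises an error
naming the site; pipelines on tiny simulated datasets may instead drop
such rows explicitly (`drop_constant=True`).

## Reliability weighting

The combined coverage of a pair (i, j) in condition s is
v_s = t_{i,s} + c_{i,s} + t_{j,s} + c_{j,s}.  Raw weights are
log(v_s + 1) (logarithm scheme) or 1/β above/below a count threshold
(threshold scheme), normalized to sum to one per pair.  Normalization
makes the logarithm scheme independent of the log base.  An all-zero
raw vector (possible with β = 0, or zero coverage everywhere) falls
back to uniform weights so every pair has a defined distance.

The threshold is parameterized as a quantile α of the empirical
distribution of pairwise coverage sums over all entity pairs and
conditions — resolved once per dataset and cached on the scheme.  The
quantile uses numpy's default linear interpolation between order
statistics, pinned for bit-reproducibility; the resolved threshold is
therefore generally fractional, which is immaterial because it is only
compared against integer sums.  For more than 2000 entities the
distribution is estimated from 100 000 seeded random pairs.  α = 0
resolves to a threshold of 0, so no measurement is penalized.  β is not
clamped to [0, 1]: values above 1 deliberately invert the weighting and
serve as negative controls.  Quantiles over *pairwise sums* (the
quantity the threshold rule actually tests) rather than per-measurement
coverages are used throughout; at α = 0.45 with ~45 % unreliable
measurements the cut lands at the upper edge of the unreliable mass.

## Distances and clustering

Weighted Euclidean (default), weighted squared Euclidean and weighted
city-block metrics are available; the Euclidean form takes the square
root of the weighted sum, and with uniform weights equals the classic
Euclidean distance divided by √S — a monotone transform, so
rank-based linkages are unaffected.  Distances between *samples* reuse
the same contract with profiles and coverage transposed: the weight of
site dimension *n* for a sample pair is driven by
t_{n,s_i} + c_{n,s_i} + t_{n,s_j} + c_{n,s_j}.

Clustering is scipy agglomerative linkage on the condensed matrix.  Two
defaults are used deliberately:

* the 6-sample benchmark clusters **samples** with *complete* linkage,
  which depends only on the ranking of distances (so any monotone
  rescaling gives identical labels — an invariant the tests exploit);
* module detection clusters thousands of **sites** with *Ward* linkage.
  On large, noisy site sets complete and average linkage split big
  modules around outliers often enough to matter (in our recovery
  experiments they fail on ~20 % of seeds where Ward fails on none);
  Ward's variance criterion is the standard choice for compact
  modules of comparable size.  Both are configurable everywhere.

The silhouette diagnostic follows the usual definition with singleton
clusters contributing 0.  The exact-match benchmark criterion counts a
dataset as correct only when the predicted partition equals the true
sample labels up to relabeling; for n samples in two groups there are
2^(n−1) − 1 distinct bipartitions, giving the 1/31 ≈ 3.2 % chance
floor at n = 6.

The (α, β) grid search evaluates every combination over datasets of
several sizes.  Dataset seeds derive from the root seed and the
(size, repetition) indices only, so every grid cell sees identical
data: columns are exactly comparable and the β = 1 column reproduces
the unweighted baseline bit-for-bit.  Default axes are
α ∈ {0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.50, 0.55, 0.65, 0.75, 0.85, 0.95},
β ∈ {1e-4, 5e-4, 2.5e-3, 1.35e-2, 0.03, 0.045, 0.06, 0.09, 0.135,
0.15, 0.3, 0.75, 1, 1.5, 7.5} and sizes 10–100 in steps of 10
(duplicates deduplicated).  The tuned operating point used as the
package default is α = 0.45, β = 0.09.

## Enrichment scoring

A module's biological significance against a term↔gene annotation is
scored per term by the one-sided hypergeometric tail P(X ≥ k) (module
size n, term-in-background size K, background N); terms with more than
1000 background genes are discarded as uninformatively broad before
ranking.  The score is the sum of −log₁₀ p over the 20 smallest
p-values (ties broken by term id).  Base 10 is a presentation choice:
any base rescales all scores by the same factor and never reorders
them.  Because raw scores are incomparable across module sizes, a
module is judged by the fraction of uniformly random same-size *site*
sets (mapped to deduplicated genes) that it out-scores; matching on
sites rather than genes reflects that clustering operates on sites.
The background is the gene set of the analyzed sites.  No
multiple-testing correction is applied: only the ranking of p-values
enters the score.  Overlap with an external target-site list uses a
2×2 Fisher exact test (one-sided, "greater"); the odds ratio is ad/bc
with a Haldane 0.5 correction only when a cell is zero.

## Synthetic data

The generator emulates the features of MeRIP-seq count data that the
weighting strategy is sensitive to, and nothing more.

**Noise model.**  Each measurement draws a total count
T ~ Poisson(λ·depth) and splits it binomially, t ~ Binomial(T, p),
c = T − t.  This makes m̂ = t/(t+c) unbiased with variance ∝ 1/T —
precisely the coverage-reliability coupling the weighting presupposes.
Independent Poisson IP/input draws would decouple the ratio's variance
from the total and were rejected for that reason.

**Coverage heterogeneity.**  Per-site expression λ is log-normal
(median 100 reads for module simulations, 30 for the small benchmark
datasets; σ_log = 1.0 and 0.25 respectively).  A fraction of
measurements — default 0.45, reflecting that roughly half the genome is
unexpressed in any one cell type — fall on lowly expressed
site-condition cells with λ log-normal around 6 reads (benchmark) or
2 reads (module mode).  In module mode the low-coverage cells are
chosen per *measurement* (context-specific expression: the same site
can be well covered in one condition and unmeasurable in another);
this is what gives per-condition weights something to act on.

**Artifacts.**  Measurements on lowly expressed cells additionally
scatter around the true methylation level with a Beta perturbation of
concentration 2 — far beyond binomial noise.  This models the
background-dominated, artifact-prone character of weak-signal IP
measurements; without it, moderately covered junk measurements are
partially self-correcting and the logarithm and threshold schemes
become practically indistinguishable.

**Planted structure.**  Module profiles π[k, s] are uniform on
(0.1, 0.9) with a minimum pairwise Euclidean separation of 0.25·√S
(rejection-redrawing): modules are meant to model *distinct* regulatory
programs, and profiles closer than the within-module jitter (Beta,
concentration 150) would not be distinct in any operational sense.
The benchmark mode plants a two-group design (3 + 3 samples): 75 % of
sites shift their level by 0.17 between groups, half up and half down
so that quantile normalization — which forces equal marginals across
samples — cannot erase the signal, as it would for a one-directional
global shift.

**What it does not model.**  Read-level artifacts (GC, fragment
length, mappability), correlated sites along a transcript,
differential expression confounding, overdispersed library sizes.
Consequently, passing tests show that the method behaves as designed
when unreliability is coverage-linked; they cannot certify performance
on artifacts uncorrelated with coverage.

**Problem sizes.**  The shipped experiments use 600-dataset benchmark
suites (30 sites × 6 samples each), 50-seed recovery runs at 2000
sites × 9 conditions, and 400-site degradation/rescue comparisons —
sizes at which the Monte-Carlo error is small relative to the effects
being demonstrated while a full test run stays comfortably fast.

## Numerical and degenerate-input choices

* Weight vectors are renormalized in C-contiguous memory so that equal
  weights produce bit-identical distances across schemes — the
  α = 0 / β = 1 reduction to the unweighted method is exact, not
  approximate.
* Merge ties in linkage follow scipy's deterministic index order; all
  stochastic routines take explicit seeds, with named substreams
  (profiles, expression, jitter, counts, annotation) so components are
  independently reproducible.
* Dense distance matrices are capped at 20 000 entities with a clear
  error; the cap is an argument, not a constant.
* The run pipeline embeds a config hash in every artifact and logs the
  resolved count threshold, so a run can be audited (`run --verify`).

## Known limitations

* α and β need data-specific tuning; the shipped defaults are a tuned
  operating point for ~45 % unreliable measurements, not a universal
  constant.
* Modules are mutually exclusive flat clusters; sites regulated by
  several enzymes at once are forced into one module.
* The hypergeometric score treats terms independently (no ontology
  DAG propagation) and its comparison to random modules is a relative,
  not calibrated, significance statement.
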