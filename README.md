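# epimodule

Coverage-weighted clustering of RNA-m⁶A methylation profiles from
MeRIP-seq count data, for finding **epitranscriptome modules** — groups
of methylation sites whose methylation levels co-vary across
experimental conditions and therefore plausibly share an upstream
regulator (a writer such as METTL3/METTL14/WTAP, or an eraser such as
FTO/ALKBH5).

## The problem

MeRIP-seq (m⁶A-seq) measures methylation at a site by pairing an IP
library (antibody-enriched, methylated fragments; read count *t*) with
an input library (background RNA; read count *c*).  With per-library
size factors *d_t*, *d_c*, the methylation level of a site under one
condition is the depth-corrected IP fraction

    m = (t / d_t) / (t / d_t + c / d_c)  ∈ [0, 1].

The catch is that transcriptome coverage is wildly heterogeneous: a site
with *t* = 100, *c* = 0 and a site with *t* = 1, *c* = 0 both give
*m* = 1, but the second estimate rests on a single read and carries
essentially no signal.  Treating all measurements equally lets this long
tail of unreliable estimates dominate any distance-based analysis.

## The method

Every pairwise profile comparison is weighted by the read coverage
behind it.  For sites *i*, *j* and condition *s*, let
*v_s* = *t_{i,s}* + *c_{i,s}* + *t_{j,s}* + *c_{j,s}* be the combined
coverage.  The weighted Euclidean distance is

    d_w(i, j) = sqrt( Σ_s w_{s,i,j} (m_{i,s} − m_{j,s})² ),   Σ_s w_{s,i,j} = 1,

with two weighting schemes:

* **logarithm** — raw weight log(*v_s* + 1), normalized per pair:
  reliability grows with coverage but saturates;
* **threshold** — raw weight 1 when *v_s* reaches a count threshold,
  otherwise a reduced weight **β**.  The threshold is given as a
  quantile **α** of the empirical pairwise-coverage distribution, so
  α = 0.45 penalizes roughly the least-covered 45 % of measurements.
  β > 1 is allowed as a negative control (it *up-weights* junk).

Around this sit the standard steps: replicate merging, total-count size
factors, quantile normalization, dynamic-site selection (top 20 000 by
mean methylation, then top 10 000 by variance), per-site
standardization, hierarchical clustering, silhouette diagnostics, and
hypergeometric GO-style enrichment scoring of the resulting modules
(sum of −log₁₀ *p* over the top 20 terms, broad terms with > 1000
background genes discarded), plus Fisher-exact overlap tests against
external target-site lists.  A seeded synthetic generator stands in for
real GEO datasets: planted modules, log-normal coverage with a
context-specific low-expression tail, Poisson totals split binomially
between IP and input, and a 6-sample / 2-condition benchmark mode
scored by the exact-match criterion (a clustering counts only if every
sample is placed correctly; for 6 samples random guessing succeeds with
probability 1/31 ≈ 3.2 %).

## Worked example

```python
from epimodule import ModuleDetection, SyntheticSpec, simulate_counts, adjusted_rand

counts, truth = simulate_counts(SyntheticSpec(
    n_sites=1000, n_conditions=9, n_modules=5, seed=7,
))
model = ModuleDetection(counts, merge=False, drop_constant=True)
res = model.fit(k=5)
print(res.summary())
```

```
Epitranscriptome module detection
==============================================
sites retained        1000
conditions            9
modules (k)           5
metric / linkage      euclidean / ward
weighting             threshold
  alpha (quantile)    0.45
  beta                0.09
  count threshold     83
mean silhouette       0.1875
----------------------------------------------
module   n_sites   n_genes
     1       194       194
     2       214       214
     3       220       220
     4       160       160
     5       212       212
```

The resolved count threshold (83 reads here) is the 45 % quantile of
the pairwise coverage sums for this dataset; the low mean silhouette is
typical of epitranscriptome data, where cluster structure is real but
weak.  Comparing recovered modules against the planted truth on this
dataset (45 % of measurements on lowly expressed, artifact-prone
conditions):

```python
adjusted_rand(res.labels, truth.site_modules)   # 0.575 with weighting
# refitting with scheme=WeightingScheme("none") gives 0.423
```

— the threshold weighting recovers a substantial part of the accuracy
that unreliable measurements destroy.

## Command line

`epimodule` exposes `simulate`, `quantify`, `cluster`, `benchmark`,
`gridsearch`, `enrich` and `run` (end-to-end from a YAML config, with
`--verify` for artifact/config-hash auditing).  All stochastic commands
take `--seed`.

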