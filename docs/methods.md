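# Methods

## Model

Hi-C contact counts between bins `i` and `j` decay steeply with genomic
distance `d = |i - j|`, so enrichment is only meaningful relative to the
distance-matched expectation. `nbloop` works on one chromosome at a time,
on the upper triangle of the (balanced) contact matrix restricted to a
distance band — by default 4 bins to 2 Mb, since near-diagonal pairs are
dominated by polymer proximity rather than looping, and loops beyond a few
megabases are rare.

### Expected values and obs/exp

Three per-distance expected values are supported:

* `nonzero` (default): sum of values at distance `d` divided by the number
  of nonzero entries at `d`. Robust to sparse rows, and the least likely to
  deflate the expectation on poorly covered matrices.
* `all`: sum divided by all `n_bins - d` positions.
* `ligation`: the nonzero mean scaled per element by
  `rowsum_i · rowsum_j / total_sum`, a coverage correction in the spirit of
  HOMER's background model. Row sums are marginals of the full symmetric
  matrix (off-diagonal entries contribute to both rows).

Distances whose entries are all zero carry no expected value and are
excluded from fitting and candidate search — an expectation of zero would
make every downstream ratio undefined.

### Per-distance continuous negative binomial

Counts at a fixed distance are overdispersed (variance > mean), which a
Poisson model cannot express; the negative binomial adds the needed free
parameter. Because obs/exp values are real-valued, the discrete NB pmf is
continued by replacing the binomial coefficient with gamma functions:

    f(k; r, p) = Γ(k+r) / (Γ(k+1) Γ(r)) · p^k · (1-p)^r,  k ≥ 0, r > 0, 0<p<1

with mean `r·p/(1-p)` and variance `r·p/(1-p)²`. The density is evaluated
in log space (`gammaln`), so arguments up to k ~ 10⁴, r ~ 10³ neither
overflow nor underflow.

The right tail is the regularised incomplete beta function

    P(X ≥ m) = I_p(m, r),

the continuous extension of the discrete tail sum `Σ_{x≥k} f(x)`: the two
agree exactly at integer `m`, `I_p(m, r) → 1` as `m → 0⁺`, and the function
is non-increasing in `m`. A zero obs/exp value is assigned p-value 1
outright — an empty pixel can never be evidence of enrichment.

**Fitting.** Each distance is fitted independently by maximum likelihood of
the continuous density, with `p` profiled out analytically (at fixed `r`
the likelihood is maximised by `p = mean/(mean + r)`, which pins the model
mean to the sample mean) and `r` optimised in log space over a bounded
interval (`r ∈ [10⁻³, 6.6·10⁷]`, Brent/bounded scalar minimisation,
`xatol 1e-8`). When the sample is overdispersed the method-of-moments value
`r = mean²/(var - mean)` is effectively recovered; when it is
*under*dispersed — the typical situation after the prefit tail truncation
below, since cutting the left of a distribution shrinks its variance — the
optimiser converges to the large-`r`, small-`p` corner, i.e. a
quasi-Poisson continuous NB. That is a deliberate property, not a failure:
the model stays valid (`r > 0`, `p ∈ (0,1)`) and its right tail remains a
usable, slightly conservative significance measure. A fit is refused
(`fit_ok = False`, distance skipped) only when fewer than
`min_fit_observations` (default 100) values are available or the sample is
degenerate (zero mean or zero variance).

**Prefit thinning.** Values below `obsExpThreshold` (default 1.5) are
removed before fitting. This reuses the candidate enrichment gate as a data
reduction device: the fitted model then describes the upper tail of the
per-distance distribution, which makes the preselection p-value
conservative for values near the threshold while leaving strong
enrichments (several-fold over expectation) clearly significant.

**Overdispersion diagnostic.** The Cameron–Trivedi auxiliary regression:
with sample mean `m̂`, regress `(x - m̂)² - x` on `m̂` without intercept and
flag overdispersion when the one-sided t statistic exceeds the 5% critical
value. It is intended for raw counts per distance, where the NB premise
lives; an all-equal sample returns `(0, False)` by convention.

## Candidate selection

A pixel `(i, j)` is a candidate iff all of:

* its distance lies in the configured band and carries a model,
* `m* ≥ obsExpThreshold` (default 1.5),
* `P(X ≥ m*) < pValuePreselection` (default 0.1), applied with the same
  significance level independently at every distance,
* its **raw** (uncorrected) count `≥ peakInteractionThreshold` (default
  10) — balancing can inflate ratios in poorly covered rows, so the
  absolute-interaction gate intentionally bypasses the correction.

Tightening any gate can only remove candidates, which the test suite pins
as a superset/subset property.

## Neighborhood testing

Candidates within Chebyshev distance `windowSize` of one another describe
the same structure; only the one with the highest obs/exp survives pooling
(ties break toward smaller distance, then smaller `i`, making pooling
deterministic and idempotent).

Around each representative, the window of inradius `windowSize` (default 5
→ 11×11 = 121 cells) is partitioned by offsets `(di, dj)` (rows grow
downward):

| region     | membership                                  | cells (defaults) |
|------------|---------------------------------------------|------------------|
| peak       | `max(|di|,|dj|) ≤ pw`                       | 25               |
| vertical   | `|di| ≤ pw`, `pw < |dj| ≤ w`                | 30               |
| horizontal | `|dj| ≤ pw`, `pw < |di| ≤ w`                | 30               |
| corner     | `pw < di ≤ w`, `-w ≤ dj < -pw` (bottom-left)| 9                |

The three remaining window corners belong to no test region but do count
toward `all_background` (window minus peak, 96 cells) for the mean filter.
In-band cells with no stored entry enter regions as zeros; cells outside
the matrix or the distance band are truncated — absent, never imputed. A
neighborhood whose truncated background falls below
`min_background_elements` (default 25) is rejected as untestable. An 11×11
window holds 121 elements; when a configuration drops the window below
~250 elements a startup warning notes the reduced power of the rank-sum
tests on sparse data (the default configuration deliberately accepts this
trade-off; its tests remain well calibrated on the dense fixtures below).

A representative is rejected outright when
`mean(all_background) ≥ mean(peak)` (a lone outlier is not a loop);
otherwise the peak is compared against each of the three regions with a
one-sided Wilcoxon rank-sum test (alternative: peak stochastically
greater). The exact null distribution is used when both groups have ≤ 25
values and no ties; otherwise the normal approximation with tie and
continuity correction. A fully tied comparison returns p = 1. All three
p-values must fall below `pValue` (default 0.025), with no multiplicity
correction — each region test carries the significance level individually.

## Synthetic data

The generator draws, for every band entry at distance `d`, a negative
binomial count with mean `decay(d)` and variance `dispersion × mean`
(dispersion default 3; values ≤ 1 are rejected since the NB requires
overdispersion). The decay is a power law with floor,
`decay(d) = c·d^(-α) + 0.1·c` with `c = 80`, `α = 1` and `d` in bins:
mean counts fall from ~28 at 40 kb to ~8 at 2 Mb, emulating the coverage
of a deeply sequenced (several-billion-read) in situ Hi-C experiment at
10 kb — the regime the default thresholds address, in which a handful of
stray counts cannot fake a multi-fold obs/exp enrichment. Loops multiply
the local mean over a `(2·spread+1)²` patch, tapered (full factor inside
the core, square root of the factor on the outermost ring) to reproduce
the focally peaked profile seen in aggregate pileups of real loops;
because planting is multiplicative, the planted obs/exp enrichment is
independent of `c`. Optional uniform sparsity and zeroed "faulty" bin
ranges emulate unmappable regions. Everything is driven by a single seed;
the same seed reproduces the matrix bit for bit.

What the generator does **not** emulate: TADs and compartments (block
structure along the diagonal), distance-correlated noise, copy-number
effects, and balancing artifacts. Passing the planted-recovery tests
therefore demonstrates correctness of the statistical machinery under the
model's own assumptions — not loop-calling accuracy on real tissue data,
where those confounders reduce both precision and recall.

Recovery is scored by greedy one-to-one matching of called to planted
centers within a Chebyshev tolerance (default 2 bins); precision is
defined as 1 when nothing is called.

## Numerical and design choices

* p-values and densities are computed via `scipy.special`
  (`gammaln`, `betainc`); no naive factorials anywhere.
* The rank-sum tests use `scipy.stats.mannwhitneyu`; an exact enumeration
  oracle in the test suite verifies all group sizes ≤ 8.
* The two-proportion z-test is the closed-form pooled statistic; a pooled
  proportion of exactly 0 or 1 returns `(z=0, p=1)` by convention.
* Coordinates are 0-based half-open; anchors are single bins. Only the
  upper triangle is stored; symmetric lookups mirror across the diagonal.
* Loop output is sorted by `(chrom, bin_i, bin_j)` and written with fixed
  formatting, so BEDPE bytes are identical across repeated runs and worker
  counts. Parallelism is one worker per chromosome with an order-stable
  merge.
* Evaluation matching tolerance defaults to 0 bins for loop-set
  intersection (exact anchor bins), adjustable per call.

## Problem sizes

The test-suite and acceptance fixtures use 2,000-bin chromosomes (20 Mb at
10 kb) with a 200-bin band, 20 planted loops at 8× enrichment, and 20
independent null replicates — large enough that every distance in the
2 Mb band carries hundreds of fit observations, while a full pipeline run
completes in roughly a second.

## Known limitations

* Matrix balancing is consumed, never computed; matrices must arrive
  KR/ICE-corrected (or be used raw).
* Only intra-chromosomal loops within the configured band are considered.
* The per-distance models assume within-distance exchangeability; strong
  local structure (TAD corners) can inflate candidate counts, and the
  neighborhood tests are the only guard against it.
* On very sparse matrices the preselection becomes permissive (obs/exp is
  quantised) and the rank-sum tests lose power; loop calls on
  low-coverage data should be treated with caution.
* Multi-resolution (`.mcool`) containers and `.hic` files are not read;
  extract a single-resolution cooler first.
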