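# Methods

## Problem and model

A Hi-C library digested with a restriction enzyme yields, per chromosome,
an n×n symmetric read-pair count matrix `RC` over restriction fragments
(RFs).  The latent quantity of interest is the interaction-frequency matrix
`IF_true` — the contact map one would measure at unbounded sequencing
depth, up to scale.  At RF resolution `RC` is an extremely high-variance
estimator of `IF_true` (most entries are 0 or 1), but neighboring entries
of `IF_true` are strongly correlated, which every estimator here exploits.

### Fragment bias and normalization

Fragment size, GC content, and mappability give each fragment a
multiplicative propensity.  We estimate it from the matrix marginals:
`bias_i = (Σ_j RC_ij / Σ_i'j' RC_i'j') · n`, with all sums over the full
symmetric matrix and `n` the number of fragments with non-zero coverage;
under this convention the mean bias over unmasked fragments is exactly 1,
an identity the tests assert.  Zero-coverage fragments get bias 0 and are
masked but never dropped, so fragment ordinals stay stable.
`nRC_ij = RC_ij/(bias_i·bias_j)`; `denormalize` inverts this exactly.

### Smoothing estimators

* **Fixed binning**: `IF_ij` = mean `nRC` over the `binSize`×`binSize`
  block of the bin pair containing (i, j); a trailing partial bin divides
  by its actual cell count, so a constant matrix is reproduced exactly.
* **KDE**: truncated Gaussian window ±3h; cells falling outside the matrix
  (or masked) are removed from numerator *and* denominator, so constant
  fields are invariant including at edges and corners.
* **Adaptive KDE**: per-cell bandwidth `h_ij` is the smallest integer h
  whose ±3h window of *raw* counts reaches `MinimumCount` (default 100 —
  roughly a 10% standard error on the window mean), capped at `hMax = 64`
  to bound cost; smoothing itself still averages `nRC`.  This deliberate
  raw/normalized asymmetry mirrors the two defining formulas.  Window
  counts come from a summed-area table (exact, O(1) per query, verified
  against brute force).

### MRF estimator

Prior: `log IF_ij ~ N(log MedNeigh_ij, σ²_ij)` where `MedNeigh` is the
median of the ≤8 neighbors (median rather than mean to preserve sharp
domain edges; an even neighbor count takes the mean of the two central
values) and `σ²_ij = α·log MedNeigh_ij` with α = 0.2 — small α means a
tight, smoothing prior; the prior *vanishes* as α → ∞.  Because
`α·log MedNeigh ≤ 0` whenever `MedNeigh ≤ 1`, σ² is floored at 0.01
(log-scale standard deviation 0.1).  Likelihood:
`RC_ij ~ Poisson(IF_ij·bias_i·bias_j)`, or negative-binomial with variance
`v·λ` (v = 1 recovers Poisson exactly; implemented as a dispatch).

Before optimization the `nRC` matrix is scanned for sharp transitions: for
every adjacent row (and column) pair and every sliding 8-cell segment, a
two-sample Kolmogorov-Smirnov statistic scaled by `√(nm/(n+m))` is
computed (the scaling makes the printed acceptance threshold 1.5 > 1
meaningful; two fully separated 8-cell samples score 2.0); segments are
accepted greedily from the strongest statistic down, skipping overlaps,
and held fixed thereafter.  Neighbors across an accepted transition are
excluded from the median.  Ties in `nRC` are handled by evaluating the
ECDF difference only at the end of tie runs.

Optimization is iterated conditional modes: raster sweeps (a seeded
randomized order is available) over all n² cells of the symmetric field,
each cell replaced by the best of a grid of multiplicative rescalings of
its current value — a fine ladder 2^(k/4), k = −4..4, plus coarse jumps
{1/16, 1/4, 4, 16}.  The coarse jumps matter: the adaptive-KDE
initialization can sit orders of magnitude from the optimum in sparse far
fields, and with 0.5–2× moves alone the sweep count triples without
changing the estimate.  Each local update maximizes exactly the terms the
cell participates in (its prior and likelihood plus the priors of its
usable neighbors), so the joint log-probability is non-decreasing by
construction — asserted after every sweep.  Convergence is declared when
the relative joint-log-probability change drops below 1e-3 (≪0.01 nats per
cell; the held-out error is stable from about sweep 3 onward), with a cap
of 50 sweeps; in practice 5–10 sweeps suffice.  Updating both (i, j) and
(j, i) keeps monotonicity exact; the output is symmetrized by averaging,
a numerically negligible correction.  Cells with zero raw counts anywhere
in their `hMax` window are frozen at initialization and flagged.  Output
is normalized by default; `bias_i·bias_j` can be re-applied for raw-scale
comparisons (as in cross-validation).

## Structure callers

**Directionality index.** For fragment i, `A` sums IF with fragments whose
3' end lies within δ = 500 kb upstream, `B` downstream, `E = (A+B)/2`;
`DI = sign(B−A)·((A−E)²/E + (B−E)²/E)` and the scale-normalized
`DI' = sign(B−A)·((A−E)²/E² + (B−E)²/E²)`, bounded by ±2 and much less
depth-sensitive.  Boundaries are strict local extrema of DI' within a
21-RF centered window (51 recommended for 4-cutter digests), ranked by
|DI'|.  Fragments without a complete window are ineligible (a one-sided
window always looks extremal), and fragments within 2 Mb of the chromosome
ends or supplied mask intervals (centromeres) are excluded; synthetic
chromosomes are shorter than 4 Mb, so tests pass `exclusion_bp=0`.  A
fixed-binning comparison mode evaluates only bin-center fragments.

**Loop calling.** `IFnorm` divides each cell by the mean IF of its 10-kb
genomic-distance stratum (stratum means are exactly 1 afterwards — both
divisors use the same 10-kb width).  For each cell, region means are taken
over bp-delimited index rectangles (fragment counts per region vary with
RF sizes): peak P (±p), donut D (±w minus peak and crosses), horizontal/
vertical flanks H/V, lower-left block BL; `score = P/max(D,H,V,BL)`,
masked when any background region is empty.  Candidates with score ≥ 1 are
reduced by eliminating any candidate within 20 kb (Chebyshev distance on
anchor positions) of a higher-scoring candidate — ties broken by smaller
genomic distance, then (i, j) — implemented with a spatial hash so the
flat-field candidate flood stays O(k).  The representative anchor pair is
the IFnorm argmax inside the peak square.  FDR: the matrix is permuted
diagonal-wise (per-offset shuffles preserve fragment distance; one seeded
permutation by default, averaging over k available), re-scored, and null
scores per 10-kb distance bin are fit by a method-of-moments gamma
(bins with <30 scores pool neighbors; a zero-variance null degenerates to
a step function, which makes flat matrices self-consistently report
FDR = 1).  Calls from both scales, (30 kb, 60 kb) and (50 kb, 100 kb),
are merged and sorted by FDR; calls whose bin could not be fit keep a
flag instead of a number.

## Synthetic data and cross-validation

The generator emulates one chromosome: gamma-distributed fragment sizes
(mean 3700 bp — a six-cutter average — shape 4), power-law distance decay
`IF ∝ (d/s̄ + 1)^−γ` with γ = 1 and `s̄` the mean fragment size (measuring
distance in fragment-size units keeps the diagonal from absorbing
essentially all mass, as a raw-bp scale would), 4 TADs (4× within-block
enrichment) subdivided into 12 subTADs (2×), 5 point loops (10×, 3×3
cells, anchors 50–500 kb apart), and log-normal fragment biases
(log-sd 0.4, rescaled to mean 1).  Reads are independent Poisson per
upper-triangle cell with rates normalized to a total depth, default one
read pair per two cells (~0.5 mean counts/cell); input/test splits and
downsampling are exact binomial thinning (`input + test == RC` cell-wise).
Estimators are compared by `SSE = Σ_{i<j} (IF_pred − RC_test)²` after
scaling predictions to the test total.  Everything is deterministic given
the seed.

What the generator does *not* emulate: trans contacts, ligation artifacts,
mappability structure, copy-number variation, or fine-scale biological
variability of the truth field (see limitations).  Passing tests therefore
demonstrate correct algorithmic behavior under a known generative model,
not performance on real libraries.

## Known limitations

* The synthetic truth field is piecewise-smooth by construction, so at
  well-covered cells the MRF posterior rightly tracks the likelihood and
  re-admits some Poisson noise that the heavily averaging adaptive KDE
  suppresses; on this testbed the MRF estimator decisively beats fixed
  binning (~9% lower held-out SSE) but can trail the adaptive KDE by a few
  percent.  On real maps, whose fine-scale structure is signal rather than
  noise, likelihood tracking is the point.
* The bias model is a single marginal coefficient; explicit GC/mappability
  regression and matrix balancing are out of scope.
* Loop FDRs from a single permutation are noisy in sparse distance bins;
  increase `n_permutations` for stable tails.
* ICM finds a local maximum of the joint probability; no uncertainty
  intervals are provided.
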