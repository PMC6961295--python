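# finehic

Restriction-fragment-resolution Hi-C interaction-frequency inference.

Hi-C measures genome-wide DNA-DNA contacts, but at its native resolution —
the restriction fragment (RF) — the read-pair count matrix `RC` is so
sparse that most fragment pairs are observed zero or one times.  Standard
practice throws resolution away by binning at fixed intervals (e.g. 25 kb),
which blurs exactly the promoter/enhancer-scale structure fragment-level
analysis is after.  `finehic` estimates the complete latent
interaction-frequency (IF) matrix at RF resolution by exploiting the strong
dependence between neighboring fragment pairs, and provides RF-resolution
callers for domain (TAD/subTAD) boundaries and chromatin loops, plus a
fully seeded synthetic-data / cross-validation harness.

It is intended for computational genomicists who want fragment-level
contact maps out of existing Hi-C libraries without resequencing.

## Estimators

All estimators consume a raw symmetric count matrix, estimate per-fragment
multiplicative biases `bias_i = (Σ_j RC_ij / Σ_i'j' RC_i'j') · n` (mean 1),
normalize `nRC_ij = RC_ij / (bias_i · bias_j)`, and then smooth:

* **Fixed binning** — block means over runs of `binSize` consecutive RFs.
* **KDE** — truncated (±3h) 2-D Gaussian kernel smoothing of `nRC` at a
  fixed bandwidth `h`.
* **Adaptive KDE** — per-cell bandwidth `h_ij = min{h : Σ RC over the
  (6h+1)² window ≥ MinimumCount}` (default 100), so dense regions keep
  fine resolution; window sums are O(1) via a summed-area table.
* **MRF** — a Markov-random-field maximum a posteriori estimate with a
  log-normal neighborhood prior
  `log IF_ij ~ N(log MedNeigh_ij, α·log MedNeigh_ij)` (α = 0.2) and a
  Poisson (optionally negative-binomial) likelihood
  `RC_ij ~ Poisson(IF_ij · bias_i · bias_j)`, optimized by iterated
  conditional modes from the adaptive-KDE initialization.  Sharp domain
  boundaries are protected by excluding neighbors across Kolmogorov-Smirnov
  detected transitions (scaled statistic ≥ 1.5) from the median.

Downstream, domain boundaries are strict local extrema of the
scale-normalized directionality index
`DI' = sign(B−A)·((A−E)²/E² + (B−E)²/E²)` (δ = 500 kb window, 21-RF
extremum window), and loops are called HiCCUPS-style on the
distance-normalized matrix `IFnorm` with peak/donut/flank scores at scales
(p = 30 kb, w = 60 kb) and (p = 50 kb, w = 100 kb), ranked by an empirical
gamma FDR from a diagonal-wise permuted matrix.

## Worked example

```python
import finehic as fh

params = fh.SimulationParams(n_fragments=500, seed=1)   # ~0.5 reads/cell
sim = fh.simulate_true_if(params)
rc = fh.sample_read_counts(sim.if_true, sim.bias, params.effective_depth, seed=2)
rc_in, rc_test = fh.split_read_counts(rc, 0.8, seed=3)

mrf = fh.MRFSmoother(normalized_output=False).fit(rc_in)
print(mrf.n_sweeps_)                                    # 7
print(round(fh.sse_eval(mrf.if_matrix_, rc_test), 1))   # 10127.0

fixed = fh.FixedBinning(bin_size=2, normalized_output=False).fit(rc_in)
print(round(fh.sse_eval(fixed.if_matrix_, rc_test), 1)) # 11072.2
```

The MRF estimate converges in 7 ICM sweeps and its held-out sum of squared
errors against the 20% test split (10127.0) is ~8% below the best
fixed-binning estimate (11072.2 at two RFs per bin): fragment-level
inference beats binning even at half a read per matrix cell.

The same pipeline is available from the shell:

```bash
finehic simulate --seed 1 --n-fragments 500 --out-prefix sim
finehic estimate --method mrf --fragments sim.fragments.bed --matrix sim.rc.tsv --out mrf.tsv
finehic boundaries --fragments sim.fragments.bed --matrix mrf.tsv --exclusion-bp 0 --out tads.bed
finehic loops --fragments sim.fragments.bed --matrix mrf.tsv --out loops.bedpe
```

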