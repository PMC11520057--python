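# Methods

This note records the statistical model implemented by the package, the
choices made where the method leaves room, and what the synthetic benchmark
does and does not establish.

## The calling problem

A raw (unfiltered) 10x-multiome barcode matrix contains three populations
per modality, visible as modes of the log10 library-size histogram:

1. a **technical-error cluster** at ~1 count (chimeric molecules,
   uncorrected barcode errors);
2. an **ambient cluster** at tens of counts — droplets that captured only
   the "soup" of cell-free RNA/DNA released when nuclei are permeabilized;
3. **nuclei-containing droplets** at thousands of counts and above.

The caller's null hypothesis for any droplet is *all of its counts are
soup*. Calling proceeds per modality and is then aggregated.

## Library-size structure

A three-component Gaussian mixture is fitted to log10 library sizes
(totals < 1 are excluded). The boundary `b` ending the technical-error
cluster is the count at which the technical and ambient components carry
equal posterior responsibility (their weighted densities cross); `l` ending
the ambient cluster is `10^(m2 + k·s2)` with `k = 1.5` for RNA and `k = 2`
for ATAC (both configurable, as is a manual `b`/`l` override).

Numerical choices:

* Library sizes are integers, so the low end of the log axis consists of
  discrete spikes at 1, 2, 3 counts. An unregularized EM happily collapses
  two components onto neighbouring spikes (that *is* the likelihood
  optimum). Component variances are therefore floored at `0.1` log10 units
  (`reg_covar = 0.01`) — narrower than any real library-size cluster — and
  the fit tries a fixed sequence of initializations (range-spanning
  linspace, 10/50/90th percentiles, then seeded random restarts), accepting
  the first converged fit whose sorted means are ≥ 0.3 log10 units apart
  and that yields a valid `b ≤ l`.
* The density crossing is located on a 10,000-point grid between the two
  lowest means and refined by Brent bisection to 1e-6 log10 units; a closed
  form exists only for equal variances.

## Soup profile (Simple Good-Turing)

Per modality, the counts of all droplets with `b ≤ t ≤ l` are pooled into
per-feature sums, and Gale–Sampson Simple Good-Turing converts them into
posterior expected proportions: Turing estimates while they differ from the
linear (log Z vs log r) smoothing by more than 1.96 standard deviations,
the smoothed estimate afterwards. The unseen mass `n1/N` is divided
uniformly over features never observed in the soup, so every feature keeps
strictly positive probability and no droplet can have likelihood zero under
the null. If there are no singletons, or fewer than two distinct counts,
the estimator falls back to add-0.1-pseudocount proportions (logged). The
final vector is renormalized to sum exactly to 1. Note that smoothing makes
the proportions mildly dependent on the overall count scale; duplicating
every soup droplet reproduces the proportions only approximately.

## Dirichlet-multinomial null and Monte-Carlo testing

Droplet counts under the null follow a Dirichlet-multinomial: capture is a
Dirichlet draw with concentration `α·p` around the soup proportions `p`,
sequencing a multinomial of the droplet total `t`. The log-likelihood is
evaluated entirely through log-gamma functions; zero-count features
contribute nothing, so sparse columns are cheap.

`α` is the maximum-likelihood over-dispersion of the soup droplets
themselves (smaller `α` = soupier droplets vary more in composition). The
MLE maximizes the summed log-likelihood over `α ∈ [0.01, 10^4]` on the log
scale — a 30-point grid followed by bounded scalar refinement (relative
tolerance 1e-4). Data with no over-dispersion push `α̂` to the upper bound,
which is reported with a warning. For speed the MLE uses at most 2,000
(seeded, subsampled) soup droplets; sampling noise on `α̂` is second-order.

Every droplet with `t > b` is tested. Its observed log-likelihood is ranked
among `M` simulated null log-likelihoods at the same total, giving
`P = (M_c + 1)/(M + 1)` where `M_c` counts simulations with
`log L' ≤ log L_obs + 1e-8` (ties count as extreme — conservative). The
default is `M = 10,000` per modality (resolution 1e-4, matching the 0.1%
calling threshold); ATAC is independently configurable because its smaller
dynamic range can require more iterations. The RNA and ATAC streams are
seeded `seed` and `seed + 1`.

**Simulation strategy.** The Dirichlet-multinomial is exchangeable and
closed under prefix marginalization: conditionally on one Dirichlet draw θ,
the first `t` categorical draws of a sequence are an exact DM(t) sample.
Each of the `M` iterations therefore draws θ once, then extends a single
categorical sequence across the sorted unique totals, updating the
log-likelihood in O(1) per added count and recording it at each checkpoint
total. This makes the cost `O(M · t_max)` instead of `O(M · N)` per
distinct total, at the price of sharing draws across totals within an
iteration (p-values stay exactly valid marginally; the same sharing is used
by the established RNA-only implementation of this test). Sampling uses
Vose's alias method inside a compiled (numba) kernel, with a pure-numpy
fallback; a test cross-checks the shared-draw sampler against brute-force
per-total sampling.

## Aggregation, FDR control and retention lines

The two modality p-values are combined by their arithmetic mean, which
controls for arbitrary dependence between modalities. A barcode tested in
only one modality contributes `p = 1` for the missing one (conservative; a
flag switches to averaging only the tested modalities). The optional
multiplier 2 turns the mean into a p-value valid at any level; the default
multiplier 1 reproduces the published rule.

Benjamini–Hochberg runs over the universe of barcodes tested in at least
one modality (technical-error barcodes never enter). `FDR_RNA` is BH
applied to the RNA p-values over the RNA-tested subset — thresholding it
reproduces the RNA-only (EmptyDrops-style) caller. Overrides act on the
adjusted values, in the order the rule is stated: droplets below the
**lower retention line** (parallel to the k-means line, through
`(log10 l_A, log10 l_R)`) get FDR 1; with `retain_large`, droplets above
the **upper line** (2/3 of the way from the k-means line to the 99th
percentile of signed offsets) get FDR 0. The k-means line itself is the
perpendicular bisector of the two k = 2 centroids in
`(log10 t_A, log10 t_R)` space, fitted on barcodes above both `b`
boundaries (10 seeded restarts). "Top percentile of the distribution" is
interpreted as the 99th percentile of the droplets' signed perpendicular
offsets from the k-means line — the only line-compatible scalar summary —
and is configurable. `retain_large` defaults to off.

A consequence worth knowing: with `M` iterations the smallest attainable
aggregated p-value is `1/(M+1)`, so BH at threshold `q` can only call a
block of `k` floor-level barcodes out of `m` tested when
`m/(k·(M+1)) ≤ q`. Benchmarks that test many ambient droplets therefore
need `M` large enough for the discreteness floor, which is why the
defaults below differ between benchmark designs.

## Synthetic data

The generator emulates the structure above rather than any particular
tissue: a sparse symmetric-Dirichlet soup profile per modality
(concentration 0.1 over 1,000 genes / 2,000 peaks); cell-type profiles
mixing the soup with an independent sparse Dirichlet component (divergence
0.7 — distinct cell types whose composition still shares the soup's
high-abundance features); technical barcodes with Poisson(1) totals
scattered uniformly over features; ambient droplets as DM draws from the
soup at `α = 50` with log-normal totals (RNA mode ≈ 90 counts, the typical
ambient mode of a raw run; the ATAC ambient cluster sits closer to the
technical cluster, mode ≈ 50); nuclei as DM draws from their cell-type
profile with totals around 10^3.9 (RNA) and 10^4.0 (ATAC). Benchmark
perturbations follow the published constructions: binomial thinning (20%
RNA / 20% ATAC) plus per-cell scrambling of 10% of nonzero features for
the "novel small cell type", and amplified empties multiplying ambient
count vectors by U{2..10} (RNA) × U{2..40} (ATAC).

Preset designs:

* **default** — 8,000 technical / 2,000 ambient / 500 + 200 nuclei / 200
  amplified empties: the ROC comparison design at desk scale.
* **fdr-benchmark** — 18,500 technical / 1,500 ambient (the ~9:1 ratio of
  raw barcode lists) / 2,000 untouched nuclei, no amplified empties: pure
  null draws plus strong signal, for measuring the empirical
  false-discovery proportion at `M = 2,000`.
* **tiny-cells** — 6,000 technical / 28,000 ambient / 2,000 + 2,000 nuclei
  downsampled to 6% RNA / 2% ATAC without scrambling, at shallower depths
  (ambient modes ≈ 30/25 counts, nuclei 10^3.7/10^4.1). The 14:1
  ambient:small ratio mirrors real runs and is what keeps the fitted
  ambient component tight — at comparable weights the EM optimum absorbs
  the small group and the lower retention line would swallow it. The BH
  floor arithmetic above then requires `M ≈ 9,000` for calling at 0.1%.

What passing these benchmarks does *not* show: robustness to feature
spaces 10–100× larger, to chimera/index-hopping structure beyond a count
signature, to doublets, to fragment-level ATAC effects (FRiP), or to real
biological cell-type hierarchies; real-data quality control remains a
downstream step.

## Known limitations

* The three-component mixture assumes three separated library-size modes;
  samples whose ambient and nucleus clusters merge need manual `b`/`l`.
* Scenarios where a real small population is comparable in number to the
  ambient cluster will see that population absorbed into the ambient
  component estimate (see above); the lower line then discards it.
* The soup profile includes the tested droplet's own counts (no
  leave-one-out correction), as in the published procedure.
* Amplified-empty-style artefacts — exact integer rescalings of soup — are
  genuinely over-dispersed relative to the null at their total and can be
  assigned small p-values when `α̂` is large.
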