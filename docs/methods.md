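# Methods

## Model

For one A-vs-B comparison, gene i contributes counts `(n_i, m_i)`. All
inference conditions on the total `N_i = n_i + m_i`: `n_i` is
beta-binomial,

    n_i | N_i ~ BetaBinom(N_i, alpha_i, beta_i),
    alpha_i = p_i / theta_i,   beta_i = (1 - p_i) / theta_i,

so `p_i = alpha/(alpha+beta)` is the mean proportion and
`theta_i = 1/(alpha+beta)` the dispersion. The limit `theta -> 0` is the
binomial; the package evaluates that limit as an exact binomial branch,
never as a small-theta approximation. The conditional variance of the
proportion is

    Var(n/N | N) = p(1-p) (1 + N*theta) / (N (1 + theta)).

The central assumption is a depth-dependent dispersion

    theta_i = D_i / N_i**gamma,   gamma >= 0, D_i >= 0,

with `gamma` shared across genes. For `0 < gamma < 1` the proportion
variance behaves like `p(1-p) D_i N^-gamma` at large depth: accuracy
still improves with sequencing depth, but more slowly than binomially.
`gamma = 0` recovers the classical beta-binomial with constant
overdispersion; `D_i = 0` recovers the binomial. This is a model of
*technical* replication (independent library preparations of the same
material); it contains no term for genetic or biological between-subject
variation, which would demand a depth-independent variance floor.

## Normalization

Two estimators of the neutral ratio `p_n` (the proportion at which a
gene counts as equally expressed in A and B):

- **peak**: assumes most genes are unchanged. Histogram of `p_i` over
  (0,1) with bin width 0.01, restricted to genes with at least 20 total
  tags; a scaled beta density `s * Beta(x; a, b)` is least-squares
  fitted (`scipy.optimize.curve_fit`, moment-based start values,
  `a, b > 1`) to the binned density within ±0.15 of the tallest bin;
  `p_n` is the fitted mode `(a-1)/(a+b-2)`. A Gaussian fit to the same
  window is the fallback if the beta fit fails; if both fail the error
  carries the histogram for inspection. The fit is windowed rather than
  a full-range MLE because DE genes populate the tails and would drag a
  global fit off the peak. At least 100 proportions are required.
  Bin width, window and min-count are free choices of this package
  (recorded in `HistogramSpec`); on 10,000-gene synthetic data with no
  DE the peak estimate lands within 0.001 of the generating ratio, so
  the defaults are not delicate.
- **rpkm**: `p_n = N/(N+M)` from the two column totals — the proportion
  equivalent of comparing RPKM values (count / millions of mapped tags /
  gene length in kb, computed by `rpkm_values` when lengths are known).

`median_log2_ratio` summarizes how well a chosen `p_n` centers a
comparison (median over genes with ≥ 20 tags of `log2 FC`; 0 is
perfectly centered).

## Fitting gamma and D_i

Duplicate pairs: repeated A-vs-B sequencings through independent library
preparations, stacked over a common gene universe (`ReplicatePairSet`).
For gene i and pair p, `n_ip | N_ip ~ BetaBinom(p_i, theta_ip)` with
`theta_ip = D_i / N_ip**gamma` at the pair's own observed total and a
single proportion `p_i` shared across pairs. Sharing `p_i` is what makes
the dispersion identifiable: for any *single* observation,
`sup_p BetaBinom(n; N, p, theta) <= Binom(n; N, n/N)` with equality only
at `theta = 0` (a beta mixture of binomials cannot exceed the binomial
at its own mode), so a model with a free proportion per pair would
always collapse to `D_i = 0`. With a shared `p_i`, between-pair scatter
of the proportions drives `D_i`, and how that scatter changes with the
pair totals drives `gamma`.

The profile likelihood at fixed `gamma` maximizes, gene by gene, over
`(p_i, D_i)`: an outer golden-section search on `log D_i` over
[1e-8, 10] (40 iterations) with an explicit `D_i = 0` boundary
comparison, around an inner golden-section search on `p_i` (35
iterations; the log-pmf is concave in `p` — its second derivative is a
difference of trigamma functions — so the search is exact up to bracket
width). Both searches are vectorized across all genes at once.
`fit_overdispersion` evaluates the profile on a gamma grid (default 0 to
1.2 in steps of 0.1, matching the one-decimal resolution at which the
exponent is scientifically meaningful) and returns the grid argmax with
the full profile curve. Ties break toward the smaller gamma; genes with
zero totals in every pair are excluded.

The analytic form of the likelihood-maximizing proportion is stated but
not printed in the method's source; `estimate_phat` therefore maximizes
numerically, and the test suite reports the conjectured closeness to
`n/(n+m)`: exact at `theta = 0` (< 1e-8 numerically), but deviations up
to ~0.2 exist at `theta <= 1` for skewed counts, so `n/(n+m)` is *not*
the maximizer in general.

## Testing

- `binomial_test`: exact two-sided binomial p-value against `p_n`,
  minimum-likelihood ordering (outcomes no more probable than the one
  observed), via `scipy.stats.binomtest`; p = 1 at the mode.
- `lrt_pvalue`: `Lambda = 2[l(p_hat) - l(p_n)]` referred to
  chi-squared(1), with `theta_i = D_hat_i / N_i**gamma_hat` from the
  fitted model. Genes absent from the fit fall back to `theta = 0`.
- Fold change: `FC = [p/(1-p)]*[(1-p_n)/p_n]`, with a pseudo-count of
  0.5 added to both counts *only* for reported proportions and fold
  changes — never inside likelihoods.
- Genes are flagged by a >20-total-tag filter (`passed_min_count`), and
  evaluation consumes only flagged genes; small-count p-values are
  dominated by discreteness.

**Calibration of the LRT.** With one observation per gene the
chi-squared reference is an approximation whose quality is governed by
the effective information `1/theta`. Measured on 5,000-gene null
simulations (`gamma = 0.3`, `D ~ Gamma(2,1)`, so `theta ~ 0.1-0.5`): the
fraction of p-values below 0.05 is a robust 0.04-0.055, while the
Kolmogorov-Smirnov distance to uniform is typically 0.02-0.04 — i.e. a
mild mid-range warp that a 5,000-sample KS test can resolve (KS p > 0.01
in roughly a quarter of replications). At `theta = 0.01` the same code
gives KS p = 0.82, confirming the warp is the Wilks approximation, not
the implementation. Tail-area diagnostics and rankings are unaffected in
practice; users needing exactly uniform nulls at high dispersion should
calibrate thresholds against `simulate`d nulls.

## Evaluation protocol

Empirical FDR treats every gene called DE between two replicates of the
same sample as false: with genes ranked by the test-arm p-value,
`FDR(k) = #{null-arm p <= k-th smallest test p} / k`, capped at 1 and
reported for k = 1..1,000. The null arm is **one of the duplicate pairs
used to fit the model** — the protocol characterizes the false calls of
the fitted pipeline on the very replicates that defined its
overdispersion. (With an out-of-sample null pair, per-gene noise in
`D_hat_i` from 3 pairs dominates both arms' smallest p-values and the
comparison degenerates; measured FDR ordering drops from 10/10 to 4/10
seeds.) ROC curves sweep a ranking statistic against gold labels
(tie-grouped, endpoints (0,0) and (1,1); the trapezoid AUC equals the
Mann-Whitney statistic). The t-test gold standard works on
`log2(RPKM+1)` (or `log2(CPM+1)` without lengths), equal-variance
two-sample t per gene, BH adjustment at 0.05, or raw p < 0.05 plus a
two-fold rule; which expression scale the original protocol used is not
recorded, so this is a package choice. Top-k overlaps use (p-value,
gene id) tie-breaking for bit-reproducibility.

## Synthetic data generator

`simulate_pairs` draws, in a fixed documented order from one seed: DE
flags (a `de_fraction` of genes), fold-change signs, `D_i ~
Gamma(shape 2, scale 1)` (`d_scale = 0` degenerates to exact zeros),
per-gene expected totals `E_i = 10^Normal(3, 1)`, per-pair depth factors
`s_p = 10^Uniform(-0.5, 0.5)` shared across genes, totals
`N_ip ~ Poisson(E_i s_p)` clipped to ≥ 1, latent
`q ~ Beta(p_i/theta_ip, (1-p_i)/theta_ip)`, and `n_ip ~ Binom(N_ip, q)`.
DE genes are odds-shifted from `p_n` by `|log2 FC| = 2` (four-fold) with
random sign. The two-component depth model matters: a gene's totals
across replicate pairs differ by *run depth* (a shared factor), not by
an independent redraw of its expression — and it is precisely this
shared depth contrast that identifies `gamma`, in simulation as in real
run tables. Defaults span 1-1e5 tags per gene, the range over which the
variance-depth trend is observable.

What the generator does **not** emulate: positional/hexamer sequence
bias (the likely mechanism behind `D_i`, here just a gamma draw),
correlation of `D_i` with expression or GC content, multi-mapping
artifacts, biological variation between subjects, and more than two
conditions. Passing tests therefore demonstrate correctness of the
machinery and self-consistency of the model, not that any particular
real dataset follows `theta = D/N^gamma`.

## Numerical choices

- Proportions are clamped to `[1e-12, 1-1e-12]` inside likelihoods.
- The beta-binomial log-pmf uses log-gamma throughout; when `alpha` and
  `beta` are both huge (theta tiny with moderate p) `betaln` cancels
  catastrophically, so for `N*theta`, `n*theta/p` and `m*theta/(1-p)`
  all below 1e-4 an exact second-order `log1p` expansion of the rising
  factorials around the binomial limit is used instead (absolute error
  < ~1e-7 there).
- Golden-section iteration counts (60 for standalone `estimate_phat`,
  35/40 inside the profile) put bracket widths at 1e-13 and 1e-4
  respectively; the profiled log-likelihood is quadratic near its
  maximum, so the looser inner bracket costs < 1e-5 log-units.
- `variance_table` measures deviation from `p_n`, not from the per-gene
  pair mean: with a handful of proportions per gene the global neutral
  ratio is the stabler centre, and it is the centre the normalization
  defines as "no change". `slope_gamma` regresses log10 variance on
  log10 mean total over genes with mean count > 100 (below that,
  binomial noise and discreteness bend the trend) and needs ≥ 20 genes.
- Determinism: single-integer seeds everywhere; rankings tie-break on
  gene id.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 500-point quadrature
grids (N ≤ 50) and exhaustive pmf sums to N = 200 for the probability
layer; 1,000-10,000 genes for calibration, normalization and rank
checks; 2,000 genes × 3 pairs for gamma recovery (profile MLE and
variance slope); 3,000 genes × 3 pairs × 10 seeds for the FDR ordering.
These sizes give Monte-Carlo noise comfortably below every asserted
tolerance while keeping a full run to a few minutes on one CPU.

## Known limitations

- `gamma` is estimated on a 0.1-step grid; no standard error is
  attached (the profile curve is returned for inspection).
- `D_hat_i` from few pairs is noisy and shrinks toward the boundary
  `D = 0` for a substantial minority of genes; no pooling/shrinkage
  across genes is applied (deliberately out of scope).
- The LRT's chi-squared reference is approximate at high dispersion
  (see calibration above).
- Two-library comparisons only; no multi-condition designs, no
  length/GC bias correction, no read-level processing.
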