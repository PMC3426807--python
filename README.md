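# depthbb

Depth-dependent beta-binomial testing of differential gene expression
between two RNA-Seq libraries.

## The problem

When the same biological sample is sequenced twice through *independent
library preparations*, the scatter of per-gene counts is larger than the
binomial fluctuation implied by finite sequencing depth — yet it still
shrinks as depth grows. A plain binomial two-library test therefore calls
thousands of false positives, while a classical beta-binomial (whose
extra variance never decays) wastes the benefit of deeper sequencing.

`depthbb` models the count `n_i` a gene receives in library A,
conditional on its total `N_i = n_i + m_i` across both libraries, as
beta-binomial with mean proportion `p` and dispersion

```
theta_i = D_i / N_i**gamma        (alpha = p/theta, beta = (1-p)/theta)
```

with one depth exponent `gamma >= 0` shared by all genes and a per-gene
scale `D_i >= 0`. `gamma = 0` is the classical beta-binomial;
`0 < gamma < 1` makes the variance of the proportion `p_i = n_i/N_i`
decay like `N**-gamma` — slower than the binomial's `1/N`, but still
vanishing with depth, which is what replicate libraries empirically show.

The package provides:

- **normalization** — the neutral ratio `p_n` (the proportion meaning
  "no change") by a beta fit to the tallest peak of the proportion
  histogram, or by total-count (RPKM-equivalent) ratio `N/(N+M)`;
- **model** — the beta-binomial log-pmf in the `(p, theta)`
  parameterization, exact two-sided binomial test, variance formulas;
- **inference** — profile maximum likelihood for `(gamma, D_i)` from
  duplicate library pairs, a 1-df chi-squared likelihood-ratio test of
  each gene against `p_n`, odds-ratio fold changes
  `FC = [p/(1-p)]*[(1-p_n)/p_n]` with pseudo-counts, the log-log
  variance-vs-depth slope estimate of `gamma`, and a t-test gold
  standard with Benjamini–Hochberg adjustment;
- **evaluation** — empirical FDR from same-sample replicate nulls, ROC,
  p-value calibration diagnostics, top-k overlap between methods;
- **simulate** — a seeded generator of paired counts under the same
  model, so every stage is testable with known truth.

## Worked example

Simulate three duplicate pairs of a 2,000-gene comparison with
overdispersion exponent 0.5 and 10% four-fold DE genes, fit the model,
and test one pair:

```
$ cat cfg.yaml
n_genes: 2000
n_pairs: 3
gamma_true: 0.5
de_fraction: 0.1
seed: 7

$ depthbb simulate --config cfg.yaml --out-dir sim
wrote sim/counts.tsv (2000 genes, 3 pairs)

$ depthbb fit --counts sim/counts.tsv --sample-sheet sim/sample_sheet.tsv \
    --pairs pair1_A:pair1_B,pair2_A:pair2_B,pair3_A:pair3_B --out model.json
gamma = 0.5, loglik = -31544.7984

$ depthbb test --counts sim/counts.tsv --sample-sheet sim/sample_sheet.tsv \
    --run-a pair1_A --run-b pair1_B --method betabinom --model model.json \
    --pn peak --out results_test.tsv
wrote 2000 rows to results_test.tsv (p_n = 0.498984)

$ head -3 results_test.tsv
gene_id n       m       p_hat   fold_change     p_value method  passed_min_count
g0001   4255    2707    0.611158983197  1.57814543563   0.199008635033  betabinom       1
g0002   7339    9115    0.446034639927  0.808445733512  0.00111695563177        betabinom       1
```

The fit recovers the generating exponent (`gamma = 0.5`), the
peak-of-histogram neutral ratio lands on the generating value 0.5 to
three decimals, and each output row carries the gene's counts, its
pseudo-counted proportion, the odds-ratio fold change against `p_n`, the
likelihood-ratio p-value, and whether the gene passed the >20-tag
filter. Note `g0002`: nearly 16,500 tags and a p-value of only 1.1e-3 —
under a binomial test the same counts would be astronomically
significant (p ~ 1e-44), which is exactly the overdispersion the model
absorbs.

`depthbb evaluate` then turns a same-sample comparison plus a
sample-vs-control comparison into an empirical FDR curve, and optional
gold labels into an ROC.

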