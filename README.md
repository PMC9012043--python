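# clrda

Differential abundance analysis of microbiome compositional count data via
CLR-transformed linear models with mode-based compositional-bias correction.

## The problem

Sequencing experiments observe only *relative* abundances: the library size
`N_s` of a sample says nothing about total microbial load. When some taxa
truly change with a covariate of interest, the relative abundances of all
other taxa shift mechanically in the opposite direction — the
*compositional effect* — and naive per-taxon tests produce large numbers of
false discoveries.

## The method

Let `Y_is` be the read count of taxon `i` in sample `s`, with log-linear
absolute abundances `log X_is = u_s α_i + (1, c_s')β_i + ε_is` where `u_s`
is the covariate of interest and `c_s` are adjustment covariates. The
centered log-ratio (CLR) transform

```
W_is = log{ Y_is / (Π_j Y_js)^(1/m) }
```

satisfies the linear model `W_is = u_s(α_i − ᾱ) + … ` with
`ᾱ = m⁻¹ Σ α_i`: ordinary least squares per taxon estimates each effect
*shifted by the same unknown constant*. Under sparse differential signal,
most true `α_i` are 0, so the scaled coefficients `√n α̃_i` pile up at
`−√n ᾱ`, and the shift is identified as the argmax of their kernel density
estimate:

```
−α̃ = mode({√n α̃_i}) / √n ,    α̂_i = α̃_i + α̃ .
```

Bias-corrected statistics `T_i = √n α̂_i / √(ρ̂ σ̂_i²)` are referred to a
t-distribution with `n − d − 2` degrees of freedom and the
Benjamini–Hochberg procedure controls the FDR. For correlated samples
(paired designs, replicates, longitudinal studies) the per-taxon fits are
random-intercept linear mixed models (REML) with Satterthwaite degrees of
freedom, with the identical bias correction.

Zeros are handled by a pseudo-count (0.5), by library-size-proportional
imputation, or adaptively: imputation is used only when the library size is
associated with the covariate of interest (slope test p < 0.1), which
protects against library-size confounding.

The package also includes a full synthetic-data framework (log-normal,
gamma, and negative-binomial abundance models, zero inflation, correlated
taxa, confounded designs, mixed-effect sampling) with ground-truth labels,
and empirical FDR/TPR scoring over replicate simulations.

## Worked example

```python
from clrda import SimScenario, simulate, run_fixed, RunConfig, score_run

ds = simulate(SimScenario(seed=1))           # m=500 taxa, n=200 samples, 5% differential
res = run_fixed(ds.counts, ds.samples, RunConfig(fdr_level=0.05))
print(res.table.head(3)[["taxon", "alpha_debiased", "log2fc", "pvalue", "padj"]])
print(score_run(res.table, ds.truth, 0.05))
```

prints (abridged)

```
       taxon  alpha_debiased    log2fc        pvalue          padj
0  taxon0093        1.396189  2.014274  3.344358e-20  1.571848e-17
1  taxon0007        1.036276  1.495030  2.619914e-14  6.156799e-12
2  taxon0136        0.834372  1.203745  2.503134e-11  3.177739e-09
RunMetrics(n_rejected=23, n_true_pos=19, n_false_pos=4, fdp=0.174, tpr=0.731)
```

`taxon0093` is recovered with a debiased effect of 1.40 on the natural-log
scale (a 4-fold change, `log2fc ≈ 2.0`); 23 taxa are significant at 5% FDR
of which 19 are truly differential in this run.

The same pipeline is available from the shell:

```
clrda simulate --setting S0 --seed 1 --out sim/
clrda run --counts sim/counts.tsv --metadata sim/metadata.tsv --var u --out results.tsv
clrda evaluate --setting S0 --runs 100 --out metrics.tsv
```

Pass `--group SUBJECT` to `clrda run` for the mixed-effects path.

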