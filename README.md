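# iusmmt

Gene-centric mediation analysis for epigenomic survival studies: does
DNA methylation influence patient survival *through* the expression of
the gene it sits in?

For each gene the data are a block of `K` CpG methylation M-values
**M** (the multivariate exposure), one expression level `G` (the
mediator), a right-censored survival outcome `(t, d)` and clinical
covariates **X**.  A mediation effect exists only when both paths are
real — methylation→expression **and** expression→survival — so the null
of "no mediation" is composite: it is the union of three states
(α≠0, β=0), (α=0, β≠0), (α=0, β=0).

## The method

Two stage tests are run per gene:

1. **Methylation → expression** (`test_methylation_expression`):
   linear mixed model `G = Mα + Xw₂ + ε` with `α_k ~ N(0, τ₂)`;
   H₀: τ₂ = 0 is tested with the linear-kernel variance-component score
   statistic `Q = rᵀMMᵀr / σ̂²` whose null is a mixture of χ²₁
   variables (exact tail probability by numerical inversion of the
   characteristic function, moment-matching fallback).  Gives `P_α`.
2. **Expression → survival** (`fit_coxlmm` + `wald_test_beta`):
   Cox mixed-effects model
   `log h(t)/h₀(t) = Mγ^DE + Gβ + Xw₃` with ridge-penalized direct
   effects `γ^DE_k ~ N(0, τ₃)` (τ₃ chosen by a Laplace-approximate
   integrated partial likelihood); H₀: β = 0 by Wald.  Gives `P_β`.

The naive intersection-union test (IUT) takes `P_max = max(P_α, P_β)`
as the mediation p-value.  It is valid but conservative, because under
the composite null `P_max` is far from uniform.  The mixture-adjusted
test (IUSMMT) estimates the actual null CDF of `P_max`,

    Pr(P_max ≤ u | H₀) ∝ κ₁₀·p₁₀(u)·u + κ₀₁·p₀₁(u)·u + κ₀₀·u²,

with the component proportions `κ` estimated genome-wide by Storey-type
π₀ estimators and the stage-test power curves `p₁₀, p₀₁` by Grenander
(least-concave-majorant) deconvolution of the pooled p-value CDFs.
Evaluating this CDF at each gene's `P_max` yields an adjusted
significance value — never larger than `P_max`, so every IUT discovery
is kept — on which Benjamini–Hochberg FDR or Bonferroni FWER control is
applied.  A kernel-machine Cox score test of the total methylation
effect, a direct-effect test, and a reverse multivariate score test
(flagging "passenger" methylation driven by expression) complete the
pipeline.

## Worked example

`examples/02_genome_scan_with_mixture_null.py` simulates a
sparse-alternative study (500 genes, 10% true mediators, n=250,
τ₂=0.02, β=0.2) and scans it:

```
estimated null proportions: k00=0.682 k01=0.146 k10=0.142 k11=0.030   (truth: 0.90/0/0/0.10)
true mediators: 49 of 500 genes
IUSMMT discoveries (FDR 0.05): 25 (25 true)
IUT discoveries    (FDR 0.05): 5 (5 true)
```

The mixture calibration recovers five times as many true mediators as
the naive max-P rule at the same FDR level, with no false positives
here.  The other example scripts cover the single-gene stage tests
(`01`), the anatomy of the mixture-null calibration (`03`) and the
reverse passenger screen (`04`).

## Command line

```bash
iusmmt run --methylation M.tsv --expression E.tsv --clinical C.tsv \
           --annotation genes.bed --control fdr --level 0.05 --out results.tsv
iusmmt simulate --scenario sparse_alternative --n 400 --genes 2000 --out simdir/
iusmmt experiment --config exp.yaml
```

Matrices are TSV (first column feature id, header sample ids); the
clinical table needs `sample`, `time`, `status` plus covariate columns;
the annotation is a gene BED (0-based half-open, 4th column gene id,
6th strand).  CpG coordinates are read from methylation row ids of the
form `chrom:pos` or `chrom:pos:name`; CpGs within the gene body plus a
strand-aware 500 bp promoter window (configurable) are assigned to the
gene.

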