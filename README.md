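# offsetdge

Normalization-aware differential expression for RNA-seq from tissue that is
globally accumulating RNA — such as skeletal muscle under resistance
training.

## The problem

Bulk RNA-seq libraries are usually prepared from a **fixed mass of total
RNA** (e.g. 1000 ng). When an intervention raises total RNA per mg of
tissue — as weeks of training do in muscle, through ribosomal biogenesis —
each library silently represents **less tissue** than before, and more so
in the condition that responds more strongly. At the same time the mRNA
fraction of the input rises, so library sizes grow. Standard analyses that
compare counts per library (or per effective library size) are then
answering "per unit total RNA" questions while the biology of interest is
"per unit tissue", and contrasts between conditions can even flip sign —
a counterintuitive *reverse dose-dependency* in which the harder-trained
condition appears down-regulated.

`offsetdge` is for analysts of within-participant (e.g. contralateral
two-leg) training designs who need to compare normalization strategies and
obtain per-tissue inference. It provides:

* per-gene **negative-binomial GLMMs** with participant random intercepts,
  fitted by a fast Laplace approximation (adaptive Gauss–Hermite quadrature
  retained as a high-accuracy cross-check), under three strategies:
  **naive** (raw counts), **effective library size** (TMM-scaled depth as a
  covariate) and **tissue offset** (additionally `ln` tissue mass as a model
  offset);
* **TMM** composition factors and median-scaled effective library sizes;
* Wald tests with per-coefficient Benjamini–Hochberg FDR, a boundary-correct
  NB-vs-Poisson likelihood-ratio test, and simulation-based randomized
  quantile residual diagnostics;
* enrichment by the **CERNO** rank test on **MSD** (minimum significant
  difference) rankings, **preranked GSEA**, and hypergeometric **ORA**;
* quantifier-validation metrics (myosin heavy chain family profiling
  against fiber-type protein fractions, paired-replicate log differences);
* a **synthetic-data generator** that reproduces the fixed-input confound
  with recorded ground truth, and a pipeline/CLI tying it all together.

## The model

For gene *g*, counts *y<sub>s</sub>* in sample *s* of participant *i*:

```
y_s | u_i ~ NB(mu_s, theta)          Var = mu + mu^2/theta
ln mu_s  = x_s' beta + beta_L * ln(L_s) + o_s + u_i,   u_i ~ N(0, sigma_u^2)
```

where `x_s` carries treatment-coded time and time×volume-condition
(`setsmultiple`) terms, `L_s` is the median-scaled effective library size
(total reads × TMM factor; omitted in the naive strategy), and the offset
`o_s = ln(tissue_mg_s)` (tissue-offset strategy only) turns the modelled
rate into expression **per mg of tissue**. The marginal likelihood is
maximised over `(beta, ln theta, ln sigma_u)`; Wald z-statistics use the
outer numerical Hessian. A gene is differentially expressed when
|log2FC| > 0.5 (strict) and the BH-adjusted p-value < 0.05, adjusted per
model and coefficient.

For enrichment, MSD is the lower 95% CI bound of a positive log2FC (the
negated upper bound for a negative one), so MSD > 0 exactly when the CI
excludes zero; CERNO aggregates set ranks as `F = -2 Σ ln(R/N) ~ chi2(2n1)`
with a Mann–Whitney AUC.

## Worked example

`examples/compare_normalization_strategies.py` simulates the
null-amplification scenario — both legs amplify per-tissue mRNA equally,
but the multiple-set leg accumulates more total RNA, so its libraries
contain ~19% less tissue versus ~13% in the single-set leg — and fits all
three strategies (400 genes, 25 participants):

```
naive                               timew2pre:setsmultiple  median log2FC=-0.1619
lib_size_normalized                 timew2pre:setsmultiple  median log2FC=-0.0015
tissue_offset_lib_size_normalized   timew2pre:setsmultiple  median log2FC=+0.1072
```

No gene truly differs between legs per unit tissue, yet the naive model
reports a −0.16 log2 median volume effect — the reverse dose-dependency
created purely by the fixed RNA input. The library-size covariate removes
the depth signal (median ≈ 0); adding the tissue offset shifts the whole
distribution towards the multiple-set leg by the between-leg total-RNA
ratio (ln 1.24/1.15 ≈ +0.11 log2). The other examples show the generator's
tissue/library-size dynamics, recovery of a planted volume-responsive gene
module by all three enrichment tests, and the quantifier-validation
metrics.

A thin CLI mirrors the library:

```sh
offsetdge simulate --scenario volume-response --seed 1 --genes 500
offsetdge fit --counts sim_counts.tsv --design sim_design.tsv --strategy tissue-offset
offsetdge run-all --config pipeline.yaml
```

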