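# lncpair

Expression-level-free prognostic signatures from within-sample ranked lncRNA
pairs, for survival analysis of bulk tumor transcriptomes.

## The problem

Prognostic gene-expression signatures usually require cross-sample
normalization before a risk score can be compared between patients — a real
obstacle when cohorts come from different platforms or batches. A
rank-based alternative replaces each gene's expression level with
**within-sample pair indicators**: for a gene pair (A, B) and patient *s*,

```
C_s(A, B) = 1  if  x_s(A) > x_s(B),   else 0.
```

Because C depends only on the ordering of two genes *inside one sample*, it
is invariant to any strictly increasing per-sample transform (library-size
scaling, log transform, quantile-preserving normalization) — no
normalization is ever needed. `lncpair` builds such signatures from
immune-related long non-coding RNAs (lncRNAs) and evaluates them against
survival, the way this is done for tumor cohorts such as head and neck
squamous cell carcinoma:

1. **Screen** lncRNAs co-expressed with curated immune genes
   (Pearson r > 0.4 on log2(x+1), p < 0.001).
2. **Differential expression** between tumor and normal samples
   (|log2FC| > 1, Benjamini–Hochberg FDR < 0.05; Wilcoxon rank-sum engine).
3. **Pair** the surviving genes into the 0/1 indicator matrix and keep pairs
   whose indicator frequency lies strictly between 20% and 80% of samples.
4. **Select** a signature: per-pair univariate Cox screen (Wald p < 0.05) →
   cross-validated LASSO-Cox (λ_min by default) → forward-stepwise
   multivariate Cox by AIC.
5. **Score and stratify**: risk score η_s = Σ_i β_i · C_{i,s}; discrimination
   by IPCW time-dependent ROC/AUC at 1/3/5 years; the risk cutoff is the
   AIC minimum over dichotomized Cox fits; patients split into high/low risk.
6. **Downstream**: Kaplan–Meier + log-rank between risk groups; chi-squared
   and rank tests against clinical covariates; independence of the score in
   multivariate Cox; Spearman correlation with immune-infiltration scores;
   checkpoint-gene expression and drug-IC50 comparisons between groups.

A seeded synthetic-cohort generator with planted pairs of known log hazard
ratios makes every stage testable without any data download.

## Worked example

```python
from lncpair import PairSignatureModel, SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=3))   # 100 tumor / 20 normal samples
model = PairSignatureModel(ds.expression, ds.clinical, ds.annotation, ds.immune_genes)
results = model.fit()
print(results.summary())
```

```
Rank-pair prognostic signature
==============================================================
patients: 100   events: 73
lncRNAs in matrix:          60
immune-related lncRNAs:     20
differentially expressed:   19 (19 up / 0 down)
pairs built:                171
valid pairs (20-80%):       136
univariate survivors:       14
LASSO candidates:           14  (lambda rule: lambda_min, lambda = 0.0052433)
final signature size:       4

Final multivariate Cox fit (Wald):
                   beta     HR  HR_ci_low  HR_ci_high     se      p
covariate
LNC0012|LNC0014  0.8329 2.3000     1.2946      4.0862 0.2932 0.0045
LNC0000|LNC0002  0.8088 2.2451     1.3055      3.8610 0.2766 0.0035
LNC0005|LNC0012 -0.6087 0.5440     0.3229      0.9167 0.2662 0.0222
LNC0009|LNC0018  0.6211 1.8610     1.0626      3.2593 0.2859 0.0298

Time-dependent AUC: 1y = 0.666  3y = 0.784  5y = 0.829
Risk cutoff (AIC minimum on the 5-year horizon): 1.4419
High risk: 43   Low risk: 57
Log-rank high vs low: chi2 = 19.84, p = 8.41e-06
```

Reading the output: the cascade retained 4 of 136 valid pairs; each row of
the Cox table is one signature pair with its log hazard ratio β (a patient in
whom LNC0012 outranks LNC0014 carries 2.30× the hazard, 95% CI 1.29–4.09);
AUCs are the IPCW time-dependent discrimination for death by 1/3/5 years;
patients with Σβ·C above 1.44 form the high-risk group, whose survival is
clearly worse (log-rank p ≈ 1e−5). The simulation planted the pairs
`LNC0000|LNC0001` (β=+1) and `LNC0002|LNC0003` (β=−1); at this small n the
model recovers correlated surrogates — at n = 400 (see below) both planted
pairs are recovered with small coefficient error.

Downstream comparisons hang off the results object
(`results.clinical_association()`, `results.independence_cox()`,
`results.immune_correlation(ds.infiltration)`,
`results.drug_sensitivity_compare(ds.drugs)`), and
`results.save(outdir)` writes every stage as TSV plus a JSON manifest.

The same pipeline runs from the shell on TSV inputs:

```bash
lncpair simulate --seed 11 --out data/
lncpair run --expression data/expression.tsv --groups data/sample_groups.tsv \
    --clinical data/clinical.tsv --annotation data/annotation.tsv \
    --immune-genes data/immune_genes.txt \
    --infiltration data/infiltration.tsv --ic50 data/ic50.tsv --out out/
```

Stage-wise subcommands (`screen`, `pair`, `train`, `evaluate`,
`downstream`) read and write the same TSV dialects, so any stage can be
re-run from serialized intermediates.

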