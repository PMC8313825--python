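# Methods

## The model

`lncpair` fits a Cox proportional-hazards model whose covariates are binary
within-sample rank indicators of gene pairs. For genes A, B and patient
*s*, the indicator is `C_s(A,B) = 1{x_s(A) > x_s(B)}` with ties scoring 0
(the strict "otherwise 0" rule). Each unordered couple appears once, in
canonical orientation (lexicographically smaller gene id first); the mirror
orientation carries no extra information because `C(B,A) = 1 − C(A,B)` away
from ties. The patient's risk score is the linear predictor of the final
multivariate fit, `η_s = Σ_i β_i · C_{i,s}`.

The defining property, tested as such, is **unit-freeness from the pair
transform onward**: any strictly increasing per-sample transform of the
expression values leaves the pair matrix — and therefore risk scores, risk
groups and every rank-based downstream test — bitwise unchanged. The
*upstream* screens are deliberately not unit-free: co-expression and
differential expression operate on log2(x+1) values, where variance
stabilization matters more than scale invariance.

## Cascade and thresholds

| stage | rule | default | rationale |
|---|---|---|---|
| immune-related screen | Pearson r on log2(x+1), all samples | r > 0.4, p < 0.001 (raw) | conventional co-expression gate; p from the t transform with n−2 df; no multiplicity correction by design — the raw-p rule is part of the procedure |
| differential expression | Wilcoxon rank-sum on log2(x+1), BH FDR | \|log2FC\| > 1, FDR < 0.05 | the two-sided fold-change gate admits down-regulated genes; a Welch-t engine is available by config |
| pair validity | indicator frequency over samples | 0.2 < f < 0.8, strict | near-constant indicators cannot discriminate outcomes; the fraction is over samples (the only per-pair-computable reading) |
| univariate screen | per-pair Cox Wald p | p < 0.05 | standard candidate filter |
| LASSO-Cox | CV partial-likelihood deviance | λ_min (λ_1se by flag), 10 folds | λ_min is the permissive choice appropriate before a stepwise refinement |
| stepwise Cox | forward by AIC with backward refinement | — | AIC is used because the same criterion drives the cutpoint scan |
| ROC horizons | IPCW cumulative/dynamic ROC | 1, 3, 5 years (365-day years) | standard clinical horizons |
| cutpoint | AIC minimum over dichotomized Cox fits | min_group_frac = 0.1 | the guard prevents monotone-likelihood fits at extreme splits |

"Correlation > 0.4" is read literally as *positive* correlation; an
`abs_cor` switch enables |r| > 0.4. The correlation screen uses all samples
(tumor and normal), the WGCNA-style convention; a tumor-only variant would
be a one-line config change but is not the default.

## Survival numerics

* **Cox fitting** is Newton–Raphson with step-halving on the log partial
  likelihood, Efron tie correction by default (Breslow by config; the two
  coincide on tie-free data, which is asserted in tests). Convergence:
  max |score| < 1e−9 or relative log-likelihood change < 1e−12, ≤ 50
  iterations. Standard errors come from the inverse observed information;
  p-values and CIs are Wald. Monotone likelihood (perfect separation) is
  flagged when |β| exceeds 20 while the likelihood still improves;
  zero-variance covariates are dropped and reported, never silently kept.
  A vectorized fast path handles tie-free data (the common case for
  continuous survival times); a grouped loop handles ties.
* **LASSO-Cox** delegates the path to glmnet-style coordinate descent
  (scikit-survival's coxnet): 100 log-spaced λ from λ_max (all-zero
  solution) down to 0.01·λ_max, columns standardized internally,
  coefficients reported on the original 0/1 scale. Cross-validation scores
  each λ by the Verweij–van Houwelingen deviance
  `−2·(ℓ_full(β_−k) − ℓ_train(β_−k))` with folds stratified by the event
  indicator; both λ_min and λ_1se are recorded. KKT conditions
  (|score_j| ≤ λ·n at zero coefficients, on the standardized scale) are
  audited in tests against this package's own score function.
* **Stepwise** is forward selection by AIC: add the candidate that most
  lowers AIC, then attempt single removals that lower AIC, stop when no
  move improves. Note the statistical consequence: a null candidate enters
  with probability P(χ²₁ > 2) ≈ 0.157, so with several pure-noise
  candidates the empty model is *not* the overwhelmingly likely outcome;
  tests assert the correctly derived null rates.
* **Time-dependent ROC** is the cumulative/dynamic estimator with inverse
  probability-of-censoring weights from the Kaplan–Meier estimate of the
  censoring distribution (case weight 1/G(T−); control weights cancel).
  This estimator was chosen over kernel-smoothed alternatives because it
  has no bandwidth and an exact no-censoring reduction: the trapezoidal
  AUC then equals the Mann–Whitney statistic with ties counted ½, asserted
  to 1e−10. AUCs from bandwidth-based estimators will differ slightly.
* **Cutpoint**: candidates are midpoints between consecutive distinct
  scores, restricted so each side keeps ≥ 10% of patients; the chosen
  cutoff minimizes the AIC of the dichotomized single-covariate Cox fit,
  with ties broken toward the median score. "Maximum inflection point" has
  no standard definition; the AIC minimum is the only operationalization
  that uses the computed AIC values decisively.
* Group membership is strict: high risk iff score > cutoff, consistent
  with the strict pair rule.

## Synthetic cohort generator

The generator emulates exactly the structure the cascade assumes, on the
log2 scale, with every stream seeded from one integer:

* **Co-expression**: a partnered lncRNA and immune gene share a latent
  factor with loading a; with unit noise the log-scale correlation is
  `r = a²/(a²+1)`, so the loading is solved from the target r (default
  0.7). Non-partnered lncRNAs are independent of immune genes.
* **Differential expression**: DE lncRNAs get a mean log2 shift (default
  2.0) in tumor samples; values are exponentiated to an FPKM-like scale.
* **Survival**: exponential proportional hazards, rate λ₀·e^η with λ₀ =
  1/1000 per day (median ≈ 2 years at η = 0, a plausible tumor-cohort
  scale) and η recomputed from the emitted matrix through the pairing rule
  — so truth equality is exact, not approximate. Censoring is independent
  exponential (rate 1/2000 per day) truncated at an administrative cutoff
  (10 years); times below one day are rounded up to one day. Planted pair
  members share the same baseline mean so their indicator frequency sits
  mid-range and survives the validity filter.
* **Clinical covariates**: stage is mildly correlated with η (latent
  correlation 0.2); age, gender, grade, T and N are independent noise.
* **Downstream tables**: cell-type scores are `−ρ·z(η) + noise` (default
  ρ = 0.4, a negative high-risk association); per-drug log-IC50 is
  `γ·z(η) + noise` with signed γ per drug so both response directions are
  representable.

Default cohort sizes are 100 tumor / 20 normal; recovery experiments use
400 tumor / 40 normal with 64 lncRNAs, of which four form the two planted
pairs (β = +1 and −1) and sixty are noise. What the generator does *not*
emulate: batch effects, tumor subtypes, realistic FPKM marginals beyond
log-normality, dependent censoring, or correlated noise between pairs —
so passing tests demonstrate correctness and calibration of the
procedure, not its clinical performance on real cohorts.

## Statistical conventions downstream

Between-group comparisons of independent high/low groups use the Wilcoxon
rank-sum (Mann–Whitney) test — exact enumeration when both groups have
≤ 25 tie-free observations, the normal approximation with continuity
correction otherwise. (Reports of "signed-rank" tests for independent
groups in this literature are a common misnomer; the groups are
independent, so rank-sum is the correct test.) Categorical association
uses the chi-squared statistic Σ(O−E)²/E without continuity correction;
three or more score groups use Kruskal–Wallis; correlations are Spearman.
Stage-like covariates enter Cox models through a configurable ordinal map
(I–IV → 1–4, T1–T4 → 1–4, N0–N3 → 0–3). Exactly collinear covariates are
dropped (the later one) with a report. The downstream significance flag is
p < 0.05.

## Problem sizes

Unit and property tests run at n ≤ 500 with seeded generators; the
end-to-end recovery experiment uses 20 seeds at 400 patients, chosen so
the whole suite completes in about a minute and a half on one CPU while
keeping per-seed power high enough that recovery is a property of the
method, not of a lucky seed. `scripts/acceptance.py` reports one full
pipeline run plus a 5-seed recovery summary.

## Known limitations

* The irlncRNA screen tests each (lncRNA, immune gene) couple at raw
  p < 0.001 by design fidelity; with many immune genes the retained set
  grows with panel size.
* The DE engine is rank-based, not an empirical-Bayes moderated t;
  moderated engines shrink variances and will call slightly different DE
  sets at small n.
* LASSO λ selection by CV deviance is seed-dependent through the fold
  assignment; the seed is mandatory in the API and recorded in outputs.
* The AIC cutpoint scan inherits the optimism of any optimized
  dichotomization; the null simulations bound, but do not remove, the
  selection effect.
* Proportional hazards holds by construction in the generator; none of
  the diagnostics test it on real data.
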